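"""Shared helpers for the detector implementations."""

from __future__ import annotations

import dataclasses

import numpy as np


def causal_moving_average(x: np.ndarray, window: int) -> np.ndarray:
    """Causal boxcar average: y[n] = mean(x[max(0, n-window+1) .. n]).

    The leading edge uses the partial window, so the output has the same
    length as the input and no startup bias toward zero.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    x = np.asarray(x, dtype=float)
    csum = np.concatenate(([0.0], np.cumsum(x)))
    n = x.size
    idx = np.arange(n)
    lo = np.maximum(idx - window + 1, 0)
    return (csum[idx + 1] - csum[lo]) / (idx + 1 - lo)


def ms_to_samples(ms: float, fs: float) -> int:
    """Duration in ms to a sample count (at least 1 for positive input)."""
    return max(1, int(round(ms * fs / 1000.0)))


def params_dict(params) -> dict:
    """Flatten a params dataclass into the DetectionResult params mapping."""
    return dataclasses.asdict(params)


def check_min_length(n: int, needed: int, what: str) -> None:
    if n < needed:
        raise ValueError(f"record too short: {n} samples, {what} needs >= {needed}")
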
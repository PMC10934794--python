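"""Detector 2: dual high-pass moving-average paths with an adaptive
convex-combination threshold.

Two parallel paths high-pass the ECG by subtracting a causal moving
average, then rectify:

    u[n] = |x[n] - MA_short(x)[n]|     (short window -> high cutoff)
    y[n] = |x[n] - MA_long(x)[n]|      (long window  -> low cutoff)

``u`` triggers a fixed 200 ms search window; the R-peak is the argmax of
``y`` inside the window.  Because ``x[n]`` itself appears undelayed in
both paths, the feature peaks essentially at the R apex, which is what
gives this detector its good behavior at tight temporal tolerances.
After each beat the trigger threshold is updated as a convex combination
of its previous value and a fixed fraction of the ``y`` amplitude at the
last R-peak (the fraction keeps the steady-state threshold below the
typical trigger-path peak; a threshold that converged to the full peak
amplitude would stop triggering).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..records import DetectionResult, EcgRecord
from ._common import causal_moving_average, check_min_length, ms_to_samples, params_dict

__all__ = ["Alg2Params", "detect_dual_ma", "features_dual_ma"]


@dataclass(frozen=True)
class Alg2Params:
    """Parameters of the dual moving-average detector.

    Window lengths are in samples (defaults tuned for 360 Hz: 28 samples
    ~ 78 ms and 110 samples ~ 306 ms).  ``alpha`` weights the previous
    threshold and ``beta`` the contribution of the last R-peak; they
    must sum to 1.  ``peak_fraction`` scales the R-peak amplitude that
    enters the update.  The threshold is initialized to
    ``init_coeff x max(u)`` over the initialization window.
    """

    n_short: int = 28
    n_long: int = 110
    search_window_ms: float = 200.0
    refractory_ms: float = 200.0
    alpha: float = 0.7
    beta: float = 0.3
    peak_fraction: float = 0.5
    init_window_s: float = 2.0
    init_coeff: float = 0.5

    def __post_init__(self) -> None:
        if not 0 < self.n_short < self.n_long:
            raise ValueError("need 0 < n_short < n_long")
        if abs(self.alpha + self.beta - 1.0) > 1e-9:
            raise ValueError("alpha + beta must equal 1")
        for name in ("search_window_ms", "refractory_ms", "init_window_s",
                     "init_coeff", "peak_fraction"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")


def features_dual_ma(
    record: EcgRecord, params: Alg2Params
) -> tuple[np.ndarray, np.ndarray]:
    """The two rectified high-pass paths (u, y)."""
    x = record.samples
    u = np.abs(x - causal_moving_average(x, params.n_short))
    y = np.abs(x - causal_moving_average(x, params.n_long))
    return u, y


def detect_dual_ma(record: EcgRecord, params: Alg2Params | None = None) -> DetectionResult:
    params = params or Alg2Params()
    fs = record.fs
    check_min_length(len(record), params.n_long + 1, "the long moving average")
    init_n = min(len(record), ms_to_samples(params.init_window_s * 1000.0, fs))

    u, y = features_dual_ma(record, params)
    search_w = ms_to_samples(params.search_window_ms, fs)
    refr = ms_to_samples(params.refractory_ms, fs)

    # Threshold initialized from the record's opening seconds; detection
    # then runs from sample 0 (offline-benchmark initialization).
    thr = params.init_coeff * float(np.max(u[:init_n]))
    peaks: list[int] = []
    n = u.size
    i = 0
    while i < n:
        if u[i] > thr:
            w_end = min(n, i + search_w)
            peak = i + int(np.argmax(y[i:w_end]))
            peaks.append(peak)
            thr = params.alpha * thr + params.beta * params.peak_fraction * float(y[peak])
            # State 3: waiting state after the R-peak occurrence.
            i = max(w_end, peak + refr)
        else:
            i += 1

    return DetectionResult(
        positions=np.asarray(peaks, dtype=np.int64),
        algorithm_id=2,
        params=params_dict(params),
    )
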
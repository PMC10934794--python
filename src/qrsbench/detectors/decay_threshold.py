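"""Detector 1: differentiate / moving-window average / square, with a
three-state exponentially decaying threshold.

A low-complexity detector for wearable devices.  The feature signal is
``square(MWA(first_difference(x)))``; note the operation order —
differentiate, then average, then square.  The causal moving average of
the first difference is proportional to ``x[n] - x[n-W]``, so the
squared feature has two lobes, one on the QRS upstroke and a mirror
lobe W samples later on the downstroke.  The default window W is sized
to a QRS upstroke (40 ms), which keeps both lobes — and hence the
marked R-peak — within the QRS complex itself.

Decision logic cycles through three states:

1. *search* — once the feature crosses the decaying threshold, the R-peak
   is the feature argmax within a fixed 260 ms window;
2. *wait* — a 200 ms refractory wait from the R-peak;
3. *decay* — the threshold restarts at ``c x (mean feature amplitude at
   all previously found R-peaks)`` and decays exponentially until the
   feature reaches it.

The initial threshold is ``c x max(feature)`` over a short learning period.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..records import DetectionResult, EcgRecord
from ._common import causal_moving_average, check_min_length, ms_to_samples, params_dict

__all__ = ["Alg1Params", "detect_decay_threshold", "feature_decay_threshold"]


@dataclass(frozen=True)
class Alg1Params:
    """Parameters of the decaying-threshold detector.

    All durations in milliseconds.  ``threshold_coeff`` scales the running
    mean of feature amplitudes at previous R-peaks; ``decay_tau_ms`` is
    the exponential time constant of the threshold decay.
    """

    mwa_window_ms: float = 40.0
    search_window_ms: float = 260.0
    refractory_ms: float = 200.0
    decay_tau_ms: float = 200.0
    threshold_coeff: float = 0.5
    learning_period_s: float = 2.0

    def __post_init__(self) -> None:
        for name in ("mwa_window_ms", "search_window_ms", "refractory_ms",
                     "decay_tau_ms", "learning_period_s"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if not self.threshold_coeff > 0:
            raise ValueError("threshold_coeff must be positive")


def feature_decay_threshold(record: EcgRecord, params: Alg1Params) -> np.ndarray:
    """The preprocessed feature signal: square(MWA(first difference))."""
    x = record.samples
    d = np.diff(x, prepend=x[0])
    mwa = causal_moving_average(d, ms_to_samples(params.mwa_window_ms, record.fs))
    return mwa * mwa


def detect_decay_threshold(
    record: EcgRecord, params: Alg1Params | None = None
) -> DetectionResult:
    params = params or Alg1Params()
    fs = record.fs
    learn_n = ms_to_samples(params.learning_period_s * 1000.0, fs)
    check_min_length(len(record), learn_n + 1, "the learning period")

    f = feature_decay_threshold(record, params)
    search_w = ms_to_samples(params.search_window_ms, fs)
    refr = ms_to_samples(params.refractory_ms, fs)
    tau = params.decay_tau_ms * fs / 1000.0
    c = params.threshold_coeff

    # Offline-benchmark initialization: the starting threshold is taken
    # from the record's opening seconds, then detection runs from sample
    # 0, so beats inside the initialization window remain detectable.
    thr_start = c * float(np.max(f[:learn_n]))
    decay_from = 0
    peaks: list[int] = []
    peak_amp_sum = 0.0
    n = f.size
    i = 0
    while i < n:
        thr = thr_start * np.exp(-(i - decay_from) / tau)
        if f[i] > thr:
            # State 1: R-peak at feature argmax within the search window.
            w_end = min(n, i + search_w)
            peak = i + int(np.argmax(f[i:w_end]))
            peaks.append(peak)
            peak_amp_sum += float(f[peak])
            # State 2: wait out the refractory period from the R-peak,
            # but never rewind into the already-searched window.
            i = max(w_end, peak + refr)
            # State 3: restart the threshold from the running mean of
            # feature amplitudes at all R-peaks found so far.
            thr_start = c * peak_amp_sum / len(peaks)
            decay_from = i
        else:
            i += 1

    return DetectionResult(
        positions=np.asarray(peaks, dtype=np.int64),
        algorithm_id=1,
        params=params_dict(params),
    )
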
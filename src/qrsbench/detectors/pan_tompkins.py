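"""Detector 4: Pan-Tompkins with a Butterworth band-pass front end.

The classic preprocessing chain — band-pass filter, five-point
derivative, squaring, 150 ms moving-window integration — with a
Butterworth band-pass (5-15 Hz) in place of the original cascaded
integer filters.  The decision stage keeps the adaptive signal/noise
level estimates (SPK/NPK, 0.125/0.875 updates), the 200 ms refractory
period, threshold halving under an irregular rhythm (any of the last
RR intervals outside 92-116 % of the regular-RR average), and the
searchback mechanism that re-scans with half the threshold when no beat
arrives within 1.66x the average RR interval.  The parallel second
threshold on the band-passed signal is not applied.

The R-peak fiducial is the first local maximum of the integrated feature
above the threshold.  No group-delay compensation is applied, so this
detector carries the feature chain's inherent temporal offset — which is
precisely what a temporal-tolerance sweep is designed to expose.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from ..records import DetectionResult, EcgRecord
from ._common import causal_moving_average, check_min_length, ms_to_samples, params_dict

__all__ = ["Alg4Params", "detect_pan_tompkins", "feature_pan_tompkins"]


@dataclass(frozen=True)
class Alg4Params:
    """Parameters of the Pan-Tompkins adaptation.

    Numeric constants follow the original method: 5-15 Hz pass band,
    150 ms integration window, 0.125/0.875 running-estimate updates,
    searchback at 1.66x the average RR, 92-116 % RR regularity band.
    """

    bandpass_low_hz: float = 5.0
    bandpass_high_hz: float = 15.0
    bandpass_order: int = 2
    integration_window_ms: float = 150.0
    refractory_ms: float = 200.0
    level_weight: float = 0.125
    searchback_rr_factor: float = 1.66
    rr_low_frac: float = 0.92
    rr_high_frac: float = 1.16
    learning_period_s: float = 2.0

    def __post_init__(self) -> None:
        if not 0 < self.bandpass_low_hz < self.bandpass_high_hz:
            raise ValueError("need 0 < low cutoff < high cutoff")
        if not 0 < self.level_weight < 1:
            raise ValueError("level_weight must be in (0, 1)")


def feature_pan_tompkins(record: EcgRecord, params: Alg4Params) -> np.ndarray:
    """Band-pass -> 5-point derivative -> square -> moving-window integral."""
    fs = record.fs
    if params.bandpass_high_hz >= fs / 2:
        raise ValueError("high cutoff must be below the Nyquist frequency")
    sos = sps.butter(
        params.bandpass_order,
        [params.bandpass_low_hz, params.bandpass_high_hz],
        btype="bandpass",
        fs=fs,
        output="sos",
    )
    # initialize the filter state at the signal's starting level so a DC
    # offset does not inject a step transient at sample 0
    zi = sps.sosfilt_zi(sos) * record.samples[0]
    bp, _ = sps.sosfilt(sos, record.samples, zi=zi)
    deriv = sps.lfilter(np.array([2.0, 1.0, 0.0, -1.0, -2.0]) / 8.0, [1.0], bp)
    squared = deriv * deriv
    return causal_moving_average(
        squared, ms_to_samples(params.integration_window_ms, fs)
    )


def _local_maxima(f: np.ndarray) -> np.ndarray:
    """Indices where f is strictly greater than both neighbors."""
    return np.nonzero((f[1:-1] > f[:-2]) & (f[1:-1] > f[2:]))[0] + 1


def detect_pan_tompkins(
    record: EcgRecord, params: Alg4Params | None = None
) -> DetectionResult:
    params = params or Alg4Params()
    fs = record.fs
    learn_n = ms_to_samples(params.learning_period_s * 1000.0, fs)
    check_min_length(len(record), learn_n + 1, "the learning period")

    f = feature_pan_tompkins(record, params)
    refr = ms_to_samples(params.refractory_ms, fs)
    w = params.level_weight

    spk = 0.25 * float(np.max(f[:learn_n]))
    npk = 0.5 * float(np.mean(f[:learn_n]))
    threshold = npk + 0.25 * (spk - npk)

    detections: list[int] = []
    rr_recent: list[int] = []   # last RR intervals (regular or not)
    rr_regular: list[int] = []  # RR intervals that fell inside the limits
    noise_peaks: list[tuple[int, float]] = []  # sub-threshold maxima since last beat

    def rr_average(seq: list[int]) -> float | None:
        return float(np.mean(seq[-8:])) if seq else None

    def accept(idx: int, val: float, from_searchback: bool) -> None:
        nonlocal spk, threshold
        if from_searchback:
            spk = 0.25 * val + 0.75 * spk
        else:
            spk = w * val + (1.0 - w) * spk
        if detections:
            rr = idx - detections[-1]
            avg_reg = rr_average(rr_regular) or rr_average(rr_recent)
            rr_recent.append(rr)
            if avg_reg is None or (
                params.rr_low_frac * avg_reg <= rr <= params.rr_high_frac * avg_reg
            ):
                rr_regular.append(rr)
        detections.append(idx)
        noise_peaks.clear()
        threshold = npk + 0.25 * (spk - npk)

    # Level estimates are initialized from the record's opening seconds;
    # the maxima scan then covers the whole record.
    maxima = _local_maxima(f)
    for idx in maxima:
        idx = int(idx)
        val = float(f[idx])
        # Searchback: no beat within 1.66x the average RR -> re-scan the
        # skipped stretch with half the threshold.
        rr_avg = rr_average(rr_regular) or rr_average(rr_recent)
        if detections and rr_avg is not None:
            if idx - detections[-1] > params.searchback_rr_factor * rr_avg:
                candidates = [
                    (j, v)
                    for j, v in noise_peaks
                    if detections[-1] + refr <= j <= idx - refr and v > threshold / 2.0
                ]
                if candidates:
                    j, v = max(candidates, key=lambda c: c[1])
                    accept(j, v, from_searchback=True)
        if detections and idx - detections[-1] < refr:
            continue
        if val > (threshold / 2.0 if _irregular(rr_recent, rr_regular, params) else threshold):
            accept(idx, val, from_searchback=False)
        else:
            npk = w * val + (1.0 - w) * npk
            noise_peaks.append((idx, val))
            threshold = npk + 0.25 * (spk - npk)

    return DetectionResult(
        positions=np.asarray(detections, dtype=np.int64),
        algorithm_id=4,
        params=params_dict(params),
    )


def _irregular(rr_recent: list[int], rr_regular: list[int], params: Alg4Params) -> bool:
    """Heart rate is irregular when the latest RR leaves the 92-116 % band."""
    if not rr_recent or not rr_regular:
        return False
    avg = float(np.mean(rr_regular[-8:]))
    last = rr_recent[-1]
    return not (params.rr_low_frac * avg <= last <= params.rr_high_frac * avg)
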
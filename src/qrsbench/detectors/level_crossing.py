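"""Detector 3: level-crossing sampling with asymmetric hysteresis,
followed by peak and beat detectors.

The amplitude range of the record is divided into ``2**M - 1`` uniform
levels (placed strictly inside the range, at multiples of
``range / 2**M``).  A level-crossing ADC emits a sample (an *event*) when
the signal

(a) crosses the next level in the same direction as the previous event, or
(b) crosses ``k_l`` levels in the opposite direction (asymmetric
    hysteresis); such an event is a *direction reversal* and flags a
    local peak of the input signal.

Each event carries the crossed level index, the direction, the reversal
flag, the inter-event interval as an 11-bit timer readout (ticks modulo
2048) and — for evaluation only — the absolute sample index.

The beat detector declares an R-peak at a reversal event whose preceding
monotonic run of events spans at least ``min_run_levels`` levels within
at most ``max_run_ms`` — a steep, tall slope, which is what a QRS
complex looks like through a level-crossing sampler.  The run-span
threshold is sized relative to the level grid (default 64, a quarter of
the 8-bit range): a QRS deflection sweeps most of the record's
amplitude range, while P and T waves or troughs span only a few percent
of it, and a threshold of a few levels would flag those and let the
refractory period block the true R reversal.  A 200 ms refractory
period suppresses the complementary reversal at the S trough.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..records import DetectionResult, EcgRecord
from ._common import ms_to_samples, params_dict

__all__ = ["Alg3Params", "LcEvent", "lc_adc_sample", "detect_level_crossing"]


@dataclass(frozen=True)
class Alg3Params:
    """Parameters of the level-crossing detector.

    ``resolution_bits`` (M) sets the 2**M - 1 level grid over the
    record's amplitude range; ``hysteresis_levels`` (k_l) is the number
    of opposite-direction crossings needed for a reversal sample.
    """

    resolution_bits: int = 8
    hysteresis_levels: int = 4
    min_run_levels: int = 64
    max_run_ms: float = 120.0
    refractory_ms: float = 200.0
    timer_bits: int = 11

    def __post_init__(self) -> None:
        if self.resolution_bits < 2:
            raise ValueError("resolution_bits must be >= 2")
        if self.hysteresis_levels < 1:
            raise ValueError("hysteresis_levels must be >= 1")
        if self.min_run_levels < 1:
            raise ValueError("min_run_levels must be >= 1")
        if not (self.max_run_ms > 0 and self.refractory_ms > 0):
            raise ValueError("durations must be positive")


@dataclass(frozen=True)
class LcEvent:
    """One level-crossing sample.

    ``dt11`` is the inter-event interval in sampling ticks modulo
    ``2**timer_bits`` (the hardware counter readout); ``sample`` keeps
    the absolute index for evaluation.
    """

    level: int
    direction: int  # +1 crossing upward, -1 downward
    reversal: bool  # True for direction reversals (local-peak flag)
    dt11: int
    sample: int


def level_grid(record: EcgRecord, params: Alg3Params) -> np.ndarray:
    """The 2**M - 1 uniform levels spanning the record's amplitude range."""
    lo = float(np.min(record.samples))
    hi = float(np.max(record.samples))
    m = params.resolution_bits
    step = (hi - lo) / (1 << m)
    return lo + step * np.arange(1, (1 << m))


def lc_adc_sample(record: EcgRecord, params: Alg3Params | None = None) -> list[LcEvent]:
    """Simulate the level-crossing ADC with asymmetric hysteresis.

    A constant record produces an empty event stream.  A sample landing
    exactly on a level counts as having crossed it upward.
    """
    params = params or Alg3Params()
    x = record.samples
    if np.min(x) == np.max(x):
        return []
    levels = level_grid(record, params)
    # pos[i] = number of levels <= x[i], in 0 .. 2**M - 1
    pos = np.searchsorted(levels, x, side="right")
    k_l = params.hysteresis_levels
    wrap = 1 << params.timer_bits

    events: list[LcEvent] = []
    last_dir = 0
    ref = 0  # level index of the last emitted event
    last_sample = 0
    change_idx = np.nonzero(np.diff(pos))[0] + 1

    def emit(level: int, direction: int, reversal: bool, i: int) -> None:
        nonlocal last_dir, ref, last_sample
        events.append(
            LcEvent(
                level=int(level),
                direction=direction,
                reversal=reversal,
                dt11=int((i - last_sample) % wrap),
                sample=int(i),
            )
        )
        last_dir = direction
        ref = int(level)
        last_sample = int(i)

    for i in change_idx:
        p_old, p_new = int(pos[i - 1]), int(pos[i])
        if p_new > p_old:  # upward crossings of levels p_old .. p_new-1
            for j in range(p_old, p_new):
                if last_dir >= 0:
                    if last_dir == 0 or j > ref:
                        emit(j, +1, False, i)
                elif j >= ref + k_l - 1:
                    emit(j, +1, True, i)
        else:  # downward crossings of levels p_old-1 .. p_new
            for j in range(p_old - 1, p_new - 1, -1):
                if last_dir <= 0:
                    if last_dir == 0 or j < ref:
                        emit(j, -1, False, i)
                elif j <= ref - k_l + 1:
                    emit(j, -1, True, i)
    return events


def detect_level_crossing(
    record: EcgRecord, params: Alg3Params | None = None
) -> DetectionResult:
    params = params or Alg3Params()
    events = lc_adc_sample(record, params)
    max_run = ms_to_samples(params.max_run_ms, record.fs)
    refr = ms_to_samples(params.refractory_ms, record.fs)

    peaks: list[int] = []
    run_start = 0  # index into events of the first event of the current run
    for e_idx, ev in enumerate(events):
        if ev.reversal and e_idx > run_start:
            first = events[run_start]
            last = events[e_idx - 1]
            span = abs(last.level - first.level) + 1
            duration = last.sample - first.sample
            if span >= params.min_run_levels and duration <= max_run:
                if not peaks or ev.sample - peaks[-1] >= refr:
                    peaks.append(ev.sample)
        if ev.reversal:
            run_start = e_idx  # the reversal event opens the next run
    return DetectionResult(
        positions=np.asarray(peaks, dtype=np.int64),
        algorithm_id=3,
        params=params_dict(params),
    )
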
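"""The four QRS detection algorithms under benchmark.

Each detector maps an :class:`~qrsbench.records.EcgRecord` to a
:class:`~qrsbench.records.DetectionResult` of strictly sorted R-peak
sample indices, deterministically (no randomness anywhere).  The
numeric algorithm ids used in reports are:

1. decaying-threshold detector (diff / moving average / square),
2. dual moving-average detector (two high-pass paths),
3. level-crossing detector (event-based sampling, no filters),
4. Pan-Tompkins adaptation (Butterworth band-pass front end).
"""

from __future__ import annotations

from ..records import DetectionResult, EcgRecord
from .decay_threshold import Alg1Params, detect_decay_threshold
from .dual_ma import Alg2Params, detect_dual_ma
from .level_crossing import Alg3Params, LcEvent, detect_level_crossing, lc_adc_sample
from .pan_tompkins import Alg4Params, detect_pan_tompkins

__all__ = [
    "Alg1Params",
    "Alg2Params",
    "Alg3Params",
    "Alg4Params",
    "LcEvent",
    "detect_decay_threshold",
    "detect_dual_ma",
    "detect_level_crossing",
    "detect_pan_tompkins",
    "lc_adc_sample",
    "ALGORITHMS",
    "detect",
]

#: algorithm id -> (params class, detector function)
ALGORITHMS = {
    1: (Alg1Params, detect_decay_threshold),
    2: (Alg2Params, detect_dual_ma),
    3: (Alg3Params, detect_level_crossing),
    4: (Alg4Params, detect_pan_tompkins),
}


def detect(record: EcgRecord, algorithm_id: int, params=None) -> DetectionResult:
    """Run one of the four detectors by its numeric id."""
    try:
        params_cls, fn = ALGORITHMS[algorithm_id]
    except KeyError:
        raise ValueError(f"unknown algorithm id {algorithm_id}; valid ids are 1-4")
    if params is not None and not isinstance(params, params_cls):
        raise TypeError(
            f"algorithm {algorithm_id} expects {params_cls.__name__}, "
            f"got {type(params).__name__}"
        )
    return fn(record, params)
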
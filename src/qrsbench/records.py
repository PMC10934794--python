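"""Core containers for ECG records, beat annotations and detector output.

Conventions used throughout the package:

* sample indices are 0-based integers into the selected channel;
* amplitudes are physical units (millivolts) unless stated otherwise;
* annotation and detection position arrays are strictly increasing.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "MorphologyCode",
    "EcgRecord",
    "AnnotationSet",
    "DetectionResult",
    "MORPHOLOGY_CLASSES",
]


class MorphologyCode(str, enum.Enum):
    """Beat morphology classes.

    The six classes are the most frequent beat types of ambulatory ECG
    databases: normal (N), left/right bundle branch block (L, R),
    premature ventricular (V), paced (P, WFDB symbol ``/``) and atrial
    premature (A).  Every other beat symbol maps to ``OTHER``.
    """

    N = "N"
    L = "L"
    R = "R"
    V = "V"
    P = "P"
    A = "A"
    OTHER = "OTHER"

    @classmethod
    def from_symbol(cls, symbol: str) -> "MorphologyCode":
        """Map a WFDB beat annotation symbol to a morphology class (total map)."""
        return _SYMBOL_TO_CODE.get(symbol, cls.OTHER)


#: The six morphology classes used for stratified scoring, in report order.
MORPHOLOGY_CLASSES: tuple[MorphologyCode, ...] = (
    MorphologyCode.N,
    MorphologyCode.L,
    MorphologyCode.R,
    MorphologyCode.V,
    MorphologyCode.P,
    MorphologyCode.A,
)

_SYMBOL_TO_CODE: Mapping[str, MorphologyCode] = {
    "N": MorphologyCode.N,
    "L": MorphologyCode.L,
    "R": MorphologyCode.R,
    "V": MorphologyCode.V,
    "/": MorphologyCode.P,  # paced beat
    "A": MorphologyCode.A,
}


@dataclass(frozen=True)
class EcgRecord:
    """A uniformly sampled single-channel ECG signal.

    Parameters
    ----------
    record_id : str
        Identifier, e.g. a database record name like ``"100"``.
    fs : float
        Sampling frequency in Hz; must be positive.
    samples : numpy.ndarray
        1-D float array of amplitudes in physical units (mV).
    channel_index : int
        Which channel of the source file this signal came from.
    """

    record_id: str
    fs: float
    samples: np.ndarray
    channel_index: int = 0

    def __post_init__(self) -> None:
        if not self.fs > 0:
            raise ValueError(f"sampling frequency must be positive, got {self.fs}")
        samples = np.asarray(self.samples, dtype=float)
        if samples.ndim != 1 or samples.size == 0:
            raise ValueError("samples must be a non-empty 1-D array")
        object.__setattr__(self, "samples", samples)

    def __len__(self) -> int:
        return int(self.samples.size)

    @property
    def duration_s(self) -> float:
        return len(self) / self.fs

    def with_samples(self, samples: np.ndarray, record_id: str | None = None) -> "EcgRecord":
        """Copy of this record with new sample values (same fs and channel)."""
        return EcgRecord(
            record_id=record_id if record_id is not None else self.record_id,
            fs=self.fs,
            samples=samples,
            channel_index=self.channel_index,
        )


@dataclass(frozen=True)
class AnnotationSet:
    """Reference beat positions (sample indices) with morphology labels."""

    positions: np.ndarray
    labels: tuple[MorphologyCode, ...]

    def __post_init__(self) -> None:
        positions = np.asarray(self.positions, dtype=np.int64)
        if positions.ndim != 1:
            raise ValueError("positions must be 1-D")
        if positions.size and np.any(np.diff(positions) <= 0):
            raise ValueError("annotation positions must be strictly increasing")
        labels = tuple(MorphologyCode(l) for l in self.labels)
        if len(labels) != positions.size:
            raise ValueError(
                f"{positions.size} positions but {len(labels)} labels"
            )
        object.__setattr__(self, "positions", positions)
        object.__setattr__(self, "labels", labels)

    def __len__(self) -> int:
        return int(self.positions.size)

    def count(self, morphology: MorphologyCode | None = None) -> int:
        """Total beats (TB), optionally restricted to one morphology class."""
        if morphology is None:
            return len(self)
        return sum(1 for l in self.labels if l is MorphologyCode(morphology))

    def label_mask(self, morphology: MorphologyCode) -> np.ndarray:
        morphology = MorphologyCode(morphology)
        return np.fromiter(
            (l is morphology for l in self.labels), dtype=bool, count=len(self)
        )


@dataclass(frozen=True)
class DetectionResult:
    """Sorted R-peak sample indices produced by one detector run."""

    positions: np.ndarray
    algorithm_id: int
    params: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        positions = np.asarray(self.positions, dtype=np.int64)
        if positions.ndim != 1:
            raise ValueError("positions must be 1-D")
        if positions.size and np.any(np.diff(positions) <= 0):
            raise ValueError("detections must be strictly increasing")
        object.__setattr__(self, "positions", positions)
        object.__setattr__(self, "params", dict(self.params))

    def __len__(self) -> int:
        return int(self.positions.size)


def as_positions(values: Sequence[int] | np.ndarray) -> np.ndarray:
    """Validate and return a strictly increasing int64 position array."""
    arr = np.asarray(values, dtype=np.int64)
    if arr.ndim != 1:
        raise ValueError("positions must be 1-D")
    if arr.size and np.any(np.diff(arr) <= 0):
        raise ValueError("positions must be strictly increasing")
    return arr
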
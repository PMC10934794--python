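"""SNR-controlled mixing of muscular noise into ECG records.

The noise-stress procedure works on first-difference power factors:

    P = 1/(N-1) * sum_{i=0}^{N-2} (x[i+1] - x[i])^2

and a *relative* SNR between an ECG record (``Ps``) and a noise record
(``Pn``).  Two conventions are provided, because the source methodology
prints a 20·log10 factor on the power ratio and a scaling factor
``k = sqrt(tSNR / eSNR)`` that takes a square root of a ratio of *dB
values* — which cannot both be physically consistent:

* ``"printed"`` — literal fidelity: SNR = 20·log10(Ps/Pn) and
  ``k = sqrt(tSNR/eSNR)``;
* ``"power"`` — physically consistent: ``k`` is solved so that the scaled
  noise ``k·MA`` actually yields the target SNR under the chosen SNR
  convention (for the 20·log convention, ``k = 10**((eSNR - tSNR)/40)``).

The mixed record is always ``ECG_test[i] = ECG_orig[i] + k·MA[i]``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .records import EcgRecord

__all__ = [
    "difference_power",
    "relative_snr",
    "scaling_factor",
    "mix",
    "build_noise_dataset",
    "MixSpec",
]

SnrConvention = Literal["printed-20log", "power-10log"]
ScalingConvention = Literal["printed", "power"]

_LOG_FACTOR = {"printed-20log": 20.0, "power-10log": 10.0}


def difference_power(x: Sequence[float] | np.ndarray) -> float:
    """First-difference power factor of a sample sequence.

    Returns ``1/(N-1) * sum (x[i+1]-x[i])**2`` over the N-1 consecutive
    differences.  Zero iff the signal is constant.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("difference_power needs a 1-D sequence of length >= 2")
    d = np.diff(x)
    return float(np.dot(d, d) / d.size)


def relative_snr(
    ps: float, pn: float, convention: SnrConvention = "printed-20log"
) -> float:
    """Relative SNR in dB between signal and noise power factors."""
    if ps <= 0 or pn <= 0:
        raise ValueError(f"power factors must be positive, got Ps={ps}, Pn={pn}")
    return _LOG_FACTOR[convention] * float(np.log10(ps / pn))


@dataclass(frozen=True)
class MixSpec:
    """A resolved mixing specification: target SNR and noise scaling factor."""

    target_snr_db: float
    scaling_convention: ScalingConvention
    k: float

    def __post_init__(self) -> None:
        if not self.k > 0:
            raise ValueError(f"scaling factor must be positive, got {self.k}")


def scaling_factor(
    esnr_db: float,
    tsnr_db: float,
    convention: ScalingConvention = "printed",
    snr_convention: SnrConvention = "printed-20log",
) -> MixSpec:
    """Noise scaling factor ``k`` taking the existing SNR to the target SNR.

    ``"printed"`` evaluates the literal formula ``k = sqrt(tSNR/eSNR)``
    (a ratio of dB values under a square root); it is only defined for
    strictly positive eSNR and tSNR.  ``"power"`` solves
    ``relative_snr(Ps, k**2 * Pn) == tSNR`` for ``k``, i.e.
    ``k = 10**((eSNR - tSNR) / (2 * log_factor))``.
    In both conventions ``k = 1`` when the target equals the existing SNR.
    """
    if not (np.isfinite(esnr_db) and np.isfinite(tsnr_db)):
        raise ValueError("SNR values must be finite")
    if convention == "printed":
        if esnr_db <= 0 or tsnr_db <= 0:
            raise ValueError(
                "the printed scaling formula sqrt(tSNR/eSNR) is undefined for "
                f"non-positive dB values (eSNR={esnr_db}, tSNR={tsnr_db})"
            )
        k = float(np.sqrt(tsnr_db / esnr_db))
    elif convention == "power":
        factor = _LOG_FACTOR[snr_convention]
        k = float(10.0 ** ((esnr_db - tsnr_db) / (2.0 * factor)))
    else:
        raise ValueError(f"unknown scaling convention {convention!r}")
    return MixSpec(target_snr_db=float(tsnr_db), scaling_convention=convention, k=k)


def mix(ecg: EcgRecord, noise: EcgRecord | np.ndarray, k: float) -> EcgRecord:
    """Additively mix scaled noise into an ECG record, sample by sample.

    The noise must be aligned to the record's sampling grid: an
    :class:`EcgRecord` noise input must have the same fs.  Noise shorter
    than the record is tiled end-to-start; longer noise is truncated.
    """
    if isinstance(noise, EcgRecord):
        if noise.fs != ecg.fs:
            raise ValueError(
                f"noise fs {noise.fs} Hz does not match record fs {ecg.fs} Hz"
            )
        noise_samples = noise.samples
    else:
        noise_samples = np.asarray(noise, dtype=float)
    n = len(ecg)
    if noise_samples.size >= n:
        aligned = noise_samples[:n]
    else:
        reps = int(np.ceil(n / noise_samples.size))
        aligned = np.tile(noise_samples, reps)[:n]
    return ecg.with_samples(ecg.samples + float(k) * aligned)


def build_noise_dataset(
    records: Sequence[EcgRecord],
    noise: EcgRecord,
    targets_db: Sequence[float],
    convention: ScalingConvention = "printed",
    snr_convention: SnrConvention = "printed-20log",
) -> dict[str, dict[float, EcgRecord]]:
    """Mix one noise record into many ECG records at each target SNR.

    For each record the existing SNR is computed from the record's own
    difference power and the noise record's difference power; one mixed
    record per target is produced.  Returns
    ``{record_id: {target_snr_db: mixed record}}`` and also reports the
    per-record specs through each mixed record's id suffix.
    """
    if len(targets_db) == 0:
        raise ValueError("at least one target SNR is required")
    pn = difference_power(noise.samples)
    out: dict[str, dict[float, EcgRecord]] = {}
    for rec in records:
        ps = difference_power(rec.samples)
        esnr = relative_snr(ps, pn, snr_convention)
        per_target: dict[float, EcgRecord] = {}
        for tsnr in targets_db:
            spec = scaling_factor(esnr, tsnr, convention, snr_convention)
            mixed = mix(rec, noise, spec.k)
            per_target[float(tsnr)] = mixed.with_samples(
                mixed.samples, record_id=f"{rec.record_id}_snr{tsnr:g}"
            )
        out[rec.record_id] = per_target
    return out


def mixing_manifest(
    records: Sequence[EcgRecord],
    noise: EcgRecord,
    targets_db: Sequence[float],
    convention: ScalingConvention = "printed",
    snr_convention: SnrConvention = "printed-20log",
) -> list[dict[str, float | str]]:
    """Per-(record, target) mixing parameters: eSNR, tSNR and k."""
    pn = difference_power(noise.samples)
    rows: list[dict[str, float | str]] = []
    for rec in records:
        ps = difference_power(rec.samples)
        esnr = relative_snr(ps, pn, snr_convention)
        for tsnr in targets_db:
            spec = scaling_factor(esnr, tsnr, convention, snr_convention)
            rows.append(
                {
                    "record_id": rec.record_id,
                    "esnr_db": esnr,
                    "tsnr_db": float(tsnr),
                    "k": spec.k,
                }
            )
    return rows
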
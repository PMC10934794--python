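"""Synthetic ECG and muscle-artifact noise with exact ground truth.

Beats are sums of smooth Gaussian bumps (P wave, QRS complex, T wave)
placed at RR-jittered positions, so the R-apex sample of every beat is
known analytically.  Morphology classes differ in polarity, width and
amplitude of the bumps: ventricular (V) beats are wide, large and lack a
P wave; paced (P) beats are a narrow pacing spike followed by a wide
complex; bundle-branch-block beats (L, R) widen or notch the QRS.  The
generator emulates the *structure* of an arrhythmia-database record —
a uniformly sampled channel plus a per-beat label stream — not the
physiological dynamics of real ECG.

Muscle noise is band-limited Gaussian noise (default 20-120 Hz, chosen
to overlap QRS spectral content, which is what makes muscular artifact
hard for QRS detectors), normalized to unit first-difference power.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import signal as sps

from .noise import build_noise_dataset, difference_power, mixing_manifest
from .records import AnnotationSet, EcgRecord, MorphologyCode
from .wfdb_io import write_annotations, write_record

__all__ = [
    "SynthSpec",
    "generate_ecg",
    "generate_muscle_noise",
    "make_benchmark_fixture",
    "BEAT_TEMPLATES",
]

# Per-morphology beat templates: (amplitude mV, center offset ms from the
# R apex, Gaussian sigma ms).  V-type QRS is wider than N-type by design.
BEAT_TEMPLATES: dict[MorphologyCode, tuple[tuple[float, float, float], ...]] = {
    MorphologyCode.N: (
        (0.15, -160.0, 22.0),   # P wave
        (-0.10, -28.0, 9.0),    # Q
        (1.00, 0.0, 11.0),      # R
        (-0.22, 26.0, 10.0),    # S
        (0.35, 230.0, 55.0),    # T wave
    ),
    MorphologyCode.L: (
        (0.12, -170.0, 22.0),
        (0.90, 0.0, 24.0),      # broad, notch-free QRS
        (-0.30, 48.0, 20.0),
        (0.30, 260.0, 60.0),
    ),
    MorphologyCode.R: (
        (0.14, -160.0, 22.0),
        (0.95, 0.0, 18.0),
        (-0.45, 36.0, 14.0),    # deep S
        (0.30, 240.0, 55.0),
    ),
    MorphologyCode.V: (
        (1.25, 0.0, 28.0),      # wide ventricular complex, no P wave
        (-0.50, 55.0, 25.0),
        (-0.40, 280.0, 70.0),   # discordant (inverted) T
    ),
    MorphologyCode.P: (
        (1.10, 0.0, 4.0),       # pacing spike
        (0.55, 65.0, 32.0),     # evoked wide complex
        (0.30, 280.0, 60.0),
    ),
    MorphologyCode.A: (
        (0.18, -140.0, 18.0),   # early ectopic P'
        (-0.08, -26.0, 9.0),
        (0.95, 0.0, 11.0),
        (-0.20, 25.0, 10.0),
        (0.30, 220.0, 50.0),
    ),
}

_CODE_TO_WFDB_SYMBOL = {
    MorphologyCode.N: "N",
    MorphologyCode.L: "L",
    MorphologyCode.R: "R",
    MorphologyCode.V: "V",
    MorphologyCode.P: "/",
    MorphologyCode.A: "A",
}


@dataclass(frozen=True)
class SynthSpec:
    """Specification of one synthetic ECG record.

    ``morphology`` is cycled over the beats; ``rr_s`` (explicit RR
    intervals in seconds) overrides ``heart_rate_bpm`` when given.
    ``rr_jitter_fraction`` is the std of multiplicative RR jitter.
    """

    fs: float = 360.0
    duration_s: float = 30.0
    heart_rate_bpm: float = 60.0
    rr_s: tuple[float, ...] | None = None
    morphology: tuple[MorphologyCode, ...] = (MorphologyCode.N,)
    rr_jitter_fraction: float = 0.05
    baseline_wander_mv: float = 0.05
    baseline_wander_hz: float = 0.33
    start_offset_s: float = 0.5
    seed: int = 0
    record_id: str = "synth"

    def __post_init__(self) -> None:
        if not self.fs > 0:
            raise ValueError("fs must be positive")
        if not self.duration_s > 0:
            raise ValueError("duration must be positive")
        if self.rr_s is None and not self.heart_rate_bpm > 0:
            raise ValueError("heart rate must be positive")
        object.__setattr__(
            self, "morphology", tuple(MorphologyCode(m) for m in self.morphology)
        )


_MIN_RR_S = 0.25  # beats may not come closer than the refractory period


def generate_ecg(spec: SynthSpec) -> tuple[EcgRecord, AnnotationSet]:
    """Generate a synthetic record and its exact R-peak ground truth.

    The annotation of each beat is the argmax of the composite signal in
    a +/-40 ms neighbourhood of the nominal R apex, i.e. the true apex
    of the waveform actually written, including bump overlap and
    baseline wander.  Identical seeds give bitwise-identical output.
    """
    rng = np.random.default_rng(spec.seed)
    fs = spec.fs
    n = int(round(spec.duration_s * fs))

    # Beat schedule
    if spec.rr_s is not None:
        rr = np.asarray(spec.rr_s, dtype=float)
    else:
        base = 60.0 / spec.heart_rate_bpm
        n_beats_max = int(np.ceil(spec.duration_s / base)) + 2
        jitter = rng.normal(0.0, spec.rr_jitter_fraction, size=n_beats_max)
        rr = base * (1.0 + np.clip(jitter, -0.4, 0.4))
    if np.any(rr < _MIN_RR_S):
        raise ValueError(
            f"RR interval shorter than the template support ({_MIN_RR_S} s)"
        )
    centers_s = spec.start_offset_s + np.cumsum(np.concatenate(([0.0], rr)))
    centers_s = centers_s[centers_s < spec.duration_s - 0.25]

    x = np.zeros(n)
    t = np.arange(n) / fs
    labels: list[MorphologyCode] = []
    nominal: list[int] = []
    for b, c_s in enumerate(centers_s):
        morph = spec.morphology[b % len(spec.morphology)]
        for amp, off_ms, sigma_ms in BEAT_TEMPLATES[morph]:
            mu = c_s + off_ms / 1000.0
            sigma = sigma_ms / 1000.0
            lo = max(0, int((mu - 5 * sigma) * fs))
            hi = min(n, int((mu + 5 * sigma) * fs) + 1)
            if hi > lo:
                x[lo:hi] += amp * np.exp(-0.5 * ((t[lo:hi] - mu) / sigma) ** 2)
        labels.append(morph)
        nominal.append(int(round(c_s * fs)))

    if spec.baseline_wander_mv > 0:
        phase = rng.uniform(0, 2 * np.pi)
        x += spec.baseline_wander_mv * np.sin(
            2 * np.pi * spec.baseline_wander_hz * t + phase
        )

    half_w = int(round(0.040 * fs))
    positions = []
    for p in nominal:
        lo, hi = max(0, p - half_w), min(n, p + half_w + 1)
        positions.append(lo + int(np.argmax(x[lo:hi])))
    record = EcgRecord(record_id=spec.record_id, fs=fs, samples=x)
    truth = AnnotationSet(
        positions=np.asarray(positions, dtype=np.int64), labels=tuple(labels)
    )
    return record, truth


def generate_muscle_noise(
    fs: float = 360.0,
    duration_s: float = 30.0,
    band_low_hz: float = 20.0,
    band_high_hz: float = 120.0,
    seed: int = 0,
) -> EcgRecord:
    """Band-limited Gaussian noise, zero mean, unit difference power.

    Stands in for a muscle-artifact noise record; the default band
    overlaps the QRS spectrum.  ``band_high_hz`` is capped at 95 % of
    the Nyquist frequency and must stay below it.
    """
    band_high_hz = min(band_high_hz, 0.95 * fs / 2.0)
    if not 0 < band_low_hz < band_high_hz:
        raise ValueError("need 0 < band_low_hz < band_high_hz < fs/2")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs))
    white = rng.standard_normal(n)
    sos = sps.butter(4, [band_low_hz, band_high_hz], btype="bandpass", fs=fs, output="sos")
    x = sps.sosfiltfilt(sos, white)
    x = x - x.mean()
    x = x / np.sqrt(difference_power(x))
    return EcgRecord(record_id="ma_synth", fs=fs, samples=x)


def make_benchmark_fixture(
    out_dir: str | Path,
    specs: Sequence[SynthSpec] | None = None,
    targets_db: Sequence[float] = (15.0, 7.0, 3.0),
    seed: int = 0,
    convention: str = "power",
) -> dict[str, object]:
    """Write a miniature noise-stress database to disk.

    For each record spec: a clean WFDB record (format 16), an MIT-format
    annotation file with the ground-truth beats, and one mixed record
    per target SNR.  A ``manifest.csv`` lists the per-(record, target)
    existing SNR, target SNR and scaling factor k.  Returns the record
    ids, annotation paths and manifest rows.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if specs is None:
        mixes = [
            (MorphologyCode.N,),
            (MorphologyCode.N, MorphologyCode.V, MorphologyCode.N, MorphologyCode.L),
            (MorphologyCode.N, MorphologyCode.A, MorphologyCode.R, MorphologyCode.P),
        ]
        specs = [
            SynthSpec(
                duration_s=30.0,
                morphology=m,
                seed=seed + i,
                record_id=f"rec{i:02d}",
            )
            for i, m in enumerate(mixes)
        ]

    max_dur = max(s.duration_s for s in specs)
    noise = generate_muscle_noise(
        fs=specs[0].fs, duration_s=max_dur, seed=seed + 1000
    )
    write_record(noise, out_dir / "ma_synth.hea")

    records = []
    truths = {}
    for s in specs:
        rec, truth = generate_ecg(s)
        records.append(rec)
        truths[rec.record_id] = truth
        write_record(rec, out_dir / f"{rec.record_id}.hea")
        write_annotations(
            truth.positions,
            [_CODE_TO_WFDB_SYMBOL[l] for l in truth.labels],
            out_dir / f"{rec.record_id}.atr",
        )

    mixed = build_noise_dataset(records, noise, targets_db, convention=convention)
    for rid, per_target in mixed.items():
        for tsnr, mrec in per_target.items():
            write_record(mrec, out_dir / f"{rid}_snr{tsnr:g}.hea")

    manifest = mixing_manifest(records, noise, targets_db, convention=convention)
    with (out_dir / "manifest.csv").open("w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=["record_id", "esnr_db", "tsnr_db", "k"])
        writer.writeheader()
        writer.writerows(manifest)

    return {
        "record_ids": [r.record_id for r in records],
        "targets_db": [float(t) for t in targets_db],
        "truths": truths,
        "manifest": manifest,
        "dir": out_dir,
    }
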
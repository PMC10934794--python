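"""End-to-end benchmark orchestration: mix -> detect -> match -> stratify
-> aggregate -> report.

`run_sweep` executes the full evaluation grid
(algorithms x DTT values x noise levels x morphologies x records) over a
WFDB database directory, writes tidy and summary CSV tables plus a
provenance manifest, and returns the grid in memory.  Noise is mixed
once per (record, target) and every algorithm consumes the identical
mixed record, so detector results are point-by-point comparable.
All outputs are deterministic given the configuration.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

from . import __version__
from .detectors import ALGORITHMS, detect
from .evaluation import (
    DEFAULT_DTT_GRID,
    StratumScore,
    aggregate,
    grid_frame,
    match,
    noise_label,
    per_record_report,
    pooled_tp_tb,
    stratify,
)
from .noise import build_noise_dataset
from .records import MORPHOLOGY_CLASSES, AnnotationSet, EcgRecord, MorphologyCode
from .wfdb_io import read_annotations, read_record

__all__ = ["RunConfig", "run_sweep", "evaluate_records"]


@dataclass(frozen=True)
class RunConfig:
    """Configuration of a full benchmark sweep."""

    db_dir: str
    noise_path: str | None = None
    out_dir: str | None = None
    algorithms: tuple[int, ...] = (1, 2, 3, 4)
    dtt_grid: tuple[int, ...] = DEFAULT_DTT_GRID
    snr_targets_db: tuple[float, ...] = (15.0, 7.0, 3.0)
    morphologies: tuple[MorphologyCode, ...] = MORPHOLOGY_CLASSES
    convention: str = "power"
    channel: int = 0
    algorithm_params: Mapping[int, object] = field(default_factory=dict)
    report_morphology: str = "N"
    seed: int = 0

    def __post_init__(self) -> None:
        if any(d < 1 for d in self.dtt_grid):
            raise ValueError("DTT grid entries must be positive sample counts")
        if len(set(self.snr_targets_db)) != len(self.snr_targets_db):
            raise ValueError("SNR targets must be distinct")
        for a in self.algorithms:
            if a not in ALGORITHMS:
                raise ValueError(f"unknown algorithm id {a}")
        object.__setattr__(
            self, "morphologies", tuple(MorphologyCode(m) for m in self.morphologies)
        )

    def digest(self) -> str:
        payload = json.dumps(
            {
                k: (str(v) if not isinstance(v, (int, float, str, type(None))) else v)
                for k, v in sorted(self.__dict__.items())
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _load_database(config: RunConfig) -> tuple[list[EcgRecord], dict[str, AnnotationSet]]:
    db = Path(config.db_dir)
    records, annotations = [], {}
    for hea in sorted(db.glob("*.hea")):
        atr = hea.with_suffix(".atr")
        if not atr.exists():
            continue  # noise records and mixed variants carry no annotations
        rec = read_record(hea, channel=config.channel)
        records.append(rec)
        annotations[rec.record_id] = read_annotations(atr)
    if not records:
        raise FileNotFoundError(f"no annotated WFDB records found in {db}")
    return records, annotations


def evaluate_records(
    variants: Mapping[str, Mapping[str, EcgRecord]],
    annotations: Mapping[str, AnnotationSet],
    config: RunConfig,
) -> pd.DataFrame:
    """Detect and score every (algorithm, noise variant, DTT, morphology) cell.

    ``variants[record_id][noise_label]`` holds the signal each detector
    consumes.  Returns the tidy evaluation grid.
    """
    scores: list[StratumScore] = []
    for rid, per_noise in variants.items():
        ann = annotations[rid]
        for alg in config.algorithms:
            params = config.algorithm_params.get(alg)
            for label, rec in per_noise.items():
                try:
                    det = detect(rec, alg, params)
                except Exception as exc:  # noqa: BLE001 - abort names the stage
                    raise RuntimeError(
                        f"stage 'detect' (algorithm {alg}) failed for record "
                        f"{rid!r}, noise {label!r}: {exc}"
                    ) from exc
                for dtt in config.dtt_grid:
                    m = match(det, ann, dtt)
                    for morph in config.morphologies:
                        scores.append(
                            stratify(
                                m,
                                ann,
                                morph,
                                algorithm_id=alg,
                                noise=label,
                                record_id=rid,
                            )
                        )
    return grid_frame(scores)


def run_sweep(config: RunConfig) -> pd.DataFrame:
    """Run the full benchmark and (optionally) write report files.

    Writes, under ``config.out_dir``:

    * ``grid.csv`` — the tidy per-record evaluation grid;
    * ``pooled.csv`` — record-pooled TP/TB per stratum;
    * ``summary_by_dtt.csv`` / ``summary_by_morphology.csv`` /
      ``summary_by_noise.csv`` — mean/std summary tables;
    * ``per_record_<alg>_<morph>_dtt<d>.csv`` — per-record TP tables
      with noise deltas, for every algorithm at the two tightest DTTs;
    * ``manifest.json`` — config hash, seed and package version.
    """
    records, annotations = _load_database(config)
    noise_order = ["none"] + [noise_label(t) for t in config.snr_targets_db]

    variants: dict[str, dict[str, EcgRecord]] = {
        rec.record_id: {"none": rec} for rec in records
    }
    if config.snr_targets_db:
        if config.noise_path is None:
            raise ValueError("snr_targets_db set but no noise record given")
        noise = read_record(config.noise_path, channel=0)
        mixed = build_noise_dataset(
            records, noise, config.snr_targets_db, convention=config.convention
        )
        for rid, per_target in mixed.items():
            for tsnr, rec in per_target.items():
                variants[rid][noise_label(tsnr)] = rec

    grid = evaluate_records(variants, annotations, config)

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        fmt = {"float_format": "%.6f", "index": False}
        grid.to_csv(out / "grid.csv", **fmt)
        pooled_tp_tb(grid).to_csv(out / "pooled.csv", **fmt)
        aggregate(grid, ["algorithm", "dtt_samples"], ["morphology", "noise"]).to_csv(
            out / "summary_by_dtt.csv", **fmt
        )
        aggregate(grid, ["algorithm", "morphology"], ["dtt_samples", "noise"]).to_csv(
            out / "summary_by_morphology.csv", **fmt
        )
        aggregate(grid, ["algorithm", "noise"], ["morphology", "dtt_samples"]).to_csv(
            out / "summary_by_noise.csv", **fmt
        )
        morph = config.report_morphology
        for alg in config.algorithms:
            for dtt in sorted(config.dtt_grid)[:2]:
                try:
                    table = per_record_report(grid, alg, morph, dtt, noise_order)
                except ValueError:
                    continue  # morphology absent from this database
                table.to_csv(
                    out / f"per_record_alg{alg}_{morph}_dtt{dtt}.csv", **fmt
                )
        manifest = {
            "config_digest": config.digest(),
            "seed": config.seed,
            "qrsbench_version": __version__,
            "records": sorted(variants),
            "noise_levels": noise_order,
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return grid
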
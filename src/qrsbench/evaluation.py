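"""Tolerance-aware matching of detections against reference annotations,
morphology-stratified scoring, and the aggregation/report layouts.

A detection and an annotation may be paired when their distance is at
most the *detector temporal tolerance* (DTT), a two-sided inclusive
bound in samples.  Matching is maximum-cardinality one-to-one, computed
with a sorted two-pointer sweep (optimal for interval constraints on a
line).  TP/FN/FP and the headline TP/TB ratio follow from the pairing;
stratification by beat morphology only filters the tally — the pairing
itself is always computed against the full annotation set, so a
detection near an excluded-morphology beat cannot be counted elsewhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .records import AnnotationSet, DetectionResult, MorphologyCode

__all__ = [
    "DttSpec",
    "MatchResult",
    "StratumScore",
    "match",
    "stratify",
    "metrics",
    "samples_to_ms",
    "aggregate",
    "per_record_report",
    "noise_label",
    "DEFAULT_DTT_GRID",
]

#: The default DTT sweep grid, in samples at 360 Hz (8.33 ... 163.89 ms).
DEFAULT_DTT_GRID: tuple[int, ...] = (3, 17, 31, 45, 59)


def samples_to_ms(n: int, fs: float) -> float:
    """Convert a sample count to milliseconds at sampling frequency fs."""
    if not fs > 0:
        raise ValueError("fs must be positive")
    return n * 1000.0 / fs


def noise_label(target_snr_db: float | None) -> str:
    """Canonical label for a noise level: 'none' or e.g. '15dB'."""
    return "none" if target_snr_db is None else f"{target_snr_db:g}dB"


@dataclass(frozen=True)
class DttSpec:
    """Detector temporal tolerance: a two-sided bound in samples."""

    tolerance_samples: int
    fs: float = 360.0

    def __post_init__(self) -> None:
        if self.tolerance_samples < 1:
            raise ValueError("tolerance must be >= 1 sample")

    @property
    def tolerance_ms(self) -> float:
        return samples_to_ms(self.tolerance_samples, self.fs)


@dataclass(frozen=True)
class MatchResult:
    """TP/FN/FP counts and the annotation-detection pairing at one DTT."""

    tp: int
    fn: int
    fp: int
    tolerance_samples: int
    pairs: tuple[tuple[int, int, int], ...] = field(default_factory=tuple)
    # pairs entries: (annotation index, detection index, signed offset in samples)

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp) < 0:
            raise ValueError("counts must be nonnegative")
        if len(self.pairs) != self.tp:
            raise ValueError("pair list length must equal TP")
        for _, _, off in self.pairs:
            if abs(off) > self.tolerance_samples:
                raise ValueError("pair offset exceeds the tolerance")


def match(
    detections: DetectionResult | np.ndarray,
    annotations: AnnotationSet | np.ndarray,
    dtt: DttSpec | int,
) -> MatchResult:
    """Maximum one-to-one pairing under ``|detection - annotation| <= DTT``.

    Both inputs must be strictly sorted.  Ties are broken toward the
    earlier detection.  Unmatched annotations are FN, unmatched
    detections FP.
    """
    det = detections.positions if isinstance(detections, DetectionResult) else np.asarray(detections, dtype=np.int64)
    ann = annotations.positions if isinstance(annotations, AnnotationSet) else np.asarray(annotations, dtype=np.int64)
    tol = dtt.tolerance_samples if isinstance(dtt, DttSpec) else int(dtt)
    for name, arr in (("detections", det), ("annotations", ann)):
        if arr.size and np.any(np.diff(arr) <= 0):
            raise ValueError(f"{name} must be strictly sorted")

    pairs: list[tuple[int, int, int]] = []
    i = j = 0
    while i < ann.size and j < det.size:
        offset = int(det[j] - ann[i])
        if abs(offset) <= tol:
            pairs.append((i, j, offset))
            i += 1
            j += 1
        elif det[j] < ann[i]:
            j += 1
        else:
            i += 1
    tp = len(pairs)
    return MatchResult(
        tp=tp,
        fn=int(ann.size) - tp,
        fp=int(det.size) - tp,
        tolerance_samples=tol,
        pairs=tuple(pairs),
    )


@dataclass(frozen=True)
class StratumScore:
    """TP/TB tally for one cell of the evaluation grid."""

    algorithm_id: int
    dtt_samples: int
    noise: str
    morphology: MorphologyCode
    record_id: str
    tb: int
    tp: int

    def __post_init__(self) -> None:
        if self.tb < 0 or self.tp < 0 or self.tp > max(self.tb, 0):
            raise ValueError(f"need 0 <= tp <= tb, got tp={self.tp}, tb={self.tb}")

    @property
    def tp_tb(self) -> float | None:
        """TP/TB in percent; None (excluded) when the stratum is empty."""
        return 100.0 * self.tp / self.tb if self.tb > 0 else None


def stratify(
    match_result: MatchResult,
    annotations: AnnotationSet,
    morphology: MorphologyCode,
    *,
    algorithm_id: int = 0,
    noise: str = "none",
    record_id: str = "",
) -> StratumScore:
    """Restrict a match tally to one morphology class.

    TB counts the annotations carrying the label; TP counts matched
    pairs whose *annotation* carries the label.  The matching itself was
    performed against the full annotation set.
    """
    morphology = MorphologyCode(morphology)
    mask = annotations.label_mask(morphology)
    tb = int(mask.sum())
    tp = sum(1 for ai, _, _ in match_result.pairs if mask[ai])
    return StratumScore(
        algorithm_id=algorithm_id,
        dtt_samples=match_result.tolerance_samples,
        noise=noise,
        morphology=morphology,
        record_id=record_id,
        tb=tb,
        tp=tp,
    )


def metrics(tp: int, fn: int, fp: int, tb: int) -> dict[str, float | None]:
    """Binary-classification metrics; zero denominators yield None.

    Se, PPV, F1 and TP_TB are percentages; DER is a plain ratio.
    """
    if min(tp, fn, fp, tb) < 0:
        raise ValueError("inputs must be nonnegative")
    se = 100.0 * tp / (tp + fn) if tp + fn else None
    ppv = 100.0 * tp / (tp + fp) if tp + fp else None
    f1 = 2.0 * ppv * se / (se + ppv) if se and ppv else (0.0 if se is not None and ppv is not None else None)
    der = (fn + fp) / tb if tb else None
    tp_tb = 100.0 * tp / tb if tb else None
    return {"Se": se, "PPV": ppv, "F1": f1, "DER": der, "TP_TB": tp_tb}


# ---------------------------------------------------------------------------
# Grid aggregation (summary-table and per-record layouts)

_GRID_COLUMNS = ["algorithm", "dtt_samples", "noise", "morphology", "record_id", "tb", "tp"]


def grid_frame(scores: list[StratumScore]) -> pd.DataFrame:
    """Assemble StratumScores into the tidy evaluation-grid DataFrame."""
    rows = [
        {
            "algorithm": s.algorithm_id,
            "dtt_samples": s.dtt_samples,
            "noise": s.noise,
            "morphology": s.morphology.value,
            "record_id": s.record_id,
            "tb": s.tb,
            "tp": s.tp,
        }
        for s in scores
    ]
    return pd.DataFrame(rows, columns=_GRID_COLUMNS)


def pooled_tp_tb(grid: pd.DataFrame) -> pd.DataFrame:
    """Sum tb/tp over records and attach the pooled TP/TB percentage."""
    pooled = (
        grid.groupby(["algorithm", "dtt_samples", "noise", "morphology"], as_index=False)[["tb", "tp"]]
        .sum()
    )
    pooled = pooled[pooled["tb"] > 0].copy()
    pooled["tp_tb"] = 100.0 * pooled["tp"] / pooled["tb"]
    return pooled


def aggregate(
    grid: pd.DataFrame,
    fixed_axes: list[str],
    summarized_axes: list[str],
) -> pd.DataFrame:
    """Mean and population std of pooled TP/TB over the summarized axes.

    For each cell of the fixed axes, the TP/TB values entering the
    statistics are the record-pooled percentages of every combination of
    the summarized axes (e.g. fixing (algorithm, dtt) and summarizing
    morphology x noise pools each of the 6 x 4 = 24 strata over records
    first).  Raises if a fixed cell is missing any summarized
    combination that appears elsewhere in the grid.
    """
    pooled = pooled_tp_tb(grid)
    for ax in fixed_axes + summarized_axes:
        if ax not in pooled.columns:
            raise ValueError(f"unknown axis {ax!r}")
    expected = {
        ax: sorted(pooled[ax].unique()) for ax in summarized_axes
    }
    n_expected = int(np.prod([len(v) for v in expected.values()]))
    out_rows = []
    for keys, cell in pooled.groupby(fixed_axes):
        if not isinstance(keys, tuple):
            keys = (keys,)
        combos = cell.set_index(summarized_axes).index.unique()
        if len(combos) < n_expected:
            have = set(map(tuple, np.atleast_2d(np.array(list(combos), dtype=object))))
            missing = [
                c
                for c in _cross(expected)
                if c not in have
            ]
            raise ValueError(
                f"grid cell {dict(zip(fixed_axes, keys))} is missing strata: {missing}"
            )
        values = cell["tp_tb"].to_numpy()
        out_rows.append(
            dict(zip(fixed_axes, keys))
            | {"mean": float(values.mean()), "std": float(values.std(ddof=0)), "n": values.size}
        )
    return pd.DataFrame(out_rows)


def _cross(expected: dict[str, list]) -> list[tuple]:
    combos: list[tuple] = [()]
    for values in expected.values():
        combos = [c + (v,) for c in combos for v in values]
    return combos


def per_record_report(
    grid: pd.DataFrame,
    algorithm: int,
    morphology: MorphologyCode | str,
    dtt_samples: int,
    noise_order: list[str] = ("none", "15dB", "7dB", "3dB"),
) -> pd.DataFrame:
    """Per-record TP table at one (algorithm, morphology, DTT) cell.

    One row per record with TB and TP at each noise level, TP deltas
    versus the no-added-noise column, a flag marking improvements
    (positive deltas), and a TOTAL row summing every count column.
    Records with no beats of the morphology are omitted.
    """
    morphology = MorphologyCode(morphology).value
    sel = grid[
        (grid["algorithm"] == algorithm)
        & (grid["morphology"] == morphology)
        & (grid["dtt_samples"] == dtt_samples)
    ]
    if sel.empty:
        raise ValueError(
            f"grid has no entries for algorithm={algorithm}, "
            f"morphology={morphology}, dtt={dtt_samples}"
        )
    present = set(sel["noise"].unique())
    missing = [lvl for lvl in noise_order if lvl not in present]
    if missing:
        raise ValueError(f"grid lacks noise levels {missing}")
    base = noise_order[0]
    pivot = sel.pivot_table(index="record_id", columns="noise", values="tp", aggfunc="sum")
    tb = sel.groupby("record_id")["tb"].max()
    table = pd.DataFrame({"TB": tb})
    for lvl in noise_order:
        table[f"TP_{lvl}"] = pivot[lvl]
    table = table[table["TB"] > 0]
    for lvl in noise_order[1:]:
        table[f"delta_{lvl}"] = table[f"TP_{lvl}"] - table[f"TP_{base}"]
    table["improved"] = (table[[f"delta_{lvl}" for lvl in noise_order[1:]]] > 0).any(axis=1)
    total = table.drop(columns="improved").sum()
    table.loc["TOTAL"] = total
    table.loc["TOTAL", "improved"] = bool(
        (table.loc["TOTAL", [f"delta_{lvl}" for lvl in noise_order[1:]]] > 0).any()
    )
    int_cols = [c for c in table.columns if c != "improved"]
    table[int_cols] = table[int_cols].astype(int)
    return table.reset_index().rename(columns={"index": "record_id"})
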
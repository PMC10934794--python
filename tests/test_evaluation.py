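import numpy as np
import pytest
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import maximum_bipartite_matching

from qrsbench.evaluation import (
    DttSpec,
    StratumScore,
    aggregate,
    grid_frame,
    match,
    metrics,
    per_record_report,
    pooled_tp_tb,
    samples_to_ms,
    stratify,
)
from qrsbench.records import AnnotationSet, MorphologyCode


def _brute_force_tp(ann, det, tol):
    """Maximum bipartite matching via scipy as an independent oracle."""
    if len(ann) == 0 or len(det) == 0:
        return 0
    adj = np.abs(np.subtract.outer(ann, det)) <= tol
    m = maximum_bipartite_matching(csr_matrix(adj), perm_type="column")
    return int(np.sum(m >= 0))


def _random_instance(rng, max_points=12, span=300):
    ann = np.unique(rng.integers(0, span, rng.integers(0, max_points + 1)))
    det = np.unique(rng.integers(0, span, rng.integers(0, max_points + 1)))
    return ann.astype(np.int64), det.astype(np.int64)


class TestMatch:
    def test_identical_sequences(self):
        ann = np.array([10, 100, 200])
        m = match(ann, ann, 3)
        assert (m.tp, m.fn, m.fp) == (3, 0, 0)

    def test_all_shifted_past_tolerance(self):
        ann = np.array([100, 200, 300])
        m = match(ann + 4, ann, 3)
        assert (m.tp, m.fn, m.fp) == (0, 3, 3)

    def test_matches_bruteforce_on_random_instances(self):
        rng = np.random.default_rng(2024)
        for _ in range(200):
            ann, det = _random_instance(rng)
            tol = int(rng.integers(1, 30))
            m = match(det, ann, tol)
            assert m.tp == _brute_force_tp(ann, det, tol)

    def test_conservation(self):
        rng = np.random.default_rng(99)
        for _ in range(100):
            ann, det = _random_instance(rng, max_points=30, span=2000)
            m = match(det, ann, int(rng.integers(1, 60)))
            assert m.tp + m.fn == len(ann)
            assert m.tp + m.fp == len(det)
            assert all(abs(off) <= m.tolerance_samples for *_, off in m.pairs)
            # one-to-one pairing
            assert len({a for a, _, _ in m.pairs}) == m.tp
            assert len({d for _, d, _ in m.pairs}) == m.tp

    def test_tp_monotone_in_tolerance(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            ann, det = _random_instance(rng, max_points=25, span=3000)
            tps = [match(det, ann, tol).tp for tol in (3, 17, 31, 45, 59)]
            assert tps == sorted(tps)

    def test_fn_fp_convert_to_tp_when_tolerance_admits_pair(self):
        """Raising DTT so one more pair fits trades an FN+FP for a TP."""
        ann = np.array([100, 500])
        det = np.array([104, 530])  # second pair is 30 samples apart
        tight = match(det, ann, 17)
        loose = match(det, ann, 31)
        assert (tight.tp, tight.fn, tight.fp) == (1, 1, 1)
        assert (loose.tp, loose.fn, loose.fp) == (2, 0, 0)

    def test_unsorted_input_rejected(self):
        with pytest.raises(ValueError, match="sorted"):
            match(np.array([5, 3]), np.array([1, 2]), 3)


class TestStratify:
    def _annotations(self):
        return AnnotationSet(
            positions=np.array([10, 100, 200, 300]),
            labels=(
                MorphologyCode.N,
                MorphologyCode.V,
                MorphologyCode.N,
                MorphologyCode.A,
            ),
        )

    def test_perfect_match_single_label(self):
        ann = AnnotationSet(np.array([10, 50]), (MorphologyCode.N, MorphologyCode.N))
        s = stratify(match(ann.positions, ann, 3), ann, MorphologyCode.N)
        assert s.tp_tb == 100.0

    def test_absent_label_stratum_excluded(self):
        ann = self._annotations()
        s = stratify(match(ann.positions, ann, 3), ann, MorphologyCode.P)
        assert s.tb == 0 and s.tp_tb is None

    def test_hand_counted_hit_pattern(self):
        ann = self._annotations()
        det = np.array([11, 205, 290])  # hits N@10, N@200, A@300; misses V@100
        m = match(det, ann, 17)
        assert stratify(m, ann, MorphologyCode.N).tp == 2
        assert stratify(m, ann, MorphologyCode.V).tp == 0
        assert stratify(m, ann, MorphologyCode.A).tp == 1
        assert stratify(m, ann, MorphologyCode.N).tb == 2


class TestMetrics:
    def test_closed_form_example(self):
        out = metrics(tp=9, fn=1, fp=1, tb=10)
        assert out["Se"] == pytest.approx(90.0)
        assert out["PPV"] == pytest.approx(90.0)
        assert out["F1"] == pytest.approx(90.0)
        assert out["DER"] == pytest.approx(0.2)

    def test_perfect_detection(self):
        out = metrics(tp=10, fn=0, fp=0, tb=10)
        assert out["Se"] == out["PPV"] == out["F1"] == out["TP_TB"] == 100.0
        assert out["DER"] == 0.0

    def test_zero_denominators_are_none_not_errors(self):
        out = metrics(tp=0, fn=0, fp=0, tb=0)
        assert all(v is None for v in out.values())

    def test_f1_harmonic_identity(self):
        rng = np.random.default_rng(8)
        for _ in range(50):
            tp, fn, fp = rng.integers(1, 100, 3)
            out = metrics(int(tp), int(fn), int(fp), int(tp + fn))
            se, ppv = out["Se"], out["PPV"]
            assert out["F1"] == pytest.approx(2 * se * ppv / (se + ppv))


def test_samples_to_ms_grid_endpoints():
    assert samples_to_ms(3, 360) == pytest.approx(8.33, abs=0.005)
    assert samples_to_ms(59, 360) == pytest.approx(163.89, abs=0.005)
    assert samples_to_ms(0, 360) == 0.0
    assert DttSpec(17).tolerance_ms == pytest.approx(47.22, abs=0.005)


def _make_grid(values):
    """values: dict (alg, dtt, noise, morph, record) -> (tb, tp)."""
    scores = [
        StratumScore(
            algorithm_id=a, dtt_samples=d, noise=nz,
            morphology=MorphologyCode(mo), record_id=r, tb=tb, tp=tp,
        )
        for (a, d, nz, mo, r), (tb, tp) in values.items()
    ]
    return grid_frame(scores)


class TestAggregate:
    def test_uniform_grid_mean_100_std_0(self):
        values = {
            (1, 3, nz, mo, "r"): (10, 10)
            for nz in ("none", "15dB")
            for mo in ("N", "V")
        }
        out = aggregate(_make_grid(values), ["algorithm", "dtt_samples"], ["noise", "morphology"])
        assert out.loc[0, "mean"] == 100.0 and out.loc[0, "std"] == 0.0

    def test_population_std_convention(self):
        values = {
            (1, 3, "none", "N", "r"): (10, 0),
            (1, 3, "none", "V", "r"): (10, 10),
        }
        out = aggregate(_make_grid(values), ["algorithm"], ["morphology"])
        assert out.loc[0, "mean"] == 50.0
        assert out.loc[0, "std"] == 50.0  # divide-by-n, not n-1

    def test_matches_flat_recomputation(self):
        rng = np.random.default_rng(13)
        values = {}
        for d in (3, 17):
            for nz in ("none", "7dB"):
                for mo in ("N", "V", "A"):
                    for r in ("a", "b"):
                        tb = int(rng.integers(5, 50))
                        values[(1, d, nz, mo, r)] = (tb, int(rng.integers(0, tb + 1)))
        grid = _make_grid(values)
        out = aggregate(grid, ["algorithm", "dtt_samples"], ["morphology", "noise"])
        pooled = pooled_tp_tb(grid)
        for _, row in out.iterrows():
            flat = pooled[pooled["dtt_samples"] == row["dtt_samples"]]["tp_tb"].to_numpy()
            assert row["mean"] == pytest.approx(flat.mean())
            assert row["std"] == pytest.approx(flat.std(ddof=0))

    def test_missing_cell_reported(self):
        values = {
            (1, 3, "none", "N", "r"): (10, 5),
            (1, 3, "7dB", "V", "r"): (10, 5),  # N@7dB and V@none missing
        }
        with pytest.raises(ValueError, match="missing strata"):
            aggregate(_make_grid(values), ["algorithm"], ["morphology", "noise"])


class TestPerRecordReport:
    NOISE = ("none", "15dB", "7dB", "3dB")

    def _grid(self, tp_by_record):
        values = {}
        for r, tps in tp_by_record.items():
            for nz, tp in zip(self.NOISE, tps):
                values[(1, 3, nz, "N", r)] = (20, tp)
        return _make_grid(values)

    def test_constant_tp_gives_zero_deltas(self):
        table = per_record_report(self._grid({"a": (5, 5, 5, 5)}), 1, "N", 3, list(self.NOISE))
        row = table[table["record_id"] == "a"].iloc[0]
        assert all(row[f"delta_{nz}"] == 0 for nz in self.NOISE[1:])
        assert not row["improved"]

    def test_total_row_sums_columns(self):
        table = per_record_report(
            self._grid({"a": (5, 6, 7, 8), "b": (10, 9, 8, 7)}), 1, "N", 3, list(self.NOISE)
        )
        total = table[table["record_id"] == "TOTAL"].iloc[0]
        assert total["TB"] == 40
        assert total["TP_none"] == 15 and total["TP_3dB"] == 15

    def test_improving_record_flagged(self):
        table = per_record_report(
            self._grid({"up": (5, 9, 9, 9), "down": (9, 5, 5, 5)}), 1, "N", 3, list(self.NOISE)
        )
        by_id = table.set_index("record_id")
        assert bool(by_id.loc["up", "improved"])
        assert not bool(by_id.loc["down", "improved"])
        assert by_id.loc["up", "delta_15dB"] == 4
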
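import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from qrsbench.noise import (
    build_noise_dataset,
    difference_power,
    mix,
    relative_snr,
    scaling_factor,
)
from qrsbench.records import EcgRecord

finite_arrays = st.lists(
    st.floats(min_value=-100, max_value=100, allow_nan=False), min_size=2, max_size=50
).map(np.array)


class TestDifferencePower:
    def test_constant_sequence_is_zero(self):
        assert difference_power(np.full(17, 3.2)) == 0.0

    def test_alternating_unit_steps(self):
        assert difference_power([0, 1, 0, 1, 0]) == pytest.approx(1.0)

    def test_matches_direct_summation_oracle(self):
        t = np.arange(1000) / 360.0
        x = np.sin(2 * np.pi * 5 * t)
        brute = sum((x[i + 1] - x[i]) ** 2 for i in range(len(x) - 1)) / (len(x) - 1)
        assert difference_power(x) == pytest.approx(brute, abs=1e-12)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            difference_power([1.0])

    @settings(max_examples=100, deadline=None)
    @given(x=finite_arrays, offset=st.floats(-50, 50), scale=st.floats(0.1, 10))
    def test_offset_invariance_and_quadratic_scaling(self, x, offset, scale):
        p = difference_power(x)
        assert difference_power(x + offset) == pytest.approx(p, rel=1e-9, abs=1e-9)
        assert difference_power(scale * x) == pytest.approx(
            scale**2 * p, rel=1e-9, abs=1e-9
        )


class TestRelativeSnr:
    def test_equal_powers_zero_db(self):
        assert relative_snr(2.5, 2.5, "printed-20log") == 0.0
        assert relative_snr(2.5, 2.5, "power-10log") == 0.0

    def test_closed_forms(self):
        assert relative_snr(10.0, 1.0, "printed-20log") == pytest.approx(20.0)
        assert relative_snr(100.0, 1.0, "power-10log") == pytest.approx(20.0)

    def test_antisymmetry(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            ps, pn = rng.uniform(0.01, 10, 2)
            assert relative_snr(ps, pn) == pytest.approx(-relative_snr(pn, ps))

    def test_nonpositive_power_rejected(self):
        with pytest.raises(ValueError):
            relative_snr(0.0, 1.0)


class TestScalingFactor:
    def test_identity_in_both_conventions(self):
        assert scaling_factor(9.0, 9.0, "printed").k == pytest.approx(1.0)
        assert scaling_factor(9.0, 9.0, "power").k == pytest.approx(1.0)

    def test_printed_formula_literal(self):
        assert scaling_factor(12.0, 3.0, "printed").k == pytest.approx(0.5)

    def test_printed_rejects_nonpositive_db(self):
        with pytest.raises(ValueError, match="printed"):
            scaling_factor(-3.0, 3.0, "printed")

    def test_power_mode_closed_form_and_numeric_solve(self):
        spec = scaling_factor(23.0, 3.0, "power", "printed-20log")
        assert spec.k == pytest.approx(10**0.5, rel=1e-12)
        # independent check: bisect k so the scaled noise hits the target
        ps, pn = 4.0, 4.0 / 10 ** (23.0 / 20.0)  # gives eSNR = 23 dB
        lo, hi = 1e-6, 1e6
        for _ in range(200):
            mid = np.sqrt(lo * hi)
            if relative_snr(ps, mid**2 * pn) > 3.0:
                lo = mid
            else:
                hi = mid
        assert spec.k == pytest.approx(lo, rel=1e-9)

    @settings(max_examples=50, deadline=None)
    @given(esnr=st.floats(-20, 40), tsnr=st.floats(-20, 40))
    def test_power_mode_achieves_target_exactly(self, esnr, tsnr):
        ps = 1.7
        pn = ps / 10 ** (esnr / 20.0)
        k = scaling_factor(esnr, tsnr, "power", "printed-20log").k
        assert relative_snr(ps, k**2 * pn) == pytest.approx(tsnr, abs=1e-9)


class TestMix:
    def test_zero_scaling_is_identity(self):
        ecg = EcgRecord("r", 360.0, np.array([1.0, 2.0, 3.0]))
        np.testing.assert_array_equal(mix(ecg, np.array([9.0, 9.0, 9.0]), 0.0).samples, ecg.samples)

    def test_elementwise_addition(self):
        ecg = EcgRecord("r", 360.0, np.array([1.0, 2.0]))
        np.testing.assert_array_equal(mix(ecg, np.array([1.0, 1.0]), 2.0).samples, [3.0, 4.0])

    def test_fs_mismatch_rejected(self):
        ecg = EcgRecord("r", 360.0, np.array([1.0, 2.0]))
        noise = EcgRecord("n", 250.0, np.array([1.0, 2.0]))
        with pytest.raises(ValueError, match="fs"):
            mix(ecg, noise, 1.0)

    def test_short_noise_is_tiled(self):
        ecg = EcgRecord("r", 360.0, np.zeros(5))
        out = mix(ecg, np.array([1.0, 2.0]), 1.0)
        np.testing.assert_array_equal(out.samples, [1, 2, 1, 2, 1])

    def test_linearity(self):
        rng = np.random.default_rng(5)
        ecg = EcgRecord("r", 360.0, rng.normal(size=100))
        noise = rng.normal(size=100)
        lhs = mix(ecg, noise, 0.3).samples + (1.1 - 0.3) * noise
        rhs = mix(ecg, noise, 1.1).samples
        np.testing.assert_allclose(lhs, rhs, atol=1e-12)

    def test_round_trip_snr_at_7db(self):
        """Power-consistent mixing reproduces the target SNR to < 0.01 dB."""
        rng = np.random.default_rng(11)
        t = np.arange(7200) / 360.0
        clean = np.sin(2 * np.pi * 8 * t)
        noise = rng.normal(0, 0.5, clean.size)
        esnr = relative_snr(difference_power(clean), difference_power(noise))
        k = scaling_factor(esnr, 7.0, "power").k
        achieved = relative_snr(
            difference_power(clean), difference_power(k * noise)
        )
        assert achieved == pytest.approx(7.0, abs=0.01)


class TestBuildNoiseDataset:
    def _inputs(self):
        rng = np.random.default_rng(2)
        t = np.arange(3600) / 360.0
        recs = [
            EcgRecord("a", 360.0, np.sin(2 * np.pi * 6 * t)),
            EcgRecord("b", 360.0, 0.4 * np.sin(2 * np.pi * 6 * t)),
        ]
        noise = EcgRecord("n", 360.0, rng.normal(0, 0.1, t.size))
        return recs, noise

    def test_noise_amplitude_grows_as_target_drops(self):
        recs, noise = self._inputs()
        out = build_noise_dataset(recs[:1], noise, [15.0, 7.0, 3.0], convention="power")
        powers = [
            difference_power(out["a"][t].samples - recs[0].samples)
            for t in (15.0, 7.0, 3.0)
        ]
        assert powers[0] < powers[1] < powers[2]

    def test_empty_targets_rejected(self):
        recs, noise = self._inputs()
        with pytest.raises(ValueError):
            build_noise_dataset(recs, noise, [])

    def test_per_record_scaling(self):
        """Records with different signal power get different k for one target."""
        recs, noise = self._inputs()
        out = build_noise_dataset(recs, noise, [7.0], convention="power")
        k_a = np.max(np.abs(out["a"][7.0].samples - recs[0].samples)) / np.max(np.abs(noise.samples))
        k_b = np.max(np.abs(out["b"][7.0].samples - recs[1].samples)) / np.max(np.abs(noise.samples))
        # independently recompute each record's k from its own eSNR
        pn = difference_power(noise.samples)
        for rec, k_obs in ((recs[0], k_a), (recs[1], k_b)):
            esnr = relative_snr(difference_power(rec.samples), pn)
            assert k_obs == pytest.approx(scaling_factor(esnr, 7.0, "power").k, rel=1e-6)
        assert k_a != pytest.approx(k_b)
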
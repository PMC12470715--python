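"""Unit-dose response kernel and superposition of dose waveforms."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

import vasosim as vs
from vasosim.kernel import DeltaBPTrace, DoseSchedule

from conftest import brute_force_superpose

# direct evaluation of the piecewise reference formula (linear rise to the
# peak, exponential decay reaching 5% of peak at the support edge), frozen
# for t_peak=3, t_support=12, peak_effect=0.8
FROZEN_KERNEL_3_12_08 = [
    0.0, 0.266666666667, 0.533333333333, 0.8,
    0.57349693155, 0.411123413121, 0.294722519891, 0.21127807602,
    0.151459160377, 0.108576704664, 0.077835508703, 0.055798031758, 0.04,
]


class TestMakeReferenceKernel:
    def test_boundary_and_peak(self):
        k = vs.make_reference_kernel(t_peak=2, t_support=10, peak_effect=1.0)
        assert k.values[0] == 0.0
        assert k.values[2] == 1.0
        assert k.effect_at(11) == 0.0
        assert k.t_peak == 2 and k.t_support == 10

    def test_minimal_support(self):
        k = vs.make_reference_kernel(t_peak=1, t_support=1, peak_effect=5.0)
        assert np.array_equal(k.values, [0.0, 5.0])
        assert k.effect_at(2) == 0.0

    def test_matches_direct_formula_evaluation(self):
        k = vs.make_reference_kernel(t_peak=3, t_support=12, peak_effect=0.8)
        np.testing.assert_allclose(k.values, FROZEN_KERNEL_3_12_08, atol=1e-11)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(t_peak=0, t_support=10),
            dict(t_peak=3, t_support=2),
            dict(t_peak=2.5, t_support=10),
            dict(t_peak=2, t_support=10, peak_effect=0.0),
            dict(t_peak=2, t_support=10, peak_effect=-1.0),
            dict(t_peak=2, t_support=10, tail_fraction=1.0),
        ],
    )
    def test_rejects_bad_parameters(self, kwargs):
        with pytest.raises(ValueError):
            vs.make_reference_kernel(**kwargs)

    def test_deterministic(self):
        a = vs.make_reference_kernel()
        b = vs.make_reference_kernel()
        assert np.array_equal(a.values, b.values)


class TestResponseKernelType:
    def test_rejects_negative_values(self):
        with pytest.raises(ValueError):
            vs.ResponseKernel(values=np.array([0.0, -0.1, 0.2]))

    def test_rejects_bimodal(self):
        with pytest.raises(ValueError, match="unimodal"):
            vs.ResponseKernel(values=np.array([0.0, 1.0, 0.5, 1.0]))

    def test_csv_round_trip(self, ref_kernel, tmp_path):
        p = tmp_path / "kernel.csv"
        ref_kernel.to_csv(p)
        back = vs.ResponseKernel.from_csv(p)
        np.testing.assert_array_equal(back.values, ref_kernel.values)

    def test_csv_rejects_gap(self, tmp_path):
        p = tmp_path / "kernel.csv"
        p.write_text("minute,mmHg_per_mg\n0,0.0\n2,0.4\n")
        with pytest.raises(ValueError, match="contiguous"):
            vs.ResponseKernel.from_csv(p)


class TestBolusResponse:
    def test_zero_dose_is_zero(self, ref_kernel):
        for t in range(15):
            assert vs.bolus_response(ref_kernel, 0.0, t) == 0.0

    def test_half_dose_halves_the_waveform(self, ref_kernel):
        # linear dose-response: half the dose gives half the effect at every t
        for t in range(ref_kernel.t_support + 2):
            full = vs.bolus_response(ref_kernel, 10.0, t)
            half = vs.bolus_response(ref_kernel, 5.0, t)
            assert half == pytest.approx(full / 2.0, abs=0.0)

    def test_linearity_at_peak(self, ref_kernel):
        got = vs.bolus_response(ref_kernel, 2.0, ref_kernel.t_peak)
        assert got == 2.0 * ref_kernel.values[ref_kernel.t_peak]

    def test_rejects_negative_dose_or_time(self, ref_kernel):
        with pytest.raises(ValueError):
            vs.bolus_response(ref_kernel, -1.0, 0)
        with pytest.raises(ValueError):
            vs.bolus_response(ref_kernel, 1.0, -1)


def _random_schedule(rng, duration):
    n = duration + 1
    return DoseSchedule(
        bolus=rng.uniform(0, 20, size=n) * (rng.random(n) < 0.3),
        infusion=rng.uniform(0, 2, size=n),
    )


class TestSuperpose:
    def test_constant_infusion_sums_waveforms(self, ref_kernel):
        # minute 4 of a constant infusion is the sum of five unit waveforms
        C = 0.7
        sched = DoseSchedule(bolus=np.zeros(21), infusion=np.full(21, C))
        trace = vs.superpose(ref_kernel, sched, duration=20)
        expected = C * sum(ref_kernel.effect_at(k) for k in range(5))
        assert trace.values[4] == pytest.approx(expected, rel=1e-15)

    def test_all_zero_schedule(self, ref_kernel):
        trace = vs.superpose(ref_kernel, DoseSchedule.zeros(20))
        assert np.array_equal(trace.values, np.zeros(21))

    def test_matches_brute_force_oracle(self, ref_kernel, rng):
        for _ in range(20):
            sched = _random_schedule(rng, 20)
            got = vs.superpose(ref_kernel, sched, duration=20).values
            want = brute_force_superpose(ref_kernel, sched, 20)
            np.testing.assert_allclose(got, want, rtol=1e-12, atol=1e-12)

    def test_rejects_short_schedule(self, ref_kernel):
        with pytest.raises(ValueError):
            vs.superpose(ref_kernel, DoseSchedule.zeros(5), duration=10)

    def test_single_bolus_shift_invariance(self, ref_kernel):
        # a bolus M at minute s reproduces M * f(t - s) exactly
        M, s, duration = 7.5, 6, 25
        sched = DoseSchedule.zeros(duration)
        sched.bolus[s] = M
        trace = vs.superpose(ref_kernel, sched, duration=duration)
        for t in range(duration + 1):
            expected = M * ref_kernel.effect_at(t - s) if t >= s else 0.0
            assert trace.values[t] == pytest.approx(expected, abs=1e-14)

    @given(alpha=st.floats(0, 10, allow_nan=False), seed=st.integers(0, 2**20))
    def test_linearity_in_schedule(self, ref_kernel, alpha, seed):
        sched = _random_schedule(np.random.default_rng(seed), 15)
        base = vs.superpose(ref_kernel, sched).values
        scaled = vs.superpose(ref_kernel, sched.scaled(alpha)).values
        np.testing.assert_allclose(scaled, alpha * base, rtol=1e-12, atol=1e-12)

    @given(seed=st.integers(0, 2**20))
    def test_additivity(self, ref_kernel, seed):
        rng = np.random.default_rng(seed)
        s1, s2 = _random_schedule(rng, 15), _random_schedule(rng, 15)
        lhs = vs.superpose(ref_kernel, s1 + s2).values
        rhs = vs.superpose(ref_kernel, s1).values + vs.superpose(ref_kernel, s2).values
        np.testing.assert_allclose(lhs, rhs, rtol=1e-12, atol=1e-12)

    def test_causality(self, ref_kernel, rng):
        # perturbing a future dose leaves earlier minutes unchanged
        sched = _random_schedule(rng, 20)
        t_cut = 9
        perturbed = DoseSchedule(
            bolus=sched.bolus.copy(), infusion=sched.infusion.copy()
        )
        perturbed.bolus[t_cut + 1] += 100.0
        a = vs.superpose(ref_kernel, sched).values
        b = vs.superpose(ref_kernel, perturbed).values
        np.testing.assert_array_equal(a[: t_cut + 1], b[: t_cut + 1])
        assert not np.array_equal(a, b)


class TestEffectNoise:
    def test_zero_range_is_identity(self, ref_kernel):
        trace = DeltaBPTrace(values=np.linspace(0, 10, 11))
        out = vs.apply_effect_noise(trace, 0.0, 1)
        np.testing.assert_array_equal(out.values, trace.values)

    def test_bounded_multiplicative(self):
        trace = DeltaBPTrace(values=np.full(200, 10.0))
        out = vs.apply_effect_noise(trace, 0.05, 7)
        assert np.all(out.values >= 9.5) and np.all(out.values <= 10.5)
        assert not np.allclose(out.values, 10.0)

    def test_reproducible_per_seed(self):
        trace = DeltaBPTrace(values=np.arange(50, dtype=float))
        a = vs.apply_effect_noise(trace, 0.05, 42)
        b = vs.apply_effect_noise(trace, 0.05, 42)
        np.testing.assert_array_equal(a.values, b.values)

    def test_rejects_out_of_range(self):
        trace = DeltaBPTrace(values=np.ones(3))
        with pytest.raises(ValueError):
            vs.apply_effect_noise(trace, 1.0, 0)


class TestDoseSchedule:
    def test_rejects_negative_entries(self):
        with pytest.raises(ValueError):
            DoseSchedule(bolus=np.array([-1.0]), infusion=np.array([0.0]))

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError):
            DoseSchedule(bolus=np.array([np.inf]), infusion=np.array([0.0]))

    def test_rejects_length_mismatch(self):
        with pytest.raises(ValueError):
            DoseSchedule(bolus=np.zeros(3), infusion=np.zeros(4))
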
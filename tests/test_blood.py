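"""Arterial input construction: fwb, parent fraction, fp, and assembly."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from petquant.blood import (
    BloodDataset,
    ExtrapolationError,
    ParentFractionFit,
    assemble_aif,
    build_fp,
    estimate_fwb,
    eval_parent_fraction,
    fit_parent_fraction,
    whole_blood_interpolator,
)
from petquant.synthetic import generate_input_profile

# Group-mean parent fractions at the five metabolite sampling times.
PPF_TIMES = np.array([2.0, 10.0, 30.0, 90.0, 205.0])
PPF_MEANS = np.array([0.9940, 0.9740, 0.9620, 0.9540, 0.9530])


def _dataset(wb_t, wb_c, p_t=None, p_c=None):
    return BloodDataset(
        wb_time=np.asarray(wb_t, float),
        wb_activity=np.asarray(wb_c, float),
        plasma_time=np.asarray(p_t if p_t is not None else [], float),
        plasma_activity=np.asarray(p_c if p_c is not None else [], float),
    )


class TestEstimateFwb:
    def test_published_per_subject_means_average_to_1_79(self):
        subject_means = np.array([1.84, 1.78, 1.77, 1.77])
        assert np.mean(subject_means) == pytest.approx(1.79)

    def test_identical_curves_give_unit_ratio(self):
        ds = _dataset([1, 2, 3], [5, 6, 7], [1, 2, 3], [5, 6, 7])
        mean, sd = estimate_fwb(ds)
        assert mean == pytest.approx(1.0)
        assert sd == pytest.approx(0.0)

    def test_hand_computed_two_sample_mean(self):
        ds = _dataset([1, 2], [2, 4], [1, 2], [4, 6])
        mean, _ = estimate_fwb(ds)
        assert mean == pytest.approx(1.75)  # ratios 2.0 and 1.5

    def test_zero_whole_blood_at_paired_time_rejected(self):
        ds = _dataset([1, 2], [0, 4], [1, 2], [4, 6])
        with pytest.raises(ValueError, match="whole-blood"):
            estimate_fwb(ds)

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(st.floats(0.01, 100.0))
    def test_invariant_to_common_rescaling(self, scale):
        base = _dataset([1, 2, 5], [2, 4, 3], [1, 2, 5], [3, 7, 5])
        scaled = _dataset([1, 2, 5], np.array([2, 4, 3]) * scale,
                          [1, 2, 5], np.array([3, 7, 5]) * scale)
        assert estimate_fwb(base)[0] == pytest.approx(
            estimate_fwb(scaled)[0], rel=1e-9
        )


class TestParentFractionFit:
    def test_group_mean_fractions_recover_published_parameters(self):
        """The one-exponential washout fit of the five mean fractions lands
        near A0 = 0.046, T = 9.06 min."""
        fit = fit_parent_fraction(PPF_TIMES, PPF_MEANS)
        assert fit.A0 == pytest.approx(0.046, rel=0.10)
        assert fit.T == pytest.approx(9.06, rel=0.15)

    def test_all_unity_fractions_give_zero_plateau_with_flag(self):
        fit = fit_parent_fraction(np.array([2.0, 10.0, 30.0]), np.ones(3))
        assert fit.A0 == pytest.approx(0.0, abs=1e-5)
        assert fit.t_unidentifiable

    def test_noise_free_forward_generated_samples_recovered(self):
        true = ParentFractionFit(A0=0.10, T=20.0, ssr=0.0, n=5)
        samples = eval_parent_fraction(true, PPF_TIMES)
        fit = fit_parent_fraction(PPF_TIMES, samples)
        assert fit.A0 == pytest.approx(0.10, rel=1e-6)
        assert fit.T == pytest.approx(20.0, rel=1e-6)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_parent_fraction(np.array([1.0, 2.0]), np.array([1.0, 0.9]))

    def test_fitted_curve_monotone_non_increasing(self):
        fit = fit_parent_fraction(PPF_TIMES, PPF_MEANS)
        t = np.linspace(0, 300, 500)
        curve = eval_parent_fraction(fit, t)
        assert np.all(np.diff(curve) <= 1e-12)


class TestEvalParentFraction:
    FIT = ParentFractionFit(A0=0.046, T=9.06, ssr=0.0, n=5)

    def test_time_zero_is_exactly_one(self):
        assert eval_parent_fraction(self.FIT, 0.0) == 1.0

    def test_asymptote_is_one_minus_plateau(self):
        assert eval_parent_fraction(self.FIT, 1e9) == pytest.approx(1 - 0.046)

    def test_half_rise_at_t_equals_T(self):
        assert eval_parent_fraction(self.FIT, 9.06) == pytest.approx(
            1 - 0.046 / 2
        )

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            eval_parent_fraction(self.FIT, -1.0)


class TestBuildFp:
    TIMES = np.array([2.0, 10.0, 30.0, 90.0, 205.0])
    VALUES = np.array([0.0048, 0.0082, 0.0114, 0.0190, 0.0161])

    def test_late_mean_averages_samples_past_threshold(self):
        fp = build_fp(self.TIMES, self.VALUES, mode="LATE_MEAN",
                      late_threshold_min=30.0)
        expected = np.mean([0.0114, 0.0190, 0.0161])
        assert fp(np.array([0.0, 100.0]))[0] == pytest.approx(expected)

    def test_constant_samples_give_constant_function_in_both_modes(self):
        const = np.full(5, 0.015)
        for mode in ("TIME_VARYING", "LATE_MEAN"):
            fp = build_fp(self.TIMES, const, mode=mode)
            np.testing.assert_allclose(fp(np.linspace(0, 300, 7)), 0.015)

    def test_time_varying_hits_sample_nodes_exactly(self):
        fp = build_fp(self.TIMES, self.VALUES, mode="TIME_VARYING")
        np.testing.assert_array_equal(fp(self.TIMES), self.VALUES)

    def test_late_mean_without_late_samples_rejected(self):
        with pytest.raises(ValueError):
            build_fp(np.array([2.0, 10.0]), np.array([0.005, 0.008]),
                     mode="LATE_MEAN", late_threshold_min=30.0)


class TestAssembleAif:
    def test_unit_corrections_reproduce_whole_blood(self):
        ds = _dataset([0.5, 1, 5, 50, 100], [10, 20, 15, 8, 5],
                      [1, 5, 50], [10, 7.5, 4])
        ds.fwb = 1.0
        fit = ParentFractionFit(A0=0.0, T=10.0, ssr=0.0, n=3)
        grid = np.linspace(0, 100, 401)
        out = assemble_aif(ds, fit, lambda t: np.ones_like(t), grid)
        np.testing.assert_allclose(
            out.aif, whole_blood_interpolator(ds)(grid), rtol=1e-12
        )

    def test_componentwise_product_at_a_grid_point(self):
        # Cwb=100, fwb=1.79, PPf=0.96, fp=0.018 -> 3.09312
        assert 100 * 1.79 * 0.96 * 0.018 == pytest.approx(3.09312)
        ds = _dataset([1.0, 10.0], [100.0, 100.0])
        ds.fwb = 1.79
        fit = ParentFractionFit(A0=0.08, T=5.0, ssr=0.0, n=3)
        grid = np.array([0.0, 5.0, 10.0])
        out = assemble_aif(ds, fit, lambda t: np.full_like(t, 0.018), grid)
        t = 5.0
        ppf = eval_parent_fraction(fit, t)
        assert out.aif[1] == pytest.approx(ppf * 1.79 * 100.0 * 0.018, rel=1e-12)

    def test_generator_components_reconstructed_pointwise(self, profile, aif):
        """Rebuilding the input function from noise-free generator samples
        matches the generator's own closed-form product."""
        from petquant.synthetic import sample_blood

        ds = sample_blood(profile, noise_scale=0.0)
        estimate_fwb(ds)
        ppf_fit = fit_parent_fraction(ds.ppf_time, ds.ppf_fraction)
        fp_fun = build_fp(ds.fp_time, ds.fp_fraction, mode="TIME_VARYING")
        # compare on the sampled support (interpolation is exact at nodes)
        grid = ds.wb_time
        out = assemble_aif(ds, ppf_fit, fp_fun, grid)
        want = (
            profile.ppf(grid) * profile.fwb * profile.cwb(grid) * profile.fp(grid)
        )
        np.testing.assert_allclose(out.aif, want, rtol=1e-6, atol=1e-9)

    def test_grid_beyond_samples_plus_margin_rejected(self):
        ds = _dataset([1.0, 10.0], [5.0, 4.0])
        ds.fwb = 1.0
        fit = ParentFractionFit(A0=0.0, T=10.0, ssr=0.0, n=3)
        with pytest.raises(ExtrapolationError):
            assemble_aif(ds, fit, lambda t: np.ones_like(t),
                         np.linspace(0, 100, 11))

    def test_aif_nonnegative_and_zero_before_appearance(self, profile):
        grid = np.linspace(0.0, 220.0, 2000)
        _, true_if = generate_input_profile(profile, grid)
        assert true_if.aif.min() >= 0.0
        assert np.all(true_if.aif[grid < profile.delay_min] == 0.0)
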
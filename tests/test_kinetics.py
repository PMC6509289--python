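import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from srtmkit import (
    SRTMParameters,
    ThetaGrid,
    TimeActivityCurve,
    build_basis,
    exp_convolve,
    fit_srtm_bfm,
    fit_srtm_nls,
    forward_srtm,
    make_frame_schedule,
)
from srtmkit.exceptions import (
    InsufficientDataError,
    ParameterError,
    ScheduleError,
    SingularFitError,
)
from srtmkit.kinetics import _convolve_sampled


@pytest.fixture(scope="module")
def mono_exp_curve():
    """C_R(t) = exp(-0.1 t), analytic, on a schedule whose 3rd midpoint is t = 5 min."""
    sched = make_frame_schedule([(5, 120)])
    return TimeActivityCurve.from_exponentials(sched, [1.0], [0.1])


class TestExpConvolve:
    def test_single_exponential_closed_form(self, mono_exp_curve):
        # int_0^t e^{-as} e^{-theta(t-s)} ds = (e^{-at} - e^{-theta t}) / (theta - a)
        v = exp_convolve(mono_exp_curve, 0.3)
        assert v[2] == pytest.approx(1.917002497821018, rel=1e-12)

    def test_theta_zero_is_running_integral(self, mono_exp_curve):
        v = exp_convolve(mono_exp_curve, 0.0)
        assert v[2] == pytest.approx(3.934693402873666, rel=1e-12)

    def test_zero_input_gives_zeros(self, schedule):
        zero = TimeActivityCurve(schedule, np.zeros(schedule.n_frames))
        np.testing.assert_array_equal(exp_convolve(zero, 0.2), 0.0)

    def test_negative_theta_rejected(self, mono_exp_curve):
        with pytest.raises(ParameterError):
            exp_convolve(mono_exp_curve, -0.1)

    def test_sampled_path_tracks_analytic(self, schedule, ref_tac):
        """Piecewise-linear reconstruction agrees with the exact convolution."""
        sampled_only = TimeActivityCurve(schedule, ref_tac.activity)
        approx = _convolve_sampled(schedule.mid_min, sampled_only.activity, np.array([0.12]))[0]
        exact = exp_convolve(ref_tac, 0.12)
        # interpolation error is largest on the earliest (tiny-valued) frames
        rel = np.abs(approx - exact) / np.max(exact)
        assert rel.max() < 5e-3

    def test_nonnegative_for_nonnegative_input(self, ref_tac):
        assert np.all(exp_convolve(ref_tac, 0.4) >= 0)


class TestForwardSrtm:
    def test_zero_binding_collapses_to_reference(self, ref_tac):
        p = SRTMParameters.from_bp(r1=1.0, k2=0.25, bp_nd=0.0)
        ct = forward_srtm(p, ref_tac)
        np.testing.assert_allclose(ct.activity, ref_tac.activity, rtol=1e-12)

    def test_zero_weight_basis_term_scales_reference(self, ref_tac):
        # k2 = R1 * k2a makes the convolution term vanish: C_T = R1 * C_R
        p = SRTMParameters(r1=0.8, k2=0.8 * 0.2, k2a=0.2)
        ct = forward_srtm(p, ref_tac)
        np.testing.assert_allclose(ct.activity, 0.8 * ref_tac.activity, rtol=1e-12)

    def test_bp_identity_holds(self):
        p = SRTMParameters.from_bp(r1=1.1, k2=0.3, bp_nd=1.5)
        assert p.bp_nd == pytest.approx(1.5, rel=1e-14)
        assert p.k2 / p.k2a - 1 == pytest.approx(p.bp_nd, rel=1e-14)

    def test_nonpositive_k2a_rejected(self):
        with pytest.raises(ParameterError):
            SRTMParameters(r1=1.0, k2=0.3, k2a=0.0)

    def test_analytic_propagation_matches_samples(self, ref_tac):
        p = SRTMParameters.from_bp(r1=1.0, k2=0.3, bp_nd=1.5)
        ct = forward_srtm(p, ref_tac)
        assert ct.analytic is not None
        np.testing.assert_allclose(
            ct.analytic.value(ct.schedule.mid_min), ct.activity, rtol=1e-10
        )


class TestBuildBasis:
    def test_grid_size_and_endpoints(self, ref_tac, grid):
        basis = build_basis(ref_tac, grid)
        assert basis.shape == (100, ref_tac.schedule.n_frames)
        np.testing.assert_allclose(basis[0], exp_convolve(ref_tac, 0.05))
        np.testing.assert_allclose(basis[-1], exp_convolve(ref_tac, 0.4))

    def test_two_bases_are_exactly_the_endpoints(self, ref_tac):
        basis = build_basis(ref_tac, ThetaGrid(0.05, 0.4, 2))
        np.testing.assert_allclose(basis[0], exp_convolve(ref_tac, 0.05))
        np.testing.assert_allclose(basis[1], exp_convolve(ref_tac, 0.4))

    def test_pointwise_decreasing_in_theta(self, ref_tac, grid):
        basis = build_basis(ref_tac, grid)
        assert np.all(np.diff(basis, axis=0) <= 1e-12)
        assert np.all(basis >= 0)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"theta_min": -0.1, "theta_max": 0.4},
            {"theta_min": 0.4, "theta_max": 0.05},
            {"n_bases": 1},
            {"spacing": "cubic"},
        ],
    )
    def test_invalid_grids_rejected(self, kwargs):
        with pytest.raises(ParameterError):
            ThetaGrid(**{"theta_min": 0.05, "theta_max": 0.4, "n_bases": 100, "spacing": "log", **kwargs})


class TestFitSrtmBfm:
    def test_identity_fit(self, ref_tac, grid):
        fit = fit_srtm_bfm(ref_tac, ref_tac, grid)
        assert fit.params.r1 == pytest.approx(1.0, abs=1e-8)
        assert fit.coefficients[1] == pytest.approx(0.0, abs=1e-8)
        assert fit.params.bp_nd == pytest.approx(0.0, abs=1e-6)

    def test_round_trip_recovery(self, ref_tac, grid):
        true = SRTMParameters.from_bp(r1=1.0, k2=0.30, bp_nd=1.5)  # k2a = 0.12, in grid
        ct = forward_srtm(true, ref_tac)
        fit = fit_srtm_bfm(ct, ref_tac, grid)
        assert abs(fit.params.bp_nd - 1.5) <= 0.05
        assert abs(fit.params.r1 - 1.0) <= 0.01

    def test_rss_is_profile_minimum(self, ref_tac, grid):
        true = SRTMParameters.from_bp(r1=0.9, k2=0.25, bp_nd=0.8)
        ct = forward_srtm(true, ref_tac)
        noisy = TimeActivityCurve(
            ct.schedule, ct.activity + np.random.default_rng(0).normal(0, 1.0, ct.activity.size)
        )
        fit = fit_srtm_bfm(noisy, ref_tac, grid)
        assert fit.rss == fit.rss_profile[fit.chosen_index]
        assert np.all(fit.rss >= 0)
        assert np.all(fit.rss <= fit.rss_profile + 1e-12)

    @settings(deadline=None, derandomize=True, max_examples=20)
    @given(scale=st.floats(min_value=1e-3, max_value=1e3))
    def test_scale_equivariance(self, ref_tac, grid, scale):
        """Multiplying target and reference by c > 0 leaves all parameters unchanged."""
        true = SRTMParameters.from_bp(r1=1.1, k2=0.3, bp_nd=1.2)
        ct = forward_srtm(true, ref_tac)
        f1 = fit_srtm_bfm(ct, ref_tac, grid)
        f2 = fit_srtm_bfm(ct.scaled(scale), ref_tac.scaled(scale), grid)
        assert f2.chosen_index == f1.chosen_index
        assert f2.params.r1 == pytest.approx(f1.params.r1, rel=1e-8)
        assert f2.params.bp_nd == pytest.approx(f1.params.bp_nd, rel=1e-8, abs=1e-10)

    def test_zero_reference_is_singular(self, schedule, grid):
        zero = TimeActivityCurve(schedule, np.zeros(schedule.n_frames))
        target = TimeActivityCurve(schedule, np.ones(schedule.n_frames))
        with pytest.raises(SingularFitError):
            fit_srtm_bfm(target, zero, grid)

    def test_too_few_frames_rejected(self, grid):
        sched = make_frame_schedule([(2, 60)])
        tac = TimeActivityCurve(sched, np.array([1.0, 2.0]))
        with pytest.raises(InsufficientDataError):
            fit_srtm_bfm(tac, tac, grid)

    def test_schedule_mismatch_rejected(self, ref_tac, grid):
        other = make_frame_schedule([(10, 270)])
        tac = TimeActivityCurve(other, np.ones(10))
        with pytest.raises(ScheduleError):
            fit_srtm_bfm(tac, ref_tac, grid)

    def test_duration_weights_accepted(self, ref_tac, grid):
        true = SRTMParameters.from_bp(r1=1.0, k2=0.3, bp_nd=1.5)
        ct = forward_srtm(true, ref_tac)
        fit = fit_srtm_bfm(ct, ref_tac, grid, weights="duration")
        assert abs(fit.params.bp_nd - 1.5) <= 0.05

    @pytest.mark.parametrize("bad", ["frameweights", np.zeros(50), -np.ones(50)])
    def test_invalid_weights_rejected(self, ref_tac, grid, bad):
        with pytest.raises(ParameterError):
            fit_srtm_bfm(ref_tac, ref_tac, grid, weights=bad)


class TestFitSrtmNls:
    def test_noiseless_recovery_to_optimiser_tolerance(self, ref_tac):
        true = SRTMParameters.from_bp(r1=1.0, k2=0.30, bp_nd=1.5)
        ct = forward_srtm(true, ref_tac)
        fit = fit_srtm_nls(ct, ref_tac)
        assert fit.params.r1 == pytest.approx(1.0, rel=1e-4)
        assert fit.params.k2 == pytest.approx(0.30, rel=1e-4)
        assert fit.params.bp_nd == pytest.approx(1.5, rel=1e-4)
        assert fit.diagnostics["converged"]

    def test_identity_target_gives_zero_binding(self, ref_tac):
        fit = fit_srtm_nls(ref_tac, ref_tac)
        assert fit.params.bp_nd == pytest.approx(0.0, abs=1e-6)

    def test_agrees_with_bfm_within_one_grid_step(self, ref_tac, grid):
        """Randomised sweep: the two estimators may differ only by grid resolution."""
        rng = np.random.default_rng(42)
        step = (grid.theta_max / grid.theta_min) ** (1.0 / (grid.n_bases - 1))
        for _ in range(20):
            k2a = rng.uniform(0.06, 0.38)
            bp = rng.uniform(0.1, 2.5)
            r1 = rng.uniform(0.7, 1.3)
            true = SRTMParameters(r1=r1, k2=k2a * (1 + bp), k2a=k2a)
            ct = forward_srtm(true, ref_tac)
            bfm = fit_srtm_bfm(ct, ref_tac, grid)
            nls = fit_srtm_nls(ct, ref_tac)
            assert abs(np.log(bfm.params.k2a / nls.params.k2a)) <= np.log(step) + 1e-9
            bp_tol = (1 + nls.params.bp_nd) * (step - 1)
            assert abs(bfm.params.bp_nd - nls.params.bp_nd) <= bp_tol + 1e-9
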
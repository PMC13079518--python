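"""Closed-form model: transducer, moments, Weber fractions, difference limens."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.optimize import brentq

import tiup
from tiup import ModelParams, SaturationError, Stimulus

S100 = Stimulus(luminance=100.0, duration=0.1)


class TestPopulationRate:
    def test_half_saturation_at_K(self, fig5_params):
        assert tiup.population_rate(fig5_params, 100.0) == pytest.approx(5000.0)

    def test_zero_luminance_gives_zero_rate(self, fig5_params):
        assert tiup.population_rate(fig5_params, 0.0) == 0.0

    def test_direct_substitution(self, fig5_params):
        # 10000 * 300 / (300 + 100)
        assert tiup.population_rate(fig5_params, 300.0) == pytest.approx(7500.0)

    def test_negative_luminance_rejected(self, fig5_params):
        with pytest.raises(ValueError):
            tiup.population_rate(fig5_params, -1.0)

    def test_monotone_and_bounded(self, fig5_params):
        L = np.logspace(-2, 5, 200)
        r = tiup.population_rate(fig5_params, L)
        assert np.all(np.diff(r) > 0)
        assert np.all(r < fig5_params.lambda_max)

    def test_analytic_slope_matches_finite_difference(self, fig5_params):
        for L in (3.0, 50.0, 100.0, 400.0):
            h = L * 1e-6
            fd = (
                tiup.population_rate(fig5_params, L + h)
                - tiup.population_rate(fig5_params, L - h)
            ) / (2 * h)
            assert tiup.population_rate_slope(fig5_params, L) == pytest.approx(
                fd, rel=1e-6
            )


class TestParamsValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(lambda_max=-1, K=1, n=1, sigma2=0.1),
            dict(lambda_max=1, K=0, n=1, sigma2=0.1),
            dict(lambda_max=1, K=1, n=-2, sigma2=0.1),
            dict(lambda_max=1, K=1, n=1, sigma2=-0.1),
        ],
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ModelParams(**kwargs)

    @pytest.mark.parametrize("L,t", [(-1, 0.1), (0, 0.1), (1, 0), (1, -0.5)])
    def test_invalid_stimulus_rejected(self, L, t):
        with pytest.raises(ValueError):
            Stimulus(luminance=L, duration=t)


class TestSpikeCountMoments:
    def test_fig5_setting(self, fig5_params):
        m = tiup.spike_count_moments(fig5_params, S100)
        assert m.mean == pytest.approx(500.0)
        assert m.variance == pytest.approx(500.0 + 0.0625 * 500.0**2)

    def test_poisson_limit_variance_equals_mean(self):
        p = ModelParams(10000.0, 100.0, 1.0, 0.0)
        m = tiup.spike_count_moments(p, S100)
        assert m.variance == pytest.approx(m.mean)

    def test_vanishing_window(self, fig5_params):
        m = tiup.spike_count_moments(fig5_params, Stimulus(100.0, 1e-12))
        assert m.mean == pytest.approx(0.0, abs=1e-6)
        assert m.variance == pytest.approx(0.0, abs=1e-6)


class TestWeberFraction:
    def test_fig5_value(self, fig5_params):
        # sqrt(200 / (1e4 * 100 * 0.1 / 200 * 200) ...) = sqrt(1/500 + 0.0625)
        assert tiup.weber_fraction(fig5_params, S100) == pytest.approx(
            np.sqrt(0.0645), rel=1e-12
        )

    def test_long_duration_asymptote_from_above(self, fig5_params):
        ws = [
            tiup.weber_fraction(fig5_params, Stimulus(100.0, t))
            for t in (1.0, 10.0, 100.0, 1e4)
        ]
        assert np.all(np.diff(ws) < 0)
        assert ws[-1] > np.sqrt(fig5_params.sigma2)
        assert ws[-1] == pytest.approx(np.sqrt(fig5_params.sigma2), rel=1e-3)

    def test_poisson_limit_inverse_sqrt_count(self):
        p = ModelParams(10000.0, 100.0, 1.0, 0.0)
        mean = tiup.spike_count_moments(p, S100).mean
        assert tiup.weber_fraction(p, S100) == pytest.approx(1.0 / np.sqrt(mean))


class TestDurationDL:
    def test_fig5_value(self, fig5_params):
        assert tiup.dl_duration(fig5_params, S100) == pytest.approx(
            np.sqrt(0.0645) * 0.1, rel=1e-12
        )

    def test_poisson_sqrt_t_scaling(self):
        p = ModelParams(10000.0, 100.0, 1.0, 0.0)
        d1 = tiup.dl_duration(p, Stimulus(100.0, 0.05))
        d4 = tiup.dl_duration(p, Stimulus(100.0, 0.20))
        assert d4 == pytest.approx(2.0 * d1, rel=1e-12)

    def test_increasing_in_duration(self, fig5_params):
        ts = np.linspace(0.01, 2.0, 30)
        dls = [tiup.dl_duration(fig5_params, Stimulus(100.0, t)) for t in ts]
        assert np.all(np.diff(dls) > 0)


class TestLuminanceDLLinear:
    def test_fig5_value_against_numeric_derivative(self, fig5_params):
        W = tiup.weber_fraction(fig5_params, S100)
        L = 100.0
        h = 1e-5
        slope = (
            tiup.population_rate(fig5_params, L + h)
            - tiup.population_rate(fig5_params, L - h)
        ) / (2 * h)
        oracle = W * tiup.population_rate(fig5_params, L) / slope
        got = tiup.dl_luminance_linear(fig5_params, S100)
        assert got == pytest.approx(oracle, rel=1e-8)
        assert got == pytest.approx(100.0 * 200.0 * W / 100.0, rel=1e-12)

    def test_doubling_n_at_K_halves_dl(self):
        p1 = ModelParams(10000.0, 100.0, 1.0, 0.0625)
        p2 = ModelParams(10000.0, 100.0, 2.0, 0.0625)
        s = Stimulus(100.0, 0.1)  # L = K: W is unchanged by n
        assert tiup.weber_fraction(p1, s) == pytest.approx(tiup.weber_fraction(p2, s))
        assert tiup.dl_luminance_linear(p2, s) == pytest.approx(
            tiup.dl_luminance_linear(p1, s) / 2.0, rel=1e-12
        )

    def test_decreasing_in_duration(self, fig5_params):
        dls = [
            tiup.dl_luminance_linear(fig5_params, Stimulus(100.0, t))
            for t in (0.05, 0.1, 0.4, 1.0)
        ]
        assert np.all(np.diff(dls) < 0)


class TestNakaRushtonInverse:
    def test_half_saturation_inverts_to_K(self, fig5_params):
        assert tiup.naka_rushton_inverse(fig5_params, 5000.0) == pytest.approx(100.0)

    def test_known_rate(self, fig5_params):
        # numeric root-finding oracle
        oracle = brentq(
            lambda L: tiup.population_rate(fig5_params, L) - 7500.0, 1e-6, 1e8
        )
        assert tiup.naka_rushton_inverse(fig5_params, 7500.0) == pytest.approx(
            oracle, rel=1e-9
        )
        assert oracle == pytest.approx(300.0, rel=1e-9)

    def test_round_trip_on_log_grid(self, fig5_params):
        L = np.logspace(-3, 4, 50)
        r = tiup.population_rate(fig5_params, L)
        back = tiup.naka_rushton_inverse(fig5_params, r)
        np.testing.assert_allclose(back, L, rtol=1e-10)

    def test_saturation_and_domain_errors(self, fig5_params):
        with pytest.raises(SaturationError):
            tiup.naka_rushton_inverse(fig5_params, fig5_params.lambda_max)
        with pytest.raises(ValueError):
            tiup.naka_rushton_inverse(fig5_params, 0.0)


class TestLuminanceDLExact:
    def test_fig5_value_against_bisection(self, fig5_params):
        W = tiup.weber_fraction(fig5_params, S100)
        lam = tiup.population_rate(fig5_params, 100.0)
        L_u = brentq(
            lambda L: tiup.population_rate(fig5_params, L) - lam * (1 + W), 1e-9, 1e9,
            xtol=1e-12, rtol=1e-14,
        )
        L_l = brentq(
            lambda L: tiup.population_rate(fig5_params, L) - lam * (1 - W), 1e-9, 1e9,
            xtol=1e-12, rtol=1e-14,
        )
        oracle = 0.5 * (L_u - L_l)
        got = tiup.dl_luminance_exact(fig5_params, S100)
        assert got == pytest.approx(oracle, rel=1e-8)
        # threshold rates rounded to integer Hz: ~100*(6270/3730) and mirror
        assert got == pytest.approx(
            0.5 * (100 * 6270 / 3730 - 100 * 3730 / 6270), rel=1e-3
        )

    def test_converges_to_linear_for_small_weber(self):
        p = ModelParams(10000.0, 100.0, 1.0, 0.0)
        s = Stimulus(100.0, 1000.0)  # huge count: W ~ 4.5e-4
        exact = tiup.dl_luminance_exact(p, s)
        linear = tiup.dl_luminance_linear(p, s)
        assert abs(exact - linear) / linear < 1e-3
        assert exact >= 0

    def test_saturation_error_when_weber_exceeds_headroom(self, fig5_params):
        # L far above K: population rate near ceiling, upper threshold unattainable
        with pytest.raises(SaturationError):
            tiup.dl_luminance_exact(fig5_params, Stimulus(1e5, 0.1))

    def test_linearization_gap_shrinks_with_weber(self, fig5_params):
        gaps = []
        for t in (0.05, 0.5, 5.0, 50.0):
            s = Stimulus(100.0, t)
            e = tiup.dl_luminance_exact(fig5_params, s)
            l = tiup.dl_luminance_linear(fig5_params, s)
            gaps.append(abs(e - l) / l)
        assert np.all(np.diff(gaps) < 0)


class TestPredictGrid:
    def test_single_cell_matches_scalar_ops(self, fig5_params):
        g = tiup.predict_dl_grid(fig5_params, [100.0], [0.1])
        assert g.dl_t[0, 0] == pytest.approx(tiup.dl_duration(fig5_params, S100))
        assert g.dl_L[0, 0] == pytest.approx(tiup.dl_luminance_exact(fig5_params, S100))
        assert g.weber_t[0, 0] == pytest.approx(tiup.weber_fraction(fig5_params, S100))

    def test_saturated_cells_flagged_not_raised(self, fig5_params):
        with pytest.warns(tiup.SaturationWarning):
            g = tiup.predict_dl_grid(fig5_params, [100.0, 1e5], [0.1])
        assert np.isinf(g.dl_L[1, 0])
        assert np.isfinite(g.dl_t).all()

    def test_frame_units(self, fig5_params):
        frame = tiup.predict_dl_grid(fig5_params, [100.0], [0.1]).to_frame()
        assert frame.loc[0, "duration_ms"] == pytest.approx(100.0)
        assert frame.loc[0, "dl_t_ms"] == pytest.approx(
            tiup.dl_duration(fig5_params, S100) * 1e3
        )

    def test_invalid_grid_rejected(self, fig5_params):
        with pytest.raises(ValueError):
            tiup.predict_dl_grid(fig5_params, [0.0, 1.0], [0.1])


params_strategy = st.builds(
    ModelParams,
    lambda_max=st.floats(1e2, 1e6),
    K=st.floats(0.5, 1e4),
    n=st.floats(0.3, 3.0),
    sigma2=st.floats(1e-4, 1.0),
)


@given(params=params_strategy, rate_frac=st.floats(1e-6, 1 - 1e-6))
def test_inverse_round_trip_property(params, rate_frac):
    """population_rate o naka_rushton_inverse is the identity on (0, lambda_max)."""
    rate = rate_frac * params.lambda_max
    L = tiup.naka_rushton_inverse(params, rate)
    assert tiup.population_rate(params, L) == pytest.approx(rate, rel=1e-10)


@given(params=params_strategy, L=st.floats(0.1, 1e3), t=st.floats(1e-3, 10.0))
def test_weber_decreases_in_duration_and_luminance(params, L, t):
    s = Stimulus(L, t)
    w = tiup.weber_fraction(params, s)
    assert w > np.sqrt(params.sigma2)
    assert tiup.weber_fraction(params, Stimulus(L, t * 2)) < w
    assert tiup.weber_fraction(params, Stimulus(L * 2, t)) < w
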
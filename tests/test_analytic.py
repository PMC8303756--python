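import dataclasses
import math
import warnings

import numpy as np
import pytest
from scipy.integrate import quad

from spheroidsim.analytic import (
    ClosedFormConstants,
    DegenerateCollapseWarning,
    HistoryError,
    SeriesConfig,
    closed_form_radius,
    diffusion_only_radius,
    diffusion_only_radius_exact,
    erfi,
    integrate_analytic_trajectory,
    log_abs_erfi,
    series_radius_rate,
    shape_factor,
    simplified_radius_rate,
)
from spheroidsim.params import ModelParameters
from spheroidsim.solver import MappedGrid, SolverConfig


class TestErfi:
    def test_zero_and_oddness(self):
        assert erfi(0.0) == 0.0
        xs = np.array([0.3, 1.0, 2.7, 5.0])
        np.testing.assert_allclose(erfi(-xs), -erfi(xs), rtol=1e-14)

    def test_value_matches_quadrature(self):
        # (2/sqrt(pi)) int_0^1 e^{s^2} ds
        val, _ = quad(lambda s: math.exp(s * s), 0.0, 1.0)
        assert erfi(1.0) == pytest.approx(2.0 / math.sqrt(math.pi) * val, rel=1e-12)
        assert erfi(1.0) == pytest.approx(1.650425759, abs=1e-9)

    def test_strictly_increasing_and_smooth(self):
        xs = np.linspace(-3, 3, 301)
        assert np.all(np.diff(erfi(xs)) > 0)

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError):
            erfi(float("inf"))

    def test_log_companion_matches_direct_and_extends(self):
        for x in (0.5, 3.0, 19.0):
            lm, sg = log_abs_erfi(x)
            assert sg == 1.0
            assert lm == pytest.approx(math.log(erfi(x)), rel=1e-12)
        # beyond double-precision overflow of the direct value: oracle by
        # quadrature of log(erfi(x)) = x^2 + log((2/sqrt(pi)) I), with
        # I = int_0^x e^{s^2 - x^2} ds evaluated without overflow
        x = 40.0
        I, _ = quad(lambda s: math.exp(s * s - x * x), 0.0, x)
        ref = x * x + math.log(2.0 / math.sqrt(math.pi) * I)
        lm, sg = log_abs_erfi(x)
        assert sg == 1.0
        assert lm == pytest.approx(ref, rel=1e-12)
        lm_neg, sg_neg = log_abs_erfi(-x)
        assert sg_neg == -1.0 and lm_neg == lm


class TestDiffusionOnlyRadius:
    def test_starts_at_initial_radius(self, set1_params):
        assert diffusion_only_radius(0.0, set1_params) == set1_params.R0

    def test_equal_concentrations_freeze_radius(self):
        p = ModelParameters(K=3.6e-7, eta=0.016, C0=1.0, Ci=1.0, R0=0.01)
        ts = np.linspace(0, 210, 22)
        np.testing.assert_allclose(diffusion_only_radius(ts, p), p.R0, rtol=1e-14)

    def test_strictly_decreasing_in_contraction_regime(self, set1_params):
        ts = np.linspace(0.0, 100.0, 51)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", DegenerateCollapseWarning)
            r1 = diffusion_only_radius(ts, set1_params)
        assert np.all(np.diff(r1) < 0)

    def test_eta_zero_limit_is_planar_contraction(self, set1_params):
        p0 = dataclasses.replace(set1_params, eta=0.0)
        p_tiny = dataclasses.replace(set1_params, eta=1e-9)
        for t in (1.0, 10.0, 40.0):
            planar = p0.R0 + 2 * (p0.Ci - p0.C0) * math.sqrt(p0.K * t / math.pi)
            assert diffusion_only_radius(t, p0) == pytest.approx(planar, rel=1e-12)
            assert diffusion_only_radius(t, p_tiny) == pytest.approx(planar, rel=1e-6)

    def test_degenerate_collapse_warns(self, set1_params):
        with pytest.warns(DegenerateCollapseWarning):
            diffusion_only_radius(210.0, set1_params)

    def test_matches_constant_source_solver_in_validity_window(self, set1_params):
        """Oracle gate: within its short-time validity window
        (K pi^2 t / R0^2 well below 1) the erfi form tracks a CN solve of
        the constant-source auxiliary system."""
        from spheroidsim.solver import advance_radius, cn_step, initial_field

        p = set1_params
        p_aux = dataclasses.replace(p, eta=0.0)
        grid = MappedGrid(101)
        cfg = SolverConfig(dt=2e-4)
        src = p.eta * p.Ci * p.t_max
        field = initial_field(p_aux, grid)
        t_gate = 5.0
        forcing = lambda r_bar, t_bar: np.full_like(r_bar, src)
        while field.t < t_gate - 1e-9:
            new = cn_step(field, p_aux, grid, cfg, forcing=forcing)
            new.R = advance_radius(field, p_aux, grid, cfg, field_new=new)
            field = new
        r1 = diffusion_only_radius(t_gate, p)
        assert abs(r1 - field.R) / field.R < 0.03


class TestDiffusionOnlyExact:
    def test_plateau_value(self):
        p = ModelParameters(K=3.6e-7, eta=0.0, C0=1.5, Ci=1.0, R0=0.01)
        r_inf = p.R0 * math.exp(-(p.C0 - p.Ci) / 3.0)
        assert diffusion_only_radius_exact(5000.0, p) == pytest.approx(r_inf, rel=1e-7)

    def test_short_time_limit_agrees_with_erfi_form(self):
        p = ModelParameters(K=3.6e-7, eta=0.0, C0=1.5, Ci=1.0, R0=0.01)
        for t in (0.01, 0.1):
            exact = diffusion_only_radius_exact(t, p)
            planar = diffusion_only_radius(t, p)
            assert exact == pytest.approx(planar, rel=2e-3)

    def test_requires_no_proliferation(self, set1_params):
        with pytest.raises(ValueError, match="eta = 0"):
            diffusion_only_radius_exact(10.0, set1_params)


class TestShapeFactor:
    @pytest.mark.parametrize("n", [1, 2, 3, 7])
    def test_value_at_reference_radius(self, n):
        # R = R1 gives R_bar = n pi: sin vanishes, cos alternates
        R = 0.01
        expected = n * math.pi * (-1) ** n / R**2
        assert shape_factor(R, R, n) == pytest.approx(expected, rel=1e-12)

    def test_small_r_bar_cubic_limit(self):
        R, n = 1e-7, 1
        R1 = 1.0
        r_bar = n * math.pi * R / R1
        expected = -(r_bar**3) / (3 * R**2)
        assert shape_factor(R, R1, n) == pytest.approx(expected, rel=1e-6)

    def test_direct_evaluation_cross_checked_against_expansion(self):
        # moderate R_bar: compare the closed expression with a high-order
        # Taylor expansion of (x cos x - sin x)
        R, R1, n = 0.009, 0.010, 2
        x = n * math.pi * R / R1
        series = sum(
            (-1) ** k * (x ** (2 * k + 1)) * (2 * k) / math.factorial(2 * k + 1)
            for k in range(1, 40)
        )
        assert shape_factor(R, R1, n) == pytest.approx(series / R**2, rel=1e-10)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            shape_factor(-0.01, 0.01, 1)


class TestSeriesRate:
    def test_history_must_cover_requested_time(self, set1_params):
        hist = (np.array([0.0, 1.0]), np.array([0.01, 0.0099]))
        with pytest.raises(HistoryError):
            series_radius_rate(5.0, 0.0099, hist, set1_params)

    def test_zero_initial_flux_when_concentrations_match(self):
        """With compatible data (Ci = C0) there is no surface transient:
        the initial boundary flux vanishes identically and the growth rate
        builds up continuously from zero."""
        p = ModelParameters(K=3.6e-7, eta=0.016, C0=1.0, Ci=1.0, R0=0.01)
        hist = (np.array([0.0, 1.0]), np.array([0.01, 0.01]))
        assert series_radius_rate(0.0, 0.01, hist, p) == 0.0
        r1h = series_radius_rate(1.0, 0.01, hist, p)
        steady = p.eta * p.R0 / 3.0
        assert 0.0 < r1h < steady

    def test_truncation_converged_at_default_order(self, set1_params):
        hist = (np.array([0.0, 50.0]), np.array([0.01, 0.009]))
        r100 = series_radius_rate(
            42.0, 0.009, hist, set1_params, SeriesConfig(n_terms=100)
        )
        r200 = series_radius_rate(
            42.0, 0.009, hist, set1_params, SeriesConfig(n_terms=200)
        )
        assert abs(r200 - r100) <= 1e-8 * abs(r200)

    def test_contraction_sign(self, set1_params):
        hist = (np.array([0.0, 10.0]), np.array([0.01, 0.0095]))
        assert series_radius_rate(5.0, 0.0095, hist, set1_params) < 0


class TestSimplifiedRate:
    def test_agrees_with_series_when_proliferation_slow(self, set1_params):
        """The R_bar ~ n pi reduction becomes exact in the separation of
        timescales eta / (K (pi/R0)^2) -> 0."""
        hist_t = np.linspace(0.0, 20.0, 41)

        def gap(eta_scale, k_scale):
            p = dataclasses.replace(
                set1_params, eta=set1_params.eta * eta_scale, K=set1_params.K * k_scale
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                r1 = diffusion_only_radius(hist_t, p, warn_collapse=False)
            hist = (hist_t, r1)
            t, R = 10.0, float(np.interp(10.0, hist_t, r1))
            full = series_radius_rate(t, R, hist, p)
            simp = simplified_radius_rate(t, R, p, R_history=hist)
            return abs(simp - full) / abs(full)

        assert gap(0.1, 10.0) < gap(1.0, 1.0)
        assert gap(0.1, 10.0) < 0.05

    def test_without_history_uses_diffusion_reference(self, set1_params):
        v = simplified_radius_rate(5.0, 0.0095, set1_params)
        assert np.isfinite(v) and v < 0


class TestClosedForm:
    def test_starts_at_initial_radius(self, set1_params):
        assert closed_form_radius(0.0, set1_params) == pytest.approx(
            set1_params.R0, abs=1e-18
        )

    def test_redirects_for_zero_proliferation(self):
        p = ModelParameters(K=3.6e-7, eta=0.0, C0=1.5, Ci=1.0, R0=0.01)
        with pytest.raises(ValueError, match="diffusion_only_radius"):
            closed_form_radius(10.0, p)

    def test_contraction_then_growth_shape(self, set1_params):
        ts = np.linspace(0.0, 210.0, 211)
        r = closed_form_radius(ts, set1_params)
        i_min = int(np.argmin(r))
        assert 0 < i_min < len(ts) - 1
        assert np.all(np.diff(r[: i_min + 1]) < 0)
        assert np.all(np.diff(r[i_min + 1 :]) > 0)

    def test_faster_proliferation_reaches_minimum_earlier(
        self, set1_params, set2_params
    ):
        ts = np.linspace(0.0, 210.0, 2101)
        t1 = ts[np.argmin(closed_form_radius(ts, set1_params))]
        t2 = ts[np.argmin(closed_form_radius(ts, set2_params))]
        assert t2 < t1

    def test_short_time_planar_limit(self, set1_params):
        """At early times the closed form reduces to the same planar
        contraction 2 (C0 - Ci) sqrt(K t / pi) as the diffusion-only
        radius."""
        p = set1_params
        for t in (0.01, 0.05):
            planar = p.R0 - 2 * (p.C0 - p.Ci) * math.sqrt(p.K * t / math.pi)
            assert closed_form_radius(t, p) == pytest.approx(
                planar, abs=0.05 * (p.R0 - planar)
            )

    def test_continuity_and_smoothness(self, set1_params):
        """The closed form is C^1 away from t = 0: Richardson halving of
        the central-difference step converges at second order."""
        ts = np.array([1.0, 5.0, 20.0, 80.0, 180.0])
        r = closed_form_radius(ts, set1_params)
        assert np.all(np.isfinite(r))
        for t in ts:
            d = {}
            for h in (0.1, 0.05, 0.025):
                d[h] = (
                    closed_form_radius(t + h, set1_params)
                    - closed_form_radius(t - h, set1_params)
                ) / (2 * h)
            e1 = abs(d[0.1] - d[0.025])
            e2 = abs(d[0.05] - d[0.025])
            assert e2 <= 0.3 * e1 + 1e-15

    def test_custom_constants_override(self, set1_params):
        doubled = ClosedFormConstants(
            alpha=2 * ClosedFormConstants.from_parameters(set1_params).alpha
        )
        base = closed_form_radius(50.0, set1_params) - set1_params.R0
        big = closed_form_radius(50.0, set1_params, doubled) - set1_params.R0
        assert big == pytest.approx(2 * base, rel=1e-12)

    def test_constants_validation(self):
        with pytest.raises(ValueError):
            ClosedFormConstants(alpha=float("nan"))
        rule = ClosedFormConstants(alpha=1.0).lambda_n_rule
        lams = [rule(n, 0.01) for n in range(1, 6)]
        assert all(b > a for a, b in zip(lams, lams[1:]))


class TestAnalyticTrajectory:
    def test_equilibrium_stays_at_initial_radius(self):
        p = ModelParameters(K=3.6e-7, eta=0.0, C0=1.2, Ci=1.2, R0=0.01)
        traj = integrate_analytic_trajectory(
            p, SeriesConfig(n_time_steps=200), times=np.linspace(0, 210, 8)
        )
        np.testing.assert_allclose(traj.radii, p.R0, rtol=1e-12)

    def test_requires_times_starting_at_zero(self, set1_params):
        with pytest.raises(ValueError, match="start at 0"):
            integrate_analytic_trajectory(set1_params, times=np.array([1.0, 2.0]))

    def test_motility_ordering_of_contraction(self):
        """Higher K* contracts faster and deeper within the analytic
        family's validity window (the early contraction phase)."""
        times = np.linspace(0.0, 20.0, 41)
        curves = []
        for k_star in (1.0, 3.0):
            p = ModelParameters.from_dimensionless(
                K_star=k_star, eta_star=1.8, C0_over_Ci=1.5, R0=0.01
            )
            cfg = SeriesConfig(n_time_steps=500)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                traj = integrate_analytic_trajectory(p, cfg, times=times)
            curves.append(traj.radii)
        slow, fast = curves
        assert fast[times >= 5.0].min() < slow[times >= 5.0].min()
        assert np.interp(10.0, times, fast) < np.interp(10.0, times, slow)

    def test_matches_moving_boundary_solver_in_contraction(
        self, set1_params, cn_set1
    ):
        """Contraction-phase agreement between the analytic series solution
        and the CN solver (within 5% relative radius)."""
        times = np.linspace(0.0, 210.0, 211)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ana = integrate_analytic_trajectory(set1_params, times=times)
        r_num = np.interp(times, cn_set1.times, cn_set1.radii)
        t_min = cn_set1.times[np.argmin(cn_set1.radii)]
        sel = times <= t_min
        rel = np.abs(ana.radii[sel] - r_num[sel]) / r_num[sel]
        assert rel.max() <= 0.05
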
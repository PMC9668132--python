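"""Binned density, welfare, and the family of threshold solvers."""

import numpy as np
import pytest
from scipy import integrate

import rdthresh as rt
from rdthresh.optimize import _uniform_density

C, H = 10.0, 5.0


def affine_curve(late, ted, c=C, h=H, se_const=0.0):
    """Effect curve pi(x) = late + ted*(x-c) with constant SE."""
    return rt.EffectCurve(
        value=lambda x: late + ted * (np.asarray(x, float) - c),
        se=lambda x: np.full_like(np.asarray(x, float), se_const),
        interval=(c - h, c + h),
        source="llr",
    )


class TestDensity:
    def test_manual_tally(self):
        x = np.array([5.1, 5.2, 5.9, 6.3, 6.4, 6.5, 7.9, 9.0, 11.0, 12.5])
        data = rt.RDDataset(x=x, y=np.zeros(10), c=C)
        dens = rt.estimate_density(data, bin_width=1.0, range=(5.0, 13.0))
        np.testing.assert_allclose(
            dens.mass, np.array([3, 3, 1, 0, 1, 0, 1, 1]) / 10.0
        )
        assert dens.mass.sum() == pytest.approx(1.0, abs=1e-12)

    def test_uniform_simulation_bin_masses_within_binomial_error(self):
        data = rt.generate_sharp(
            rt.scenario_preset("canonical", n=50000, sigma=0.0, seed=12)
        )
        k = 25
        dens = rt.estimate_density(data, bin_width=10.0 / k, range=(5.0, 15.0))
        bound = 4 * np.sqrt((1 / k) * (1 - 1 / k) / 50000)
        assert np.max(np.abs(dens.mass - 1 / k)) < bound

    def test_half_open_bins_last_closed(self):
        x = np.array([5.0, 6.0, 7.0, 8.0, 9.0, 11.0, 15.0])
        data = rt.RDDataset(x=x, y=np.zeros(7), c=C)
        dens = rt.estimate_density(data, bin_width=5.0, range=(5.0, 15.0))
        # x = 15 falls in the last (closed) bin
        np.testing.assert_allclose(dens.mass, [5 / 7, 2 / 7])

    def test_empty_range_errors(self):
        data = rt.RDDataset(x=np.array([8.0, 9, 11, 12]), y=np.zeros(4), c=C)
        with pytest.raises(rt.ValidationError, match="no observations"):
            rt.estimate_density(data, range=(100.0, 101.0))


class TestWelfare:
    def test_empty_integral_is_zero(self, canonical_curve, canonical_density):
        assert rt.welfare(canonical_curve, canonical_density, 12.0, upper=12.0) == 0.0

    def test_closed_form_uniform_integral(self):
        # uniform p on [0,20], pi(x) = x-8: integral_8^20 (x-8)/20 dx = 3.6
        curve = affine_curve(2.0, 1.0, c=10.0, h=20.0)
        dens = _uniform_density(0.0, 20.0, n_bins=400)  # width 0.05
        assert rt.welfare(curve, dens, 8.0, upper=20.0) == pytest.approx(3.6, rel=0.01)

    def test_riemann_sum_equals_adaptive_quadrature(self):
        """Sum form vs scipy quadrature of pi*p with piecewise-constant p."""
        rng = np.random.default_rng(3)
        mass = rng.dirichlet(np.ones(30))
        edges = np.linspace(5.0, 15.0, 31)
        dens = rt.BinnedDensity(edges=edges, mass=mass, bin_width=edges[1] - edges[0])
        curve = affine_curve(2.0, 1.0)
        t, upper = 6.37, 14.2
        total = 0.0
        for lo, hi, m in zip(edges[:-1], edges[1:], mass):
            a, b = max(lo, t), min(hi, upper)
            if b > a:
                val, _ = integrate.quad(
                    lambda x: curve.value(np.atleast_1d(x))[0] * m / (hi - lo), a, b
                )
                total += val
        assert rt.welfare(curve, dens, t, upper=upper) == pytest.approx(
            total, abs=1e-9
        )

    def test_fuzzy_with_unit_complier_share_equals_sharp(self, canonical_density):
        sharp = affine_curve(2.0, 1.0)
        fuzzy = rt.EffectCurve(
            value=sharp.value,
            se=sharp.se,
            interval=sharp.interval,
            source="llr",
            design="fuzzy",
            complier_share=lambda x: np.ones_like(np.asarray(x, float)),
        )
        for t in (6.0, 8.0, 10.0, 12.0):
            assert rt.welfare(fuzzy, canonical_density, t, upper=C + H) == pytest.approx(
                rt.welfare(sharp, canonical_density, t, upper=C + H), abs=1e-12
            )


class TestClosedForm:
    def test_direct_substitution(self, synthetic_fits):
        below = synthetic_fits(0.0, 0.5, "below")
        above = synthetic_fits(1.0, 1.0, "above")  # late 1, ted 0.5
        res = rt.optimal_threshold_closed_form(below, above, C, 100.0)
        assert res.value == pytest.approx(8.0)
        assert not res.boundary_hit

    def test_cost_equal_to_late_means_no_move(self, synthetic_fits):
        below = synthetic_fits(0.0, 0.5, "below")
        above = synthetic_fits(2.0, 1.5, "above")
        res = rt.optimal_threshold_closed_form(below, above, C, H, cost=2.0)
        assert res.value == pytest.approx(C)

    def test_zero_cost_is_plain_root_formula_to_machine_precision(
        self, canonical_fits
    ):
        below, above = canonical_fits
        late = rt.estimate_late(below, above).value
        ted = rt.estimate_ted(below, above).value
        res = rt.optimal_threshold_closed_form(below, above, C, H, cost=0.0)
        assert res.value == C - late / ted  # exact same arithmetic path

    def test_equal_slopes_is_undefined_and_boundary(self, synthetic_fits):
        below = synthetic_fits(0.0, 0.5, "below")
        above = synthetic_fits(2.0, 0.5, "above")
        res = rt.optimal_threshold_closed_form(below, above, C, H)
        assert res.flag == "undefined-root" and res.boundary_hit
        assert res.value == C - H  # positive effect: treat everyone in window
        negative = rt.optimal_threshold_closed_form(above, below, C, H)
        assert negative.value == C + H

    def test_clamped_to_window(self, synthetic_fits):
        below = synthetic_fits(0.0, 0.5, "below")
        above = synthetic_fits(10.0, 1.0, "above")  # raw root at c - 20
        res = rt.optimal_threshold_closed_form(below, above, C, H)
        assert res.value == C - H and res.boundary_hit


class TestNumericSolver:
    def test_agrees_with_closed_form_on_canonical_curve(
        self, canonical_fits, canonical_curve, canonical_density
    ):
        below, above = canonical_fits
        closed = rt.optimal_threshold_closed_form(below, above, C, H)
        num = rt.optimal_threshold_numeric(canonical_curve, canonical_density, C, H)
        assert num.value == pytest.approx(closed.value, abs=1e-6 * H)

    def test_flat_positive_curve_hits_left_boundary(self, canonical_density):
        curve = affine_curve(2.0, 0.0)
        res = rt.optimal_threshold_numeric(curve, canonical_density, C, H)
        assert res.value == C - H and res.boundary_hit

    def test_gp_curve_on_noiseless_data_finds_analytic_root(self):
        spec = rt.scenario_preset("canonical", n=400, sigma=0.0, seed=3)
        data = rt.generate_sharp(spec)
        curve = rt.gp_effect_curve(
            rt.fit_gp_side(data, "below", H), rt.fit_gp_side(data, "above", H), C, H
        )
        res = rt.optimal_threshold_numeric(curve, rt.estimate_density(data), C, H)
        assert res.value == pytest.approx(spec.root, abs=0.05)

    def test_argmax_property_on_fine_grid(self, canonical_curve, canonical_density):
        res = rt.optimal_threshold_numeric(canonical_curve, canonical_density, C, H)
        w_star = rt.welfare(canonical_curve, canonical_density, res.value, upper=C + H)
        for t in np.linspace(C - H, C + H, 500):
            assert w_star >= rt.welfare(
                canonical_curve, canonical_density, t, upper=C + H
            ) - 1e-9


class TestConservative:
    def test_zero_variance_limit_equals_optimum(self, canonical_density):
        curve = affine_curve(2.0, 1.0, se_const=0.0)
        star = rt.optimal_threshold_numeric(curve, canonical_density, C, H).value
        res = rt.conservative_threshold(curve, 0.05, C, H, c_star=star)
        assert res.value == pytest.approx(star, abs=1e-9)

    def test_matches_million_point_grid_scan(self, canonical_curve, canonical_density):
        from scipy.stats import norm

        alpha = 0.05
        z = norm.ppf(1 - alpha)
        star = rt.optimal_threshold_numeric(
            canonical_curve, canonical_density, C, H
        ).value
        res = rt.conservative_threshold(canonical_curve, alpha, C, H, c_star=star)
        grid = np.linspace(star, C, 1_000_000)
        g = canonical_curve.value(grid) - z * canonical_curve.se(grid)
        idx = np.argmax(g >= 0)  # first grid point where the bound is safe
        step = grid[1] - grid[0]
        assert abs(res.value - grid[idx]) <= step

    def test_insignificant_late_cannot_move(self, canonical_density):
        curve = affine_curve(0.5, 1.0, se_const=2.0)  # late well inside noise
        res = rt.conservative_threshold(curve, 0.05, C, H)
        assert res.value == C and res.flag == "cannot move"

    def test_ordering_and_monotonicity_in_confidence(
        self, canonical_curve, canonical_density
    ):
        star = rt.optimal_threshold_numeric(
            canonical_curve, canonical_density, C, H
        ).value
        previous = star
        for alpha in (0.2, 0.1, 0.05, 0.01):
            c_alpha = rt.conservative_threshold(
                canonical_curve, alpha, C, H, c_star=star
            ).value
            assert star <= c_alpha <= C
            assert c_alpha >= previous  # more confidence, smaller move
            previous = c_alpha

    def test_invalid_alpha_rejected(self, canonical_curve):
        with pytest.raises(rt.ValidationError):
            rt.conservative_threshold(canonical_curve, 0.7, C, H)


class TestBudget:
    def test_slack_budget_returns_unconstrained_optimum(self, canonical_density):
        curve = affine_curve(2.0, 1.0)
        res, binding = rt.budget_constrained_threshold(
            curve, canonical_density, C, H, population=100, budget=1e9
        )
        assert not binding
        assert res.value == pytest.approx(8.0, abs=1e-6)

    def test_hand_solved_binding_program(self):
        # uniform p on [0,20], N=100, B=25; unconstrained optimum at 8 but
        # treating [8,20] costs 60 subjects; equality at t=15 (mass 0.25)
        curve = affine_curve(2.0, 1.0, c=10.0, h=10.0)
        dens = _uniform_density(0.0, 20.0, n_bins=400)
        res, binding = rt.budget_constrained_threshold(
            curve, dens, 10.0, 10.0, population=100, budget=25.0
        )
        assert binding
        assert res.value == pytest.approx(15.0, abs=1e-6)

    def test_knife_edge_budget_is_feasible_unconstrained(self, canonical_density):
        curve = affine_curve(2.0, 1.0)
        star = rt.optimal_threshold_numeric(curve, canonical_density, C, H).value
        load = 100 * canonical_density.mass_above(star)
        res, binding = rt.budget_constrained_threshold(
            curve, canonical_density, C, H, population=100, budget=load
        )
        assert not binding and res.value == pytest.approx(star, abs=1e-9)

    def test_infeasible_budget_errors(self, canonical_density):
        curve = affine_curve(2.0, 1.0)
        with pytest.raises(rt.ValidationError, match="budget"):
            rt.budget_constrained_threshold(
                curve, canonical_density, C, H, population=1e6, budget=0.0
            )


class TestGains:
    def test_no_move_no_gain(self, canonical_curve, canonical_density, canonical_data):
        rec = rt.policy_gains(
            canonical_curve, canonical_density, canonical_data, C, C
        )
        assert rec.gain_pp == 0.0 and rec.n_affected == 0

    def test_single_bin_direct_substitution(self):
        # one bin centered at 10, effect 1pp, 100 units affected
        dens = rt.BinnedDensity(
            edges=np.array([9.8, 10.2]), mass=np.array([1.0]), bin_width=0.4
        )
        curve = affine_curve(1.0, 0.0)
        x = np.concatenate([np.full(100, 10.0), [5.0, 5.1]])
        data = rt.RDDataset(x=x, y=np.zeros(102), c=9.9)
        rec = rt.policy_gains(curve, dens, data, 9.8, 10.2)
        assert rec.gain_pp == pytest.approx(1.0)
        assert rec.gain_value_per_unit == pytest.approx(0.10)
        assert rec.gain_total == pytest.approx(10.0)
        assert rec.n_affected == 100

    def test_renormalization_makes_gain_an_interval_average(
        self, canonical_curve, canonical_density, canonical_data
    ):
        rec = rt.policy_gains(
            canonical_curve, canonical_density, canonical_data, 8.0, C
        )
        vals = canonical_curve.value(np.linspace(8.0, C, 200))
        assert vals.min() - 0.05 <= rec.gain_pp <= vals.max() + 0.05


class TestCaseLabels:
    @pytest.mark.parametrize(
        "preset,label",
        [("canonical", "canonical"), ("flat_ted", "undefined"), ("adversarial", "adversarial")],
    )
    def test_presets_classify_as_constructed(self, preset, label):
        data = rt.generate_sharp(rt.scenario_preset(preset, n=400, sigma=0.0, seed=2))
        below, above = rt.fit_both_sides(data, H)
        assert rt.classify_case(below, above, tol=1e-9) == label


class TestInvariants:
    def test_shift_equivariance_of_all_thresholds(self):
        delta = 3.7
        data = rt.generate_sharp(rt.scenario_preset("canonical", n=600, seed=14))
        shifted = rt.RDDataset(x=data.x + delta, y=data.y, c=data.c + delta)
        for d, c in ((data, C), (shifted, C + delta)):
            dens = rt.estimate_density(d, range=(c - H, c + H))
            below, above = rt.fit_both_sides(d, H)
            curve = rt.effect_curve(below, above, H)
            star = rt.optimal_threshold_numeric(curve, dens, c, H).value
            cons = rt.conservative_threshold(curve, 0.05, c, H, c_star=star).value
            if c == C:
                base = (star, cons)
            else:
                assert star == pytest.approx(base[0] + delta, abs=1e-8)
                assert cons == pytest.approx(base[1] + delta, abs=1e-8)

    def test_zero_late_with_positive_ted_reads_as_optimal_threshold(self):
        """Simulated with the cutoff already at the effect-curve root: the
        estimated effect at the cutoff is null while its derivative is not —
        the signature of an optimally placed threshold."""
        spec = rt.ScenarioSpec(
            alpha0=2.0, beta0=0.5, alpha1=2.0, beta1=1.5, sigma=1.0, c=C,
            x_range=(5.0, 15.0), n=4000, seed=15,
        )
        below, above = rt.fit_both_sides(rt.generate_sharp(spec), H)
        late = rt.estimate_late(below, above)
        ted = rt.estimate_ted(below, above)
        assert abs(late.value) < 3 * late.se
        assert ted.value > 3 * ted.se
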
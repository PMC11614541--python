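"""Quadratic response surfaces, constrained optima, confidence regions, TPS."""

import numpy as np
import pytest

from nutrigeom.simulate import eval_sextet, sextet_from_optimum
from nutrigeom.surface import (NutrientResponseSurface, ThinPlateSpline,
                               by_correction_constant, by_fdr_alpha, by_fdr_stepup,
                               confidence_region, global_maximum, hull_vertices,
                               in_hull, quadratic_design, tps_landscape)


def triangle_points(rng, n=150):
    """Intake-like design: rays from the origin across a fan of ratios."""
    share = rng.uniform(0.08, 0.92, n)
    radius = rng.uniform(0.05, 1.0, n)
    return np.column_stack([radius * share, radius * (1 - share)])


def grid_max_oracle(beta, points, res=200):
    """Brute-force maximum of the quadratic over the hull: dense grid sweep."""
    verts = hull_vertices(points)
    gp = np.linspace(points[:, 0].min(), points[:, 0].max(), res)
    gc = np.linspace(points[:, 1].min(), points[:, 1].max(), res)
    P, C = np.meshgrid(gp, gc)
    flat = np.column_stack([P.ravel(), C.ravel()])
    inside = in_hull(flat, verts)
    cand = np.vstack([flat[inside], verts])  # grid plus exact vertices
    vals = eval_sextet(np.asarray(beta), cand[:, 0], cand[:, 1])
    i = np.argmax(vals)
    return cand[i], vals[i]


class TestFitSurface:
    def test_noiseless_quadratic_recovered_to_machine_precision(self, rng):
        beta = sextet_from_optimum(0.5, 0.2, 100.0, 200.0, 300.0, 50.0)
        X = triangle_points(rng)
        y = eval_sextet(beta, X[:, 0], X[:, 1])
        fit = NutrientResponseSurface().fit(X, y)
        assert np.allclose(fit.coef_, beta, atol=1e-8)
        assert fit.r_squared_ == pytest.approx(1.0)

    def test_equals_normal_equations_oracle(self, rng):
        X = triangle_points(rng, 40)
        y = rng.normal(size=40)
        fit = NutrientResponseSurface().fit(X, y)
        D = quadratic_design(X)
        beta_ne = np.linalg.solve(D.T @ D, D.T @ y)
        assert np.allclose(fit.coef_, beta_ne, atol=1e-8)

    def test_constant_trait_gives_flat_surface(self, rng):
        X = triangle_points(rng, 60)
        fit = NutrientResponseSurface().fit(X, np.full(60, 7.0))
        assert np.allclose(fit.coef_[1:], 0.0, atol=1e-8)
        assert fit.r_squared_ == pytest.approx(0.0, abs=1e-9)

    def test_collinear_design_names_offending_term(self):
        # points on one rail: P and C proportional, design is rank deficient
        t = np.linspace(0.1, 1, 30)
        X = np.column_stack([t, 2 * t])
        with pytest.raises(np.linalg.LinAlgError, match="collinear"):
            NutrientResponseSurface().fit(X, t)

    def test_too_few_points_rejected(self):
        X = np.array([[0.1, 0.2], [0.3, 0.1], [0.2, 0.2], [0.4, 0.1],
                      [0.1, 0.4], [0.5, 0.2]])
        with pytest.raises(ValueError):
            NutrientResponseSurface().fit(X, np.arange(6.0))


class TestGlobalMaximum:
    def test_interior_concave_matches_closed_form_and_grid(self, rng):
        beta = sextet_from_optimum(0.4, 0.3, 50.0, 100.0, 150.0, 30.0)
        X = triangle_points(rng)
        opt = global_maximum(beta, X)
        assert (opt.p_star, opt.c_star) == pytest.approx((0.4, 0.3), abs=1e-9)
        assert not opt.boundary
        xy_o, val_o = grid_max_oracle(beta, X)
        assert opt.value >= val_o - 1e-9

    def test_saddle_surface_maximum_on_hull_edge(self, rng):
        beta = np.array([1.0, 0.5, -0.2, 2.0, -1.0, 0.3])  # indefinite Hessian
        X = triangle_points(rng)
        opt = global_maximum(beta, X)
        assert opt.boundary
        xy_o, val_o = grid_max_oracle(beta, X, res=400)
        assert opt.value == pytest.approx(val_o, abs=1e-3 * max(1, abs(val_o)))
        assert opt.value >= val_o - 1e-9

    def test_concave_optimum_outside_hull_lands_on_boundary(self, rng):
        beta = sextet_from_optimum(2.0, 2.0, 10.0, 50.0, 50.0, 0.0)  # far outside
        X = triangle_points(rng)
        opt = global_maximum(beta, X)
        assert opt.boundary
        assert in_hull(np.array([[opt.p_star, opt.c_star]]), hull_vertices(X))[0]

    def test_fitted_value_at_optimum_dominates_all_observed_points(self, rng):
        beta = sextet_from_optimum(0.5, 0.17, 135.0, 250.0, 120.0, 50.0)
        X = triangle_points(rng)
        y = eval_sextet(beta, X[:, 0], X[:, 1]) + rng.normal(0, 10, len(X))
        fit = NutrientResponseSurface().fit(X, y)
        opt = global_maximum(fit, X)
        assert opt.value >= fit.predict(X).max() - 1e-9


class TestConfidenceRegion:
    def test_noiseless_fit_collapses_region_to_point(self, rng):
        beta = sextet_from_optimum(0.4, 0.25, 30.0, 60.0, 80.0, 10.0)
        X = triangle_points(rng)
        y = eval_sextet(beta, X[:, 0], X[:, 1])
        fit = NutrientResponseSurface().fit(X, y)
        cr = confidence_region(fit, X, n_sim=200, seed=1)
        spread = np.ptp(cr.optima, axis=0)
        assert np.all(spread < 1e-4)
        assert cr.contains(0.4, 0.25, tol=1e-4)

    def test_region_lies_within_intake_hull(self, rng):
        beta = sextet_from_optimum(0.4, 0.25, 30.0, 60.0, 80.0, 10.0)
        X = triangle_points(rng)
        y = eval_sextet(beta, X[:, 0], X[:, 1]) + rng.normal(0, 5, len(X))
        fit = NutrientResponseSurface().fit(X, y)
        cr = confidence_region(fit, X, n_sim=300, seed=2)
        verts = hull_vertices(X)
        assert in_hull(cr.optima, verts, tol=1e-8).all()
        assert in_hull(cr.polygon, verts, tol=1e-8).all()

    def test_seed_reproducibility_and_retained_fraction(self, rng):
        X = triangle_points(rng)
        y = rng.normal(10, 2, len(X))
        fit = NutrientResponseSurface().fit(X, y)
        a = confidence_region(fit, X, n_sim=100, seed=7)
        b = confidence_region(fit, X, n_sim=100, seed=7)
        assert np.array_equal(a.optima, b.optima)
        assert len(a.retained) == int(np.ceil(0.95 * 100))

    def test_small_nsim_warns(self, rng):
        X = triangle_points(rng)
        y = rng.normal(10, 2, len(X))
        fit = NutrientResponseSurface().fit(X, y)
        with pytest.warns(UserWarning, match="n_sim"):
            confidence_region(fit, X, n_sim=40, seed=3)

    def test_residual_bootstrap_also_covers_point_estimate(self, rng):
        beta = sextet_from_optimum(0.4, 0.25, 30.0, 60.0, 80.0, 10.0)
        X = triangle_points(rng)
        y = eval_sextet(beta, X[:, 0], X[:, 1]) + rng.normal(0, 2, len(X))
        fit = NutrientResponseSurface().fit(X, y)
        cr = confidence_region(fit, X, n_sim=300, seed=4, method="residuals")
        assert cr.contains(*cr.point_estimate, tol=1e-6)


class TestThinPlateSpline:
    def test_zero_smoothing_interpolates_every_point(self, rng):
        X = triangle_points(rng, 40)
        y = rng.normal(size=40)
        spl = ThinPlateSpline(smoothing=0.0).fit(X, y)
        assert np.allclose(spl.predict(X), y, atol=1e-6)

    def test_affine_data_reproduced_exactly_at_any_smoothing(self, rng):
        X = triangle_points(rng, 60)
        y = 2.0 + 3.0 * X[:, 0] - 1.5 * X[:, 1]
        for lam in (0.0, 1e-4, 1e-1, 10.0):
            spl = ThinPlateSpline(smoothing=lam).fit(X, y)
            grid = triangle_points(rng, 30)
            assert np.allclose(spl.predict(grid),
                               2.0 + 3.0 * grid[:, 0] - 1.5 * grid[:, 1], atol=1e-6)

    def test_duplicate_points_averaged(self):
        X = np.array([[0.1, 0.1], [0.1, 0.1], [0.5, 0.2], [0.2, 0.6], [0.4, 0.4]])
        y = np.array([1.0, 3.0, 0.0, 0.0, 0.0])
        spl = ThinPlateSpline(smoothing=0.0).fit(X, y)
        assert spl.predict(np.array([[0.1, 0.1]]))[0] == pytest.approx(2.0, abs=1e-6)

    def test_landscape_peak_approaches_quadratic_optimum_as_noise_shrinks(self, rng):
        beta = sextet_from_optimum(0.45, 0.25, 30.0, 60.0, 80.0, 10.0)
        X = triangle_points(rng, 200)
        y = eval_sextet(beta, X[:, 0], X[:, 1]) + rng.normal(0, 0.05, len(X))
        land = tps_landscape(X, y, grid_resolution=120)
        p, c, _ = land.peak()
        assert (p, c) == pytest.approx((0.45, 0.25), abs=0.05)

    def test_landscape_masks_outside_hull(self, rng):
        X = triangle_points(rng, 50)
        y = rng.normal(size=50)
        land = tps_landscape(X, y, grid_resolution=40)
        flat = np.column_stack([land.grid_p.ravel(), land.grid_c.ravel()])
        outside = ~in_hull(flat, hull_vertices(X))
        assert np.isnan(land.surface.ravel()[outside]).all()


class TestBenjaminiYekutieli:
    def test_single_test_unchanged(self):
        assert by_fdr_alpha(1) == pytest.approx(0.05)

    def test_three_tests_harmonic_constant(self):
        assert by_correction_constant(3) == pytest.approx(11 / 6, abs=1e-12)
        assert by_fdr_alpha(3) == pytest.approx(0.05 / (11 / 6), abs=1e-6)
        assert by_fdr_alpha(3) == pytest.approx(0.02727, abs=1e-4)

    def test_threshold_nonincreasing_in_m(self):
        ts = [by_fdr_alpha(m) for m in range(1, 30)]
        assert np.all(np.diff(ts) < 0)

    def test_stepup_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests
        p = rng.uniform(size=15) ** 2
        mine = by_fdr_stepup(p, alpha=0.05)
        ref = multipletests(p, alpha=0.05, method="fdr_by")[0]
        assert np.array_equal(mine, ref)

    def test_zero_tests_rejected(self):
        with pytest.raises(ValueError):
            by_fdr_alpha(0)
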
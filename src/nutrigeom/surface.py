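"""Second-order nutrient response surfaces and their constrained optima.

The central model regresses a life-history trait on cumulative protein and
carbohydrate intake with linear, quadratic and correlational terms,

    trait ~ b0 + bP*P + bC*C + bPP*P^2 + bCC*C^2 + bPC*P*C ,

then locates the global maximum of the fitted quadratic over the convex hull
of the observed intake points (the region the data actually cover), builds a
simulation-based 95% confidence region for that optimum, and renders the
landscape with a thin-plate-spline smoother.  Model-level significance across
a family of surfaces is adjusted with the Benjamini-Yekutieli false-discovery
procedure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy.spatial import ConvexHull
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .diets import render_ratio

TERM_NAMES = ("intercept", "P", "C", "P^2", "C^2", "P:C")

DEFAULT_CR_SEED = 20241204


def quadratic_design(X: np.ndarray) -> np.ndarray:
    """Design matrix [1, P, C, P^2, C^2, P*C] from (n, 2) intake points."""
    p, c = X[:, 0], X[:, 1]
    return np.column_stack([np.ones_like(p), p, c, p**2, c**2, p * c])


class NutrientResponseSurface(RegressorMixin, BaseEstimator):
    """OLS fit of a trait on the six-term quadratic in (P, C) intake.

    Attributes
    ----------
    coef_ : ndarray (6,)
        (b0, bP, bC, bPP, bCC, bPC).
    cov_ : ndarray (6, 6)
        Coefficient covariance (symmetric PSD).
    bse_, tvalues_, pvalues_ : ndarray (6,)
        Per-term standard errors and t tests.
    r_squared_, f_statistic_, f_pvalue_ : float
        Overall fit statistics (F tests the five slope terms jointly).
    n_ : int
    resid_ : ndarray (n,)
    """

    def __init__(self, trait_name: str = "trait"):
        self.trait_name = trait_name

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        if X.shape[1] != 2:
            raise ValueError("X must have exactly two columns: protein, carbohydrate")
        if X.shape[0] <= 6:
            raise ValueError("need more than 6 observations to fit six terms")
        D = quadratic_design(X)
        rank = np.linalg.matrix_rank(D)
        if rank < 6:
            # name the first term whose removal restores full rank
            for j in range(5, 0, -1):
                if np.linalg.matrix_rank(np.delete(D, j, axis=1)) == rank:
                    raise np.linalg.LinAlgError(
                        f"singular design: term {TERM_NAMES[j]!r} is collinear"
                    )
            raise np.linalg.LinAlgError("singular design")
        res = sm.OLS(y, D).fit()
        self.coef_ = res.params
        self.cov_ = res.cov_params()
        self.bse_ = res.bse
        self.tvalues_ = res.tvalues
        self.pvalues_ = res.pvalues
        r2 = float(res.rsquared)
        self.r_squared_ = r2 if np.isfinite(r2) else 0.0  # constant trait: TSS = 0
        self.f_statistic_ = float(res.fvalue)
        self.f_pvalue_ = float(res.f_pvalue)
        self.df_resid_ = int(res.df_resid)
        self.resid_ = res.resid
        self.resid_sd_ = float(np.sqrt(res.mse_resid))
        self.n_ = int(X.shape[0])
        self.X_ = X
        return self

    def predict(self, X):
        check_is_fitted(self, "coef_")
        X = check_array(X)
        return quadratic_design(X) @ self.coef_

    def summary_dict(self) -> dict:
        check_is_fitted(self, "coef_")
        return {
            "trait": self.trait_name,
            "n": self.n_,
            "coefficients": dict(zip(TERM_NAMES, self.coef_.tolist())),
            "se": dict(zip(TERM_NAMES, self.bse_.tolist())),
            "pvalues": dict(zip(TERM_NAMES, self.pvalues_.tolist())),
            "r_squared": self.r_squared_,
            "f_statistic": self.f_statistic_,
            "f_pvalue": self.f_pvalue_,
        }


# ---------------------------------------------------------------------------
# constrained global maximum


def hull_vertices(points: np.ndarray) -> np.ndarray:
    """Convex-hull vertices of (n, 2) intake points, counter-clockwise."""
    points = np.asarray(points, float)
    if points.shape[0] < 3:
        raise ValueError("need at least 3 intake points for a hull")
    hull = ConvexHull(points)
    return points[hull.vertices]


def in_hull(xy: np.ndarray, vertices: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    """Half-plane membership test against a ccw-ordered vertex polygon."""
    xy = np.atleast_2d(xy)
    v0 = vertices
    v1 = np.roll(vertices, -1, axis=0)
    edge = v1 - v0  # (k, 2)
    rel = xy[:, None, :] - v0[None, :, :]  # (m, k, 2)
    cross = edge[None, :, 0] * rel[:, :, 1] - edge[None, :, 1] * rel[:, :, 0]
    return (cross >= -tol).all(axis=1)


def maximize_quadratic_over_hull(
    betas: np.ndarray, vertices: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Maximize quadratic surfaces over a convex polygon, vectorised over rows.

    Closed-form stationary point when the Hessian is negative definite and
    the point lies inside the hull; otherwise the maximum over the hull edges
    (each edge restriction is a 1-D quadratic).  Returns (xy, value,
    boundary_flag) with shapes (m, 2), (m,), (m,).
    """
    B = np.atleast_2d(np.asarray(betas, float))
    bP, bC = B[:, 1], B[:, 2]
    bPP, bCC, bPC = B[:, 3], B[:, 4], B[:, 5]

    det = 4 * bPP * bCC - bPC**2
    negdef = (bPP < 0) & (det > 0)
    safe_det = np.where(det == 0, 1.0, det)
    xs = np.column_stack([
        (-2 * bCC * bP + bPC * bC) / safe_det,
        (bPC * bP - 2 * bPP * bC) / safe_det,
    ])
    interior_ok = negdef & in_hull(xs, vertices)

    def value_at(xy: np.ndarray) -> np.ndarray:
        p, c = xy[..., 0], xy[..., 1]
        return (B[:, 0] + bP * p + bC * c + bPP * p**2 + bCC * c**2 + bPC * p * c)

    # edge sweep: candidates are both endpoints plus any interior stationary t
    v0 = vertices
    v1 = np.roll(vertices, -1, axis=0)
    best_val = np.full(B.shape[0], -np.inf)
    best_xy = np.zeros((B.shape[0], 2))
    for a, b in zip(v0, v1):
        d = b - a
        a2 = bPP * d[0] ** 2 + bCC * d[1] ** 2 + bPC * d[0] * d[1]
        grad_p = bP + 2 * bPP * a[0] + bPC * a[1]
        grad_c = bC + 2 * bCC * a[1] + bPC * a[0]
        a1 = grad_p * d[0] + grad_c * d[1]
        with np.errstate(divide="ignore", invalid="ignore"):
            t_star = np.where(a2 < 0, -a1 / (2 * a2), np.nan)
        for t in (np.zeros_like(a1), np.ones_like(a1), t_star):
            ok = np.isfinite(t) & (t >= 0) & (t <= 1)
            t = np.where(ok, t, 0.0)
            xy = a[None, :] + t[:, None] * d[None, :]
            val = np.where(ok, value_at(xy), -np.inf)
            better = val > best_val
            best_val = np.where(better, val, best_val)
            best_xy = np.where(better[:, None], xy, best_xy)

    interior_val = value_at(xs)
    use_int = interior_ok & (interior_val >= best_val - 1e-12)
    out_xy = np.where(use_int[:, None], xs, best_xy)
    out_val = np.where(use_int, interior_val, best_val)
    return out_xy, out_val, ~use_int


@dataclass(frozen=True)
class OptimumEstimate:
    """Constrained global maximum of a fitted surface."""

    p_star: float
    c_star: float
    value: float
    ratio: float
    ratio_label: str
    boundary: bool  # True when the optimum sits on the intake-hull edge


def global_maximum(
    fit: NutrientResponseSurface | np.ndarray, intake_points: np.ndarray
) -> OptimumEstimate:
    """Maximize the fitted quadratic over the convex hull of intake points."""
    beta = fit.coef_ if isinstance(fit, NutrientResponseSurface) else np.asarray(fit, float)
    verts = hull_vertices(np.asarray(intake_points, float))
    xy, val, boundary = maximize_quadratic_over_hull(beta, verts)
    p, c = float(xy[0, 0]), float(xy[0, 1])
    ratio = p / c if c > 0 else float("inf")
    return OptimumEstimate(
        p_star=p, c_star=c, value=float(val[0]),
        ratio=ratio, ratio_label=render_ratio(ratio), boundary=bool(boundary[0]),
    )


# ---------------------------------------------------------------------------
# simulation-based confidence region


@dataclass
class ConfidenceRegion:
    """Confidence region for a surface optimum from simulated refits.

    ``optima`` holds every simulated optimum; ``retained`` indexes the central
    ``level`` fraction (depth-ordered by axis-scaled distance from the point
    estimate); ``polygon`` is the convex hull of the retained optima.
    """

    optima: np.ndarray
    retained: np.ndarray
    polygon: np.ndarray
    point_estimate: tuple[float, float]
    level: float
    n_sim: int
    method: str = "coefficients"

    def contains(self, p: float, c: float, tol: float = 1e-9) -> bool:
        if self.polygon.shape[0] < 3:
            return bool(np.allclose(self.polygon.mean(axis=0), (p, c), atol=1e-8))
        return bool(in_hull(np.array([[p, c]]), self.polygon, tol=tol)[0])

    @property
    def area(self) -> float:
        if self.polygon.shape[0] < 3:
            return 0.0
        x, y = self.polygon[:, 0], self.polygon[:, 1]
        return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def confidence_region(
    fit: NutrientResponseSurface,
    intake_points: np.ndarray,
    n_sim: int = 500,
    level: float = 0.95,
    seed: int = DEFAULT_CR_SEED,
    method: str = "coefficients",
) -> ConfidenceRegion:
    """Simulate optima from the fit's sampling distribution and peel to ``level``.

    ``method="coefficients"`` draws coefficient vectors from
    N(coef_, cov_); ``method="residuals"`` resamples residuals onto fitted
    values and refits.  Each draw is maximized over the intake hull; the
    central ``level`` fraction of optima (scaled-distance depth order from the
    point estimate) is retained and returned as its convex-hull polygon.
    """
    check_is_fitted(fit, "coef_")
    if not np.all(np.isfinite(fit.cov_)):
        raise ValueError("degenerate coefficient covariance")
    if n_sim < 50:
        warnings.warn("n_sim < 50 gives a very rough confidence region", stacklevel=2)
    rng = np.random.default_rng(seed)
    pts = np.asarray(intake_points, float)
    verts = hull_vertices(pts)

    if method == "coefficients":
        draws = rng.multivariate_normal(fit.coef_, fit.cov_, size=n_sim, method="svd")
    elif method == "residuals":
        D = quadratic_design(pts)
        pinv = np.linalg.pinv(D)
        fitted = D @ fit.coef_
        idx = rng.integers(0, len(fit.resid_), size=(n_sim, len(fit.resid_)))
        ys = fitted[None, :] + fit.resid_[idx]
        draws = ys @ pinv.T
    else:
        raise ValueError(f"unknown method {method!r}")

    optima, _, _ = maximize_quadratic_over_hull(draws, verts)
    point = global_maximum(fit, pts)
    center = np.array([point.p_star, point.c_star])
    scale = optima.std(axis=0, ddof=1)
    scale[scale == 0] = 1.0
    depth = np.linalg.norm((optima - center) / scale, axis=1)
    keep = int(np.ceil(level * n_sim))
    retained = np.argsort(depth)[:keep]
    kept = optima[retained]
    if np.ptp(kept, axis=0).min() < 1e-12 or kept.shape[0] < 3:
        polygon = kept[:1]
    else:
        polygon = kept[ConvexHull(kept).vertices]
    return ConfidenceRegion(
        optima=optima, retained=retained, polygon=polygon,
        point_estimate=(point.p_star, point.c_star),
        level=level, n_sim=n_sim, method=method,
    )


# ---------------------------------------------------------------------------
# thin-plate-spline landscape


@dataclass
class Landscape:
    """Smoothed (P, C) -> trait grid, masked outside the data hull."""

    grid_p: np.ndarray
    grid_c: np.ndarray
    surface: np.ndarray  # NaN outside the hull
    smoothing: float
    gcv: float | None = None
    _spline: "ThinPlateSpline" = field(default=None, repr=False)

    def peak(self) -> tuple[float, float, float]:
        """(P, C, value) of the highest in-hull grid cell."""
        i = np.nanargmax(self.surface)
        r, c = np.unravel_index(i, self.surface.shape)
        return float(self.grid_p[r, c]), float(self.grid_c[r, c]), float(self.surface[r, c])


class ThinPlateSpline:
    """2-D thin-plate-spline smoother with GCV-selected smoothing.

    Solves the penalised interpolation problem with kernel r^2 log r and an
    affine null space; ``smoothing=0`` interpolates the (duplicate-averaged)
    data exactly, and affine data are reproduced exactly at any smoothing.
    """

    def __init__(self, smoothing: float | None = None):
        self.smoothing = smoothing

    @staticmethod
    def _kernel(r: np.ndarray) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            out = r**2 * np.log(r)
        return np.where(r > 0, out, 0.0)

    def fit(self, points: np.ndarray, values: np.ndarray) -> "ThinPlateSpline":
        pts = np.asarray(points, float)
        y = np.asarray(values, float)
        # collapse duplicate locations by averaging before solving
        key = np.round(pts, 12)
        uniq, inv = np.unique(key, axis=0, return_inverse=True)
        if uniq.shape[0] < pts.shape[0]:
            sums = np.zeros(uniq.shape[0])
            counts = np.zeros(uniq.shape[0])
            np.add.at(sums, inv, y)
            np.add.at(counts, inv, 1.0)
            pts, y = uniq, sums / counts
        n = pts.shape[0]
        if n < 3:
            raise ValueError("need at least 3 distinct points")
        r = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
        K = self._kernel(r)
        T = np.column_stack([np.ones(n), pts])
        Q, R = np.linalg.qr(T, mode="complete")
        Q1, Q2 = Q[:, :3], Q[:, 3:]
        M = Q2.T @ K @ Q2
        M = (M + M.T) / 2
        d, U = np.linalg.eigh(M)
        d = np.clip(d, 0.0, None)  # bending energy is conditionally PSD
        z = U.T @ (Q2.T @ y)

        if self.smoothing is None:
            lams = np.concatenate([[0.0], np.geomspace(1e-10, 1e2, 49)])
            best = (np.inf, 0.0)
            for lam in lams:
                gcv = self._gcv(lam, n, d, z)
                if gcv < best[0]:
                    best = (gcv, lam)
            self.gcv_, self.smoothing_ = best
        else:
            self.smoothing_ = float(self.smoothing)
            self.gcv_ = self._gcv(self.smoothing_, n, d, z)

        lam = self.smoothing_
        w = U @ (z / (d + n * lam + 1e-300))
        c = Q2 @ w
        a = np.linalg.solve(R[:3, :3], Q1.T @ (y - K @ c - n * lam * c))
        self.points_, self.coef_, self.poly_ = pts, c, a
        return self

    @staticmethod
    def _gcv(lam: float, n: int, d: np.ndarray, z: np.ndarray) -> float:
        if lam == 0.0:
            return np.inf if np.all(d > 0) else np.inf  # GCV undefined at exact interpolation
        shrink = n * lam / (d + n * lam)
        rss = float(np.sum((shrink * z) ** 2))
        denom = (3 + float(np.sum(1.0 - shrink)))  # effective df of the smoother
        return n * rss / max(n - denom, 1e-12) ** 2

    def predict(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, float))
        r = np.linalg.norm(pts[:, None, :] - self.points_[None, :, :], axis=-1)
        return self._kernel(r) @ self.coef_ + np.column_stack(
            [np.ones(pts.shape[0]), pts]) @ self.poly_


def tps_landscape(
    intake_points: np.ndarray,
    trait_values: np.ndarray,
    grid_resolution: int = 60,
    smoothing: float | None = None,
) -> Landscape:
    """Thin-plate-spline landscape of a trait over the intake hull.

    ``smoothing=None`` selects the penalty by generalized cross-validation;
    predictions outside the convex hull of the data are masked (NaN).
    """
    pts = np.asarray(intake_points, float)
    if pts.shape[0] < 10:
        raise ValueError("need at least 10 points for a landscape")
    spl = ThinPlateSpline(smoothing=smoothing).fit(pts, trait_values)
    verts = hull_vertices(pts)
    gp = np.linspace(pts[:, 0].min(), pts[:, 0].max(), grid_resolution)
    gc = np.linspace(pts[:, 1].min(), pts[:, 1].max(), grid_resolution)
    P, C = np.meshgrid(gp, gc)
    flat = np.column_stack([P.ravel(), C.ravel()])
    z = spl.predict(flat)
    z[~in_hull(flat, verts)] = np.nan
    return Landscape(grid_p=P, grid_c=C, surface=z.reshape(P.shape),
                     smoothing=spl.smoothing_, gcv=spl.gcv_, _spline=spl)


# ---------------------------------------------------------------------------
# multiplicity control


def by_correction_constant(m: int) -> float:
    """Benjamini-Yekutieli constant c(m) = sum_{i=1..m} 1/i."""
    if m < 1:
        raise ValueError("need at least one test")
    return float(np.sum(1.0 / np.arange(1, m + 1)))


def by_fdr_alpha(m: int, alpha: float = 0.05) -> float:
    """Adjusted per-family threshold alpha / c(m) for the B-Y step-up rule."""
    return alpha / by_correction_constant(m)


def by_fdr_stepup(pvalues, alpha: float = 0.05) -> np.ndarray:
    """Benjamini-Yekutieli step-up decisions (True = significant)."""
    p = np.asarray(pvalues, float)
    m = p.size
    if m == 0:
        raise ValueError("need at least one p-value")
    order = np.argsort(p)
    thresh = np.arange(1, m + 1) / m * by_fdr_alpha(m, alpha)
    below = p[order] <= thresh
    reject = np.zeros(m, dtype=bool)
    if below.any():
        k = np.max(np.flatnonzero(below))
        reject[order[: k + 1]] = True
    return reject
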
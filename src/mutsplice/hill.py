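"""Cooperativity analysis: Hill dose-response fits with profile-likelihood CIs.

Gradual knockdown / overexpression of a splicing regulator traces out a
dose-response curve of splicing change (deltaPSI) versus relative protein
level x (untreated = 1).  A sigmoidal, decreasing Hill function

    y(x) = y_max - (y_max - y_min) * x^nH / (x^nH + EC50^nH)

is fitted by minimising the chi-square cost sum_i ((y_i - y(x_i)) / sigma_i)^2
within box constraints, and per-parameter 95% confidence intervals are
obtained by profile likelihood: each parameter is scanned on a grid, the
remaining parameters re-optimised at every grid point, and the interval is
bounded by the crossings of chi2(theta_0) + chi2(0.95, df=1) = chi2_0 + 3.841.

A large Hill coefficient nH indicates switch-like, cooperative regulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import chi2 as chi2_dist
from sklearn.base import BaseEstimator

__all__ = ["HillParams", "HillFit", "hill_curve", "HillCurveFitter", "fit_hill"]

PARAM_NAMES = ("y_min", "y_max", "ec50", "n_h")

#: Default fitting box: deltaPSI bounds are fractions, EC50 a relative
#: protein level, nH dimensionless (nH >= 1 excludes anti-cooperativity).
DEFAULT_BOUNDS = {
    "y_min": (-0.5, 0.0),
    "y_max": (0.0, 0.5),
    "ec50": (0.1, 2.0),
    "n_h": (1.0, 20.0),
}

#: Wider box used during profiling (the likelihood may support parameter
#: values beyond the fitting box; profiling against the fitting box would
#: truncate the CI at an arbitrary boundary).
RELAXED_BOUNDS = {
    "y_min": (-1.0, 0.0),
    "y_max": (0.0, 1.0),
    "ec50": (0.01, 10.0),
    "n_h": (1.0, 200.0),
}


@dataclass(frozen=True)
class HillParams:
    """Hill curve parameters: floor, ceiling, half-response level, steepness."""

    y_min: float
    y_max: float
    ec50: float
    n_h: float

    def __post_init__(self) -> None:
        if self.y_min > self.y_max:
            raise ValueError("y_min must not exceed y_max")
        if self.ec50 <= 0:
            raise ValueError("EC50 must be positive")

    def as_array(self) -> np.ndarray:
        return np.array([self.y_min, self.y_max, self.ec50, self.n_h])


@dataclass
class HillFit:
    """Result of a bounded chi-square Hill fit."""

    params: HillParams
    chi2: float
    ci: dict = field(default_factory=dict)          # name -> (lo, hi)
    ci_flags: dict = field(default_factory=dict)    # name -> (lo_open, hi_open)
    profiles: dict = field(default_factory=dict)    # name -> (grid, chi2 values)


def hill_curve(x, params: HillParams) -> np.ndarray:
    """Evaluate the decreasing Hill curve at protein level(s) ``x >= 0``."""
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("protein levels must be non-negative")
    xn = np.power(x, params.n_h)
    return params.y_max - (params.y_max - params.y_min) * xn / (xn + params.ec50 ** params.n_h)


def _hill_vec(x, theta):
    y_min, y_max, ec50, n_h = theta
    xn = np.power(x, n_h)
    return y_max - (y_max - y_min) * xn / (xn + ec50 ** n_h)


class HillCurveFitter(BaseEstimator):
    """Bounded chi-square Hill regression with multi-start optimisation.

    Parameters
    ----------
    bounds : dict, optional
        Per-parameter ``(low, high)`` boxes; defaults to the standard
        fitting box (y_min in [-0.5, 0], y_max in [0, 0.5], EC50 in
        [0.1, 2], nH in [1, 20]).
    n_starts : int
        Number of seeded optimisation starts; the best chi-square wins.
    alpha : float
        Confidence level used by :meth:`profile_ci`.
    relax_profile_bounds : bool
        Profile CIs beyond the fitting box (default), so that intervals are
        not truncated at the box edge.
    random_state : int or None
        Seed for the multi-start draws.

    Attributes
    ----------
    params_ : HillParams
        Best-fit parameters.
    chi2_ : float
        Residual cost at the optimum.
    fit_ : HillFit
        Full fit record (populated with CIs after :meth:`profile_ci`).
    """

    def __init__(self, bounds=None, n_starts: int = 20, alpha: float = 0.95,
                 relax_profile_bounds: bool = True, random_state=None):
        self.bounds = bounds
        self.n_starts = n_starts
        self.alpha = alpha
        self.relax_profile_bounds = relax_profile_bounds
        self.random_state = random_state

    # -- internal ---------------------------------------------------------
    def _box(self):
        box = dict(DEFAULT_BOUNDS)
        if self.bounds:
            box.update(self.bounds)
        lo = np.array([box[n][0] for n in PARAM_NAMES])
        hi = np.array([box[n][1] for n in PARAM_NAMES])
        return lo, hi

    @staticmethod
    def _validate(x, y, sigma):
        x = np.asarray(x, dtype=float).ravel()
        y = np.asarray(y, dtype=float).ravel()
        if sigma is None:
            sigma = np.ones_like(y)
        sigma = np.broadcast_to(np.asarray(sigma, dtype=float), y.shape).copy()
        if x.shape != y.shape:
            raise ValueError("x and y must have the same length")
        if len(x) < 5:
            raise ValueError("at least 5 dose points are required")
        if np.any(sigma <= 0):
            raise ValueError("all sigma must be positive")
        return x, y, sigma

    def _minimise(self, x, y, sigma, lo, hi, theta0):
        res = least_squares(
            lambda th: (y - _hill_vec(x, th)) / sigma,
            x0=np.clip(theta0, lo, hi),
            bounds=(lo, hi),
            method="trf",
            xtol=1e-12, ftol=1e-12, gtol=1e-12,
        )
        return res.x, float(res.cost * 2.0)  # cost is 0.5 * sum(resid^2)

    def _starts(self, x, y, lo, hi, rng):
        # data-driven start: plateaus from the extreme observations,
        # EC50 near mid-range x, moderate steepness
        guess = np.array([min(y.min(), 0.0), max(y.max(), 0.0),
                          float(np.sqrt(x.min() * x.max())), 4.0])
        starts = [guess]
        for _ in range(max(0, self.n_starts - 1)):
            u = rng.uniform(size=4)
            th = lo + u * (hi - lo)
            # log-uniform draws for the scale-like parameters
            th[2] = np.exp(np.log(lo[2]) + u[2] * (np.log(hi[2]) - np.log(lo[2])))
            th[3] = np.exp(np.log(lo[3]) + u[3] * (np.log(hi[3]) - np.log(lo[3])))
            starts.append(th)
        return starts

    # -- API --------------------------------------------------------------
    def fit(self, x, y, sigma=None):
        """Fit the Hill curve to dose points ``(x, y)`` with SDs ``sigma``."""
        x, y, sigma = self._validate(x, y, sigma)
        lo, hi = self._box()
        rng = np.random.default_rng(self.random_state)
        best_theta, best_chi2 = None, np.inf
        for theta0 in self._starts(x, y, lo, hi, rng):
            theta, c2 = self._minimise(x, y, sigma, lo, hi, theta0)
            if c2 < best_chi2 - 1e-12:
                best_theta, best_chi2 = theta, c2
        self.params_ = HillParams(*best_theta)
        self.chi2_ = best_chi2
        self.on_boundary_ = bool(
            np.any(np.isclose(best_theta, lo)) or np.any(np.isclose(best_theta, hi))
        )
        self.fit_ = HillFit(params=self.params_, chi2=self.chi2_)
        self._data = (x, y, sigma)
        return self

    def predict(self, x):
        return hill_curve(x, self.params_)

    def profile_ci(self, n_grid: int = 61, span: float = 4.0, names=None):
        """Profile-likelihood CIs for all four parameters.

        For each parameter a grid is scanned around the optimum (log-spaced
        for EC50 and nH, linear for the plateaus), the other three
        parameters are re-optimised at each grid value, and the CI endpoints
        are the interpolated crossings of ``chi2_0 + chi2(alpha, 1)``.
        Endpoints that never cross inside the scan range are reported at the
        scan boundary and flagged open.
        """
        if not hasattr(self, "params_"):
            raise RuntimeError("fit() must be called before profile_ci()")
        x, y, sigma = self._data
        threshold = self.chi2_ + float(chi2_dist.ppf(self.alpha, df=1))
        if self.relax_profile_bounds:
            box = dict(RELAXED_BOUNDS)
        else:
            lo, hi = self._box()
            box = {n: (lo[i], hi[i]) for i, n in enumerate(PARAM_NAMES)}
        theta_hat = self.params_.as_array()

        for j, name in enumerate(PARAM_NAMES):
            if names is not None and name not in names:
                continue
            blo, bhi = box[name]
            centre = theta_hat[j]
            if name in ("ec50", "n_h"):
                g_lo = np.geomspace(max(blo, centre / span), max(centre, blo * 1.0001), n_grid)
                g_hi = np.geomspace(centre, min(bhi, centre * span), n_grid)
            else:
                width = span * max(0.05, abs(centre))
                g_lo = np.linspace(max(blo, centre - width), centre, n_grid)
                g_hi = np.linspace(centre, min(bhi, centre + width), n_grid)
            grid = np.unique(np.concatenate([g_lo, g_hi]))
            prof = np.empty_like(grid)
            others = [i for i in range(4) if i != j]
            lo_o = np.array([box[PARAM_NAMES[i]][0] for i in others])
            hi_o = np.array([box[PARAM_NAMES[i]][1] for i in others])
            th_start = theta_hat[others]
            for k, val in enumerate(grid):
                def resid(th_o, val=val):
                    full = np.empty(4)
                    full[j] = val
                    full[others] = th_o
                    return (y - _hill_vec(x, full)) / sigma
                res = least_squares(resid, np.clip(th_start, lo_o, hi_o),
                                    bounds=(lo_o, hi_o), method="trf",
                                    xtol=1e-10, ftol=1e-10)
                prof[k] = 2.0 * res.cost
            # keep profiles anchored: ensure the optimum's grid point equals chi2_
            lo_end, lo_open = _crossing(grid, prof, threshold, centre, side="lo")
            hi_end, hi_open = _crossing(grid, prof, threshold, centre, side="hi")
            self.fit_.ci[name] = (lo_end, hi_end)
            self.fit_.ci_flags[name] = (lo_open, hi_open)
            self.fit_.profiles[name] = (grid, prof)
        return self.fit_.ci


def _crossing(grid, prof, threshold, centre, side):
    """Interpolated crossing of the profile with the CI threshold."""
    if side == "lo":
        mask = grid <= centre
        g, p = grid[mask], prof[mask]
        g, p = g[::-1], p[::-1]  # walk away from the optimum
    else:
        mask = grid >= centre
        g, p = grid[mask], prof[mask]
    above = np.nonzero(p > threshold)[0]
    if len(above) == 0:
        return (float(g[-1]) if len(g) else float(centre)), True
    k = above[0]
    if k == 0:
        return float(g[0]), False
    # linear interpolation between the last point below and first above
    g0, g1, p0, p1 = g[k - 1], g[k], p[k - 1], p[k]
    t = (threshold - p0) / (p1 - p0) if p1 != p0 else 0.0
    return float(g0 + t * (g1 - g0)), False


def fit_hill(points, bounds=None, n_starts: int = 20, alpha: float = 0.95,
             random_state=None, profile: bool = True) -> HillFit:
    """Fit a Hill curve to dose-response points and (optionally) profile CIs.

    ``points`` is an iterable of objects or tuples with fields ``x``
    (relative protein level), ``y`` (deltaPSI) and ``sigma`` (SD of y).
    """
    xs, ys, ss = [], [], []
    for pt in points:
        if hasattr(pt, "x"):
            xs.append(pt.x); ys.append(pt.y); ss.append(pt.sigma)
        else:
            x_, y_, s_ = pt
            xs.append(x_); ys.append(y_); ss.append(s_)
    est = HillCurveFitter(bounds=bounds, n_starts=n_starts, alpha=alpha,
                          random_state=random_state)
    est.fit(np.array(xs), np.array(ys), np.array(ss))
    if profile:
        est.profile_ci()
    return est.fit_
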
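"""Fractile construction of a von Neumann-Morgenstern utility function.

The fractile method anchors utility at the extremes of the tested reward
range — u(0.1 ml) = 0, u(1.2 ml) = 1 — and bisects the utility axis with
equiprobable gambles built from previously measured certainty equivalents
(CEs).  The CE of the full-range gamble earns utility 0.5; gambles between
an anchor and that CE earn 0.25 and 0.75; further bisection of the outer
subintervals yields 0.125, 0.875 and, with edge refinement, 0.063 and
0.938, for seven to nine points per session.

The points are fit with a weakly increasing piecewise cubic (a cubic
spline whose three interior knots are placed freely by least squares), the
marginal utility is its first derivative, and out-of-sample validity is
checked by Deming regression of measured against predicted CE utilities,
with and without the linear expected-value component removed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline
from scipy.optimize import brentq, minimize

from .gambles import Gamble
from .pest import PESTConfig, PESTExhaustedError, run_pest

__all__ = [
    "UtilityFunction",
    "FractileNode",
    "DemingFit",
    "expected_utility",
    "certainty_equivalent",
    "build_fractile_schedule",
    "run_fractile",
    "agent_ce_oracle",
    "fit_utility",
    "average_sessions",
    "marginal_utility",
    "interval_marginal_utility",
    "deming_regression",
    "validate_out_of_sample",
    "sample_validation_gambles",
]

_MONO_GRID = 200  # grid points at which the fitted slope is constrained >= 0


class UtilityFunction:
    """Monotone piecewise-cubic utility on a fixed volume domain.

    Defined by its knots (three interior plus the two domain endpoints)
    and the knot utilities; the curve is the cubic spline through those
    points, affinely renormalized so u(lo) = 0 and u(hi) = 1.
    """

    def __init__(self, knots_x, knots_y, domain: tuple[float, float]):
        knots_x = np.asarray(knots_x, dtype=float)
        knots_y = np.asarray(knots_y, dtype=float)
        lo, hi = map(float, domain)
        if knots_x[0] != lo or knots_x[-1] != hi:
            raise ValueError("knots must span the domain")
        if np.any(np.diff(knots_x) <= 0):
            raise ValueError("knots must be strictly increasing")
        if knots_y[-1] <= knots_y[0]:
            raise ValueError("utility must rise over the domain")
        # renormalize endpoints to 0/1 (cardinal utility is affine-free)
        knots_y = (knots_y - knots_y[0]) / (knots_y[-1] - knots_y[0])
        self.knots_x = knots_x
        self.knots_y = knots_y
        self.domain = (lo, hi)
        self._spline = CubicSpline(knots_x, knots_y, bc_type="not-a-knot")
        self._deriv = self._spline.derivative()

    def _check(self, x) -> np.ndarray:
        lo, hi = self.domain
        x = np.asarray(x, dtype=float)
        if np.any(x < lo - 1e-9) or np.any(x > hi + 1e-9):
            raise ValueError(f"volume outside domain [{lo}, {hi}] ml")
        return np.clip(x, lo, hi)

    def __call__(self, x):
        v = self._spline(self._check(x))
        return float(v) if np.isscalar(x) else np.asarray(v)

    def derivative(self, x):
        """Marginal utility du/dx (util/ml), floored at 0."""
        d = np.maximum(self._deriv(self._check(x)), 0.0)
        return float(d) if np.isscalar(x) else np.asarray(d)

    def inverse(self, level: float) -> float:
        """Volume whose utility equals ``level`` (monotone root-finding)."""
        lo, hi = self.domain
        if not -1e-9 <= level <= 1 + 1e-9:
            raise ValueError("utility level outside [0, 1]")
        level = min(max(level, 0.0), 1.0)
        f = lambda x: self._spline(x) - level
        if f(lo) >= 0:
            return lo
        if f(hi) <= 0:
            return hi
        return float(brentq(f, lo, hi, xtol=1e-12))

    def expected_utility(self, g: Gamble) -> float:
        return expected_utility(g, self)

    def certainty_equivalent(self, g: Gamble) -> float:
        return certainty_equivalent(g, self)

    def to_dict(self) -> dict:
        return {"knots_x": self.knots_x.tolist(),
                "knots_y": self.knots_y.tolist(),
                "domain": list(self.domain)}

    @classmethod
    def from_dict(cls, d: dict) -> "UtilityFunction":
        return cls(d["knots_x"], d["knots_y"], tuple(d["domain"]))

    @classmethod
    def linear(cls, domain: tuple[float, float] = (0.1, 1.2),
               n_interior: int = 3) -> "UtilityFunction":
        x = np.linspace(*domain, n_interior + 2)
        return cls(x, (x - domain[0]) / (domain[1] - domain[0]), domain)


def expected_utility(g: Gamble, u) -> float:
    """EU(g) = sum_i p_i * u(x_i)."""
    vals = [u(x) for x in g.outcomes]
    return float(np.dot(vals, g.probabilities))


def certainty_equivalent(g: Gamble, u, full_output: bool = False):
    """Safe volume at choice indifference: the x with u(x) = EU(g).

    Unique whenever u is strictly increasing at the target level; on a
    flat segment the midpoint of the level set is returned and flagged.
    """
    eu = expected_utility(g, u)
    if not -1e-9 <= eu <= 1 + 1e-9:
        raise ValueError("expected utility outside [0, 1]")
    lo, hi = u.domain
    f = lambda x: u(x) - eu
    if f(lo) >= -1e-12:
        ce, flat = lo, False
    elif f(hi) <= 1e-12:
        ce, flat = hi, False
    else:
        ce = float(brentq(f, lo, hi, xtol=1e-12))
        flat = u.derivative(ce) < 1e-9
        if flat:
            grid = np.linspace(lo, hi, 4001)
            level_set = grid[np.abs(np.array([u(x) for x in grid]) - eu) < 1e-9]
            if level_set.size:
                ce = float((level_set.min() + level_set.max()) / 2.0)
    if full_output:
        return ce, flat
    return ce


# --------------------------------------------------------------------------
# Fractile schedule

@dataclass(frozen=True)
class FractileNode:
    """One bisection step: a gamble between the volumes previously mapped
    to ``lo_level`` and ``hi_level``; its CE earns the mean level."""

    lo_level: float
    hi_level: float
    depth: int

    @property
    def level(self) -> float:
        return (self.lo_level + self.hi_level) / 2.0

    @property
    def label(self) -> float:
        """Utility level rounded half-up to 3 decimals (1/16 -> 0.063)."""
        return float(np.floor(self.level * 1000 + 0.5) / 1000)


def build_fractile_schedule(depth: int = 3, edge_refinement: bool = True
                            ) -> list[FractileNode]:
    """Level-order bisection schedule on the utility axis.

    Depth 1 is the full-range gamble (level 0.5); each further depth
    bisects the outermost subintervals, and edge refinement adds one more
    bisection at each edge (levels 1/16 and 15/16).  Depth 3 with
    refinement yields CE levels {0.063, 0.125, 0.25, 0.5, 0.75, 0.875,
    0.938}, which with the two anchors gives nine utility points.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    nodes = [FractileNode(0.0, 1.0, 1)]
    low, high = 0.5, 0.5
    for d in range(2, depth + 1):
        nodes.append(FractileNode(0.0, low, d))
        nodes.append(FractileNode(high, 1.0, d))
        low, high = low / 2.0, (high + 1.0) / 2.0
    if edge_refinement:
        nodes.append(FractileNode(0.0, low, depth + 1))
        nodes.append(FractileNode(high, 1.0, depth + 1))
    return nodes


def run_fractile(ce_oracle, schedule: list[FractileNode],
                 repeats: int = 3,
                 rng: np.random.Generator | int | None = None,
                 domain: tuple[float, float] = (0.1, 1.2),
                 session_id: int = 0) -> pd.DataFrame:
    """Collect (volume, utility) points by walking the fractile schedule.

    ``ce_oracle(gamble, rng) -> ce_ml`` measures one CE (e.g. one PEST
    sequence).  Each node is measured ``repeats`` times and the mean CE
    seeds descendant gambles.  Anchor points are appended.  A staircase
    exhaustion propagates, tagged with the failing node's level.
    """
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    rng = rng if isinstance(rng, np.random.Generator) \
        else np.random.default_rng(rng)
    lo, hi = domain
    volume_at = {0.0: lo, 1.0: hi}
    rows = []
    for node in schedule:
        g = Gamble.even(volume_at[node.lo_level], volume_at[node.hi_level])
        try:
            ces = [float(ce_oracle(g, rng)) for _ in range(repeats)]
        except PESTExhaustedError as err:
            raise PESTExhaustedError(
                f"staircase exhausted at fractile level {node.label}: {err}"
            ) from err
        volume_at[node.level] = float(np.mean(ces))
        rows.append({"volume_ml": volume_at[node.level],
                     "utility": node.level, "level_label": node.label,
                     "session_id": session_id, "n_repeats": repeats})
    for level in (0.0, 1.0):
        rows.append({"volume_ml": volume_at[level], "utility": level,
                     "level_label": level, "session_id": session_id,
                     "n_repeats": 0})
    return pd.DataFrame(rows).sort_values("volume_ml").reset_index(drop=True)


def agent_ce_oracle(agent, config: PESTConfig | None = None,
                    max_attempts: int = 3):
    """CE oracle measuring one PEST sequence per call against an agent.

    A staircase that hits the trial cap without converging is re-run from
    a fresh random start (as an experimenter would re-run a failed
    sequence), up to ``max_attempts`` times before the exhaustion
    propagates.
    """
    from .agent import choose

    cfg = config or PESTConfig()

    def oracle(gamble: Gamble, rng: np.random.Generator) -> float:
        for _ in range(max_attempts):
            res = run_pest(gamble, lambda s, g: choose(s, g, agent, rng),
                           cfg, seed=rng)
            if res.converged:
                return res.ce
        raise PESTExhaustedError(
            f"no convergence in {max_attempts} attempts of "
            f"{cfg.max_trials} trials")

    return oracle


# --------------------------------------------------------------------------
# Monotone piecewise-cubic fit

def _spline_from_params(theta: np.ndarray, lo: float, hi: float,
                        n_knots: int) -> tuple[np.ndarray, np.ndarray]:
    kx = np.concatenate([[lo], np.sort(theta[:n_knots]), [hi]])
    ky = theta[n_knots:]
    return kx, ky


def fit_utility(points: pd.DataFrame | np.ndarray,
                n_interior_knots: int = 3,
                domain: tuple[float, float] = (0.1, 1.2),
                n_starts: int = 5, seed: int = 0) -> UtilityFunction:
    """Least-squares monotone cubic-spline fit of utility points.

    Three interior knots are placed freely on the volume axis; the fit
    minimizes squared error at the data points subject to a nonnegative
    slope at 200 evenly spaced grid points, with multistart (jittered
    knot positions) to avoid local minima.  The result is renormalized so
    the endpoints map to 0 and 1.
    """
    if isinstance(points, pd.DataFrame):
        x = points["volume_ml"].to_numpy(dtype=float)
        y = points["utility"].to_numpy(dtype=float)
    else:
        pts = np.asarray(points, dtype=float)
        x, y = pts[:, 0], pts[:, 1]
    if x.size < 5:
        raise ValueError("need at least 5 utility points")
    if np.ptp(x) <= 0:
        raise ValueError("utility points must span a range of volumes")
    lo, hi = domain
    m = n_interior_knots
    grid = np.linspace(lo, hi, _MONO_GRID)
    gap = (hi - lo) / (4.0 * (m + 1))  # minimum knot separation

    def objective(theta):
        kx, ky = _spline_from_params(theta, lo, hi, m)
        if np.any(np.diff(kx) < gap / 4):
            return 1e6
        s = CubicSpline(kx, ky, bc_type="not-a-knot")
        return float(np.sum((s(x) - y) ** 2))

    def mono_constraint(theta):
        kx, ky = _spline_from_params(theta, lo, hi, m)
        if np.any(np.diff(kx) <= 0):
            return np.full(_MONO_GRID, -1.0)
        s = CubicSpline(kx, ky, bc_type="not-a-knot")
        return s.derivative()(grid)

    def knot_gaps(theta):
        kx = np.concatenate([[lo], np.sort(theta[:m]), [hi]])
        return np.diff(kx) - gap

    rng = np.random.default_rng(seed)
    even = np.linspace(lo, hi, m + 2)[1:-1]
    order = np.argsort(x)
    best, best_val = None, np.inf
    for start in range(n_starts):
        kx0 = even if start == 0 else np.sort(
            np.clip(even + rng.normal(0, 0.1 * (hi - lo), m),
                    lo + gap, hi - gap))
        ky0 = np.interp(np.concatenate([[lo], kx0, [hi]]),
                        x[order], y[order])
        theta0 = np.concatenate([kx0, ky0])
        res = minimize(
            objective, theta0, method="SLSQP",
            constraints=[{"type": "ineq", "fun": mono_constraint},
                         {"type": "ineq", "fun": knot_gaps}],
            options={"maxiter": 200, "ftol": 1e-12})
        if res.fun < best_val and np.all(mono_constraint(res.x) > -1e-6):
            best, best_val = res.x, res.fun
    if best is None:
        raise RuntimeError("monotone spline fit failed for every start")
    kx, ky = _spline_from_params(best, lo, hi, m)
    # clip marginal constraint slack so the returned curve is weakly increasing
    ky = np.maximum.accumulate(ky)
    if ky[-1] <= ky[0]:
        raise ValueError("fitted utility is flat over the whole domain")
    return UtilityFunction(kx, ky, domain)


def average_sessions(fits: list[UtilityFunction],
                     grid: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pointwise mean and sample SD of session fits on an evaluation grid."""
    if len(fits) < 2:
        raise ValueError("need at least two session fits")
    domains = {f.domain for f in fits}
    if len(domains) > 1:
        raise ValueError(f"mismatched domains: {domains}")
    vals = np.vstack([f(grid) for f in fits])
    return vals.mean(axis=0), vals.std(axis=0, ddof=1)


def marginal_utility(u, x):
    """Marginal utility dU/dx of the fitted function (util/ml)."""
    return u.derivative(x)


def interval_marginal_utility(u, x_from: float, x_to: float) -> float:
    """Average slope of u between two volumes (chord slope, util/ml)."""
    if not x_from < x_to:
        raise ValueError("need x_from < x_to")
    return (u(x_to) - u(x_from)) / (x_to - x_from)


# --------------------------------------------------------------------------
# Deming regression (errors in both variables) and out-of-sample validation

@dataclass(frozen=True)
class DemingFit:
    slope: float
    intercept: float
    variance_ratio: float
    slope_se: float
    slope_ci: tuple[float, float]
    n: int


def _deming_slope(x: np.ndarray, y: np.ndarray, delta: float) -> float:
    sxx = np.var(x, ddof=1)
    syy = np.var(y, ddof=1)
    sxy = np.cov(x, y, ddof=1)[0, 1]
    if abs(sxy) < 1e-15:
        return 0.0 if syy <= delta * sxx else np.inf
    return (syy - delta * sxx
            + np.sqrt((syy - delta * sxx) ** 2 + 4 * delta * sxy ** 2)
            ) / (2 * sxy)


def deming_regression(x, y, variance_ratio: float = 1.0) -> DemingFit:
    """Errors-in-both-variables straight-line fit.

    ``variance_ratio`` is the ratio of y-error to x-error variance (1 =
    orthogonal regression, which makes axis swapping return the
    reciprocal slope).  The slope CI is a 95% jackknife interval.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need at least 3 paired points")
    slope = _deming_slope(x, y, variance_ratio)
    intercept = float(np.mean(y) - slope * np.mean(x))
    n = x.size
    loo = np.array([_deming_slope(np.delete(x, i), np.delete(y, i),
                                  variance_ratio) for i in range(n)])
    loo = loo[np.isfinite(loo)]
    if loo.size >= 3 and np.isfinite(slope):
        se = float(np.sqrt((loo.size - 1) / loo.size
                           * np.sum((loo - loo.mean()) ** 2)))
    else:
        se = np.nan
    ci = (slope - 1.959964 * se, slope + 1.959964 * se) \
        if np.isfinite(se) else (np.nan, np.nan)
    return DemingFit(float(slope), intercept, variance_ratio, se, ci, n)


def validate_out_of_sample(u: UtilityFunction, gambles: list[Gamble],
                           measured_ces) -> tuple[DemingFit, DemingFit]:
    """Out-of-sample check of the fitted utility on held-out gambles.

    Regresses the utilities of the behaviorally measured CEs on the
    predicted expected utilities (Deming, variance ratio 1), then repeats
    after removing each gamble's linear expected-value component from both
    axes — the residual fit isolates the predictive power of the
    curvature.
    """
    if len(gambles) < 3:
        raise ValueError("need at least 3 held-out gambles")
    lo, hi = u.domain
    predicted = np.array([expected_utility(g, u) for g in gambles])
    measured = np.array([u(ce) for ce in measured_ces])
    ev_component = np.array([(g.expected_value - lo) / (hi - lo)
                             for g in gambles])
    full = deming_regression(predicted, measured)
    resid = deming_regression(predicted - ev_component,
                              measured - ev_component)
    return full, resid


def sample_validation_gambles(n: int = 12,
                              domain: tuple[float, float] = (0.1, 1.2),
                              rng: np.random.Generator | int | None = None,
                              min_spread: float = 0.15) -> list[Gamble]:
    """Held-out two-outcome equiprobable gambles spanning the domain."""
    rng = rng if isinstance(rng, np.random.Generator) \
        else np.random.default_rng(rng)
    lo, hi = domain
    out = []
    for _ in range(n):
        a = rng.uniform(lo, hi - min_spread)
        b = rng.uniform(a + min_spread, hi)
        out.append(Gamble.even(a, b))
    return out
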
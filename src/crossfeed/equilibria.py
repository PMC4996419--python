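"""Fixed points, stability, and collapse boundaries of the cross-feeding model.

The model has up to five fixed points: the origin (global extinction), one
monoculture point on each axis, and zero, one or two interior (coexistence)
points.  Two bifurcations bound the coexistence branch as the supplementation
level ``a`` varies: a saddle-node at low ``a`` where the stable coexistence
point and an interior saddle are born together (onset of mutualism
viability), and a transcritical collision with the X axis at high ``a``
(competitive exclusion of the slower strain).  Both are located here by
bisection on the existence of a stable interior equilibrium.

Interior points are found by eliminating X: the X balance condition gives
``X(Y) = 1 - c*Y - delta / (r_x * g_x(Y + a))``, and substituting into the Y
balance condition leaves a scalar residual in Y whose sign changes are scanned
on a fine grid and polished by Brent's method.  Brute but exhaustive at this
problem size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .errors import BracketingError
from .model import ModelParams, PopulationState, monoculture_equilibrium, rhs_xy

__all__ = [
    "EquilibriumPoint",
    "BifurcationDiagram",
    "jacobian",
    "jacobian_eigen",
    "find_equilibria",
    "has_stable_interior",
    "saddle_node_point",
    "exclusion_threshold",
    "bifurcation_scan",
]

logger = logging.getLogger(__name__)

#: residual tolerance every returned fixed point must satisfy
RESIDUAL_TOL = 1e-9
#: stability decided on eigenvalue real parts with this tolerance
STABILITY_TOL = 1e-10
#: default number of grid points for the interior scan in Y
INTERIOR_GRID = 10_000


@dataclass(frozen=True)
class EquilibriumPoint:
    """A fixed point with its linearization.

    ``eigenvalues`` are ordered slow-first (largest real part first), matching
    the early-warning usage: for a stable point the slow eigenvalue is the one
    closest to zero and controls the asymptotic relaxation rate.
    ``eigenvectors`` holds the matching unit-norm directions as columns.
    """

    state: PopulationState
    kind: str  # 'origin' | 'x_axis' | 'y_axis' | 'interior'
    eigenvalues: tuple  # (slow, fast), possibly complex
    eigenvectors: np.ndarray = field(repr=False)
    stable: bool

    @property
    def slow_eigenvalue(self):
        return self.eigenvalues[0]

    @property
    def fast_eigenvalue(self):
        return self.eigenvalues[1]

    @property
    def slow_eigenvector(self) -> np.ndarray:
        return self.eigenvectors[:, 0]


def jacobian(X: float, Y: float, p: ModelParams) -> np.ndarray:
    """Analytic Jacobian of the vector field at (X, Y)."""
    sx = Y + p.a  # nutrient pool seen by X
    sy = p.beta * X + p.a  # nutrient pool seen by Y
    gx = sx / (sx + p.kappa)
    gy = sy / (sy + p.kappa)
    dgx = p.kappa / (sx + p.kappa) ** 2  # d g_x / dY
    dgy = p.beta * p.kappa / (sy + p.kappa) ** 2  # d g_y / dX
    lx = 1.0 - X - p.c * Y
    ly = 1.0 - p.c * X - Y
    return np.array(
        [
            [p.r_x * gx * (lx - X) - p.delta, p.r_x * X * (dgx * lx - p.c * gx)],
            [p.r_y * Y * (dgy * ly - p.c * gy), p.r_y * gy * (ly - Y) - p.delta],
        ]
    )


def jacobian_eigen(state: PopulationState, params: ModelParams):
    """Jacobian plus its eigen-decomposition, slow eigenpair first.

    Returns ``(J, eigenvalues, eigenvectors)`` with eigenvalues sorted by
    decreasing real part (ties broken by imaginary part for determinism) and
    unit-norm eigenvectors as matching columns.
    """
    J = jacobian(state.X, state.Y, params)
    w, V = np.linalg.eig(J)
    order = np.lexsort((w.imag, -w.real))
    w = w[order]
    V = V[:, order]
    V = V / np.linalg.norm(V, axis=0, keepdims=True)
    if np.all(np.abs(w.imag) == 0):
        w = w.real
        V = V.real
    return J, (w[0], w[1]), V


def _interior_states(p: ModelParams, n_grid: int = INTERIOR_GRID):
    """All interior fixed points (X, Y) with both densities positive."""

    def x_of_y(Y):
        gx = (Y + p.a) / (Y + p.a + p.kappa)
        if gx <= 0.0:
            return np.nan
        return 1.0 - p.c * Y - p.delta / (p.r_x * gx)

    def resid(Y):
        # Y-balance residual with the Monod denominator cleared: same roots
        # for physical (positive-pool) states, but polynomial-smooth where
        # the raw quotient would blow up at unphysical negative X
        X = x_of_y(Y)
        pool = p.beta * X + p.a
        return p.r_y * pool * (1.0 - p.c * X - Y) - p.delta * (pool + p.kappa)

    ys = np.linspace(1e-9, 1.0 - 1e-9, n_grid)
    with np.errstate(divide="ignore", invalid="ignore"):
        gx = (ys + p.a) / (ys + p.a + p.kappa)
        xs = 1.0 - p.c * ys - p.delta / (p.r_x * gx)
        pool = p.beta * xs + p.a
        vals = p.r_y * pool * (1.0 - p.c * xs - ys) - p.delta * (pool + p.kappa)
    roots = []
    sign_change = np.isfinite(vals[:-1]) & np.isfinite(vals[1:]) & (vals[:-1] * vals[1:] < 0)
    for i in np.flatnonzero(sign_change):
        y_root = brentq(resid, ys[i], ys[i + 1], xtol=1e-14, rtol=8.9e-16)
        x_root = x_of_y(y_root)
        # the elimination is only meaningful where both densities are
        # genuinely positive; axis collisions are represented by axis points
        if x_root > 1e-9 and y_root > 1e-9:
            if not any(abs(y_root - yr) < 1e-9 for _, yr in roots):
                roots.append((x_root, y_root))
    # also catch exact zeros sitting on grid nodes (measure-zero, cheap guard)
    return roots


def _make_point(X: float, Y: float, kind: str, p: ModelParams) -> EquilibriumPoint:
    state = PopulationState(X, Y)
    _, w, V = jacobian_eigen(state, p)
    stable = bool(np.real(w[0]) < STABILITY_TOL and np.real(w[1]) < STABILITY_TOL)
    return EquilibriumPoint(state=state, kind=kind, eigenvalues=w, eigenvectors=V, stable=stable)


def find_equilibria(params: ModelParams, n_grid: int = INTERIOR_GRID):
    """All fixed points of the model, each with eigen-data.

    Always includes the origin; includes an axis point per strain whose
    monoculture equilibrium is positive; includes every interior point found
    by the scan-and-bisect elimination.  An empty interior set is a valid
    outcome (below the saddle-node, or beyond exclusion).
    """
    pts = [_make_point(0.0, 0.0, "origin", params)]
    xm = monoculture_equilibrium(params, "x")
    if xm > 0.0:
        pts.append(_make_point(xm, 0.0, "x_axis", params))
    ym = monoculture_equilibrium(params, "y")
    if ym > 0.0:
        pts.append(_make_point(0.0, ym, "y_axis", params))
    for X, Y in _interior_states(params, n_grid):
        pts.append(_make_point(X, Y, "interior", params))
    for pt in pts:
        res = rhs_xy(pt.state.X, pt.state.Y, params)
        if max(abs(res[0]), abs(res[1])) > RESIDUAL_TOL:
            logger.warning(
                "fixed point %s at (%.3g, %.3g) has residual %.2g",
                pt.kind, pt.state.X, pt.state.Y, max(abs(res[0]), abs(res[1])),
            )
    return pts


def has_stable_interior(params: ModelParams, n_grid: int = INTERIOR_GRID) -> bool:
    """Whether a stable coexistence (both strains positive) equilibrium exists."""
    return any(
        pt.stable for pt in find_equilibria(params, n_grid) if pt.kind == "interior"
    )


def _bisect_on_predicate(params, bracket, predicate, tol):
    a_lo, a_hi = bracket
    p_lo = predicate(params.replace(a=a_lo))
    p_hi = predicate(params.replace(a=a_hi))
    if p_lo == p_hi:
        raise BracketingError(
            f"predicate is {p_lo} at both bracket ends ({a_lo}, {a_hi}); "
            "no transition to bisect"
        )
    while a_hi - a_lo > tol:
        mid = 0.5 * (a_lo + a_hi)
        if predicate(params.replace(a=mid)) == p_lo:
            a_lo = mid
        else:
            a_hi = mid
    return 0.5 * (a_lo + a_hi)


def saddle_node_point(params: ModelParams, bracket=(0.05, 0.15),
                      tol: float = 1e-8, n_grid: int = INTERIOR_GRID) -> float:
    """Supplementation level a* where stable coexistence first appears.

    Below a* the mutualism cannot persist at any density; at a* a stable
    coexistence point and an interior saddle are born together and the slow
    eigenvalue of the coexistence point crosses zero (critical slowing down).
    Located by bisection on "a stable interior equilibrium exists" to
    ``|a_hi - a_lo| <= tol``; returns the bracket midpoint.
    """
    return _bisect_on_predicate(
        params, bracket, lambda q: has_stable_interior(q, n_grid), tol
    )


def exclusion_threshold(params: ModelParams, bracket=(0.23, 0.9),
                        tol: float = 1e-8, n_grid: int = INTERIOR_GRID) -> float:
    """Supplementation level above which the slower strain is excluded.

    The coexistence point collides transcritically with the X-axis
    monoculture point: the Y density of the stable interior equilibrium goes
    to zero continuously and beyond the threshold the stable attractor has
    Y = 0.  Bisection on the same predicate as the saddle-node, expected true
    at the low end and false at the high end.
    """
    return _bisect_on_predicate(
        params, bracket, lambda q: has_stable_interior(q, n_grid), tol
    )


@dataclass
class BifurcationDiagram:
    """Equilibria on a grid of supplementation levels plus located boundaries.

    ``boundaries`` maps labels (saddle_node, x_viability, y_viability,
    exclusion) to critical ``a`` values; only transitions actually bracketed
    by the grid appear.
    """

    a_grid: np.ndarray
    points: list  # list (per a) of list[EquilibriumPoint]
    boundaries: dict

    def as_frame(self) -> pd.DataFrame:
        rows = []
        for a, pts in zip(self.a_grid, self.points):
            for pt in pts:
                rows.append(
                    {
                        "a": a,
                        "kind": pt.kind,
                        "X": pt.state.X,
                        "Y": pt.state.Y,
                        "stable": pt.stable,
                        "eig_slow": np.real(pt.slow_eigenvalue),
                        "eig_fast": np.real(pt.fast_eigenvalue),
                    }
                )
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.as_frame().to_csv(path, index=False)

    def boundary_summary(self) -> dict:
        return {k: float(v) for k, v in sorted(self.boundaries.items(), key=lambda kv: kv[1])}


def bifurcation_scan(params: ModelParams, a_grid, n_grid: int = INTERIOR_GRID,
                     tol: float = 1e-8) -> BifurcationDiagram:
    """Equilibria at every grid level plus bisected boundary locations.

    Boundaries are refined between the bracketing grid points: the
    saddle-node and exclusion thresholds on the stable-interior predicate,
    the two monoculture viability thresholds on positivity of the closed-form
    monoculture equilibrium.  The stable coexistence total density is checked
    for monotonicity between boundaries and violations are logged, not raised.
    """
    a_grid = np.asarray(a_grid, dtype=float)
    if a_grid.size < 2 or np.any(np.diff(a_grid) <= 0):
        raise BracketingError("a_grid must be increasing with at least 2 points")
    points = [find_equilibria(params.replace(a=a), n_grid) for a in a_grid]

    boundaries = {}
    stable_int = np.array(
        [any(pt.stable and pt.kind == "interior" for pt in pts) for pts in points]
    )
    flips = np.flatnonzero(stable_int[:-1] != stable_int[1:])
    for i in flips:
        bracket = (a_grid[i], a_grid[i + 1])
        try:
            a_c = _bisect_on_predicate(params, bracket, has_stable_interior, tol)
        except BracketingError:
            continue
        label = "saddle_node" if stable_int[i + 1] else "exclusion"
        boundaries[label] = a_c
    for strain, label in (("x", "x_viability"), ("y", "y_viability")):
        viable = np.array(
            [monoculture_equilibrium(params.replace(a=a), strain) > 0 for a in a_grid]
        )
        flips = np.flatnonzero(viable[:-1] != viable[1:])
        for i in flips:
            a_c = _bisect_on_predicate(
                params,
                (a_grid[i], a_grid[i + 1]),
                lambda q, s=strain: monoculture_equilibrium(q, s) > 0,
                tol,
            )
            boundaries[label] = a_c

    # coexistence total density should grow with supplementation between
    # boundaries; violations would indicate a finder defect
    ns = np.array(
        [
            max(
                (pt.state.n for pt in pts if pt.stable and pt.kind == "interior"),
                default=np.nan,
            )
            for pts in points
        ]
    )
    ok = np.isfinite(ns)
    if np.any(np.diff(ns[ok]) < -1e-6):
        logger.warning("stable coexistence density is not monotone in a")

    return BifurcationDiagram(a_grid=a_grid, points=points, boundaries=boundaries)
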
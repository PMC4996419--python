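"""Four-strain invasion extension: can cheaters break the mutualism?

Alongside the two single-producer auxotrophs X (Trp-, leaks leucine) and Y
(Leu-, leaks tryptophan), two natural invaders are modeled: a double
producer D that makes both amino acids (self-sufficient, but pays for it
with a lower maximal growth rate and gains nothing from supplementation)
and a non-producer N that makes neither (faster-growing, but completely
dependent on amino acids from the medium or from producers).  All four
strains share one carrying capacity.

Nutrient pools: tryptophan (used by X and N) is ``w*(Y + D) + a``; leucine
(used by Y and N) is ``beta*X + w_beta*D + a``.  D grows logistically with
death and no nutrient dependence; N needs both pools at once.

Along the supplementation axis three zones emerge: at low ``a`` the double
producer takes over (it alone shrugs off the famine), at intermediate ``a``
the cross-feeding pair repels both invaders, and at high ``a`` the
non-producer invades and ultimately dominates (cooperation buys nothing once
the medium is rich).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .equilibria import find_equilibria
from .errors import InvalidParameterError
from .model import ModelParams

__all__ = ["FourStrainParams", "four_strain_rhs", "invasion_scan", "InvasionScan"]

STRAINS = ("X", "Y", "D", "N")


@dataclass(frozen=True)
class FourStrainParams:
    """Two-strain base parameters plus invader rates and production weights.

    The rate ordering ``r_d < r_y < r_x < r_n`` encodes the cost of producing
    both amino acids and the savings of producing none.  The default
    ``r_d = 0.6`` is chosen so the double producer's cost actually exceeds
    what cross-feeding earns the pair at coexistence (``r_d`` must stay below
    ``r_x * g_x`` at the co-culture equilibrium, at most ~0.82 here, for a
    non-invadable intermediate zone to exist at all); ``r_n = 1.05`` gives the
    non-producer a modest edge.  Production weights ``w``/``w_beta`` scale the
    double producer's contribution to each pool.
    """

    base: ModelParams = field(default_factory=ModelParams)
    r_d: float = 0.6
    r_n: float = 1.05
    w: float = 1.0
    w_beta: float = 1.0

    def __post_init__(self):
        if self.r_d <= 0 or self.r_n <= 0:
            raise InvalidParameterError("invader rates must be > 0")
        if not (self.r_d < self.base.r_y < self.base.r_x < self.r_n):
            raise InvalidParameterError(
                "rate ordering r_d < r_y < r_x < r_n is required "
                f"(got r_d={self.r_d}, r_y={self.base.r_y}, "
                f"r_x={self.base.r_x}, r_n={self.r_n})"
            )
        if self.w < 0 or self.w_beta < 0:
            raise InvalidParameterError("production weights must be >= 0")


def four_strain_rhs(state, fp: FourStrainParams) -> np.ndarray:
    """Time derivatives for densities (X, Y, D, N)."""
    X, Y, D, N = state
    p = fp.base
    n_tot = X + Y + D + N
    room = 1.0 - n_tot
    pool_trp = fp.w * (Y + D) + p.a
    pool_leu = p.beta * X + fp.w_beta * D + p.a
    g_trp = pool_trp / (pool_trp + p.kappa)
    g_leu = pool_leu / (pool_leu + p.kappa)
    return np.array(
        [
            p.r_x * X * g_trp * room - p.delta * X,
            p.r_y * Y * g_leu * room - p.delta * Y,
            fp.r_d * D * room - p.delta * D,
            fp.r_n * N * g_trp * g_leu * room - p.delta * N,
        ]
    )


@dataclass
class InvasionScan:
    """Equilibrium densities of all four strains along the supplementation axis."""

    a_grid: np.ndarray
    densities: np.ndarray  # shape (len(a_grid), 4), columns per STRAINS
    outcomes: list  # per-a dict: invader -> 'invaded' | 'repelled' | 'unresolved'
    zones: list  # per-a zone name

    def as_frame(self) -> pd.DataFrame:
        rows = []
        for i, a in enumerate(self.a_grid):
            for j, s in enumerate(STRAINS):
                rows.append({"a": a, "strain": s, "density": self.densities[i, j]})
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.as_frame().to_csv(path, index=False)


def _pair_attractor(p: ModelParams):
    pts = find_equilibria(p, n_grid=4000)
    interior = [q for q in pts if q.kind == "interior" and q.stable]
    if interior:
        st = interior[0].state
        return st.X, st.Y
    return 0.2, 0.2  # generic co-culture inoculum when no coexistence exists


def _zone(dens, inoculum, success_fold, ext_tol=1e-6):
    X, Y, D, N = dens
    if N > max(X, Y, D):
        return "non_producer"
    if D > success_fold * inoculum and D >= N:
        return "double_producer"
    if X > ext_tol and Y > ext_tol and D < inoculum and N < inoculum:
        return "resistant_pair"
    return "mixed"


def invasion_scan(
    fp: FourStrainParams,
    a_grid,
    inoculum: float = 1e-4,
    t_end: float = 2000.0,
    success_fold: float = 10.0,
    failure_fold: float = 0.1,
) -> InvasionScan:
    """Introduce rare invaders at the pair's attractor and integrate long.

    For each supplementation level the two-strain co-culture equilibrium (or
    a generic inoculum when none exists) is seeded with both invaders at
    ``inoculum`` and integrated to ``t_end``.  An invader ending above
    ``success_fold`` times its inoculum has invaded; below ``failure_fold``
    times it was repelled; in between the point is flagged unresolved.
    """
    a_grid = np.asarray(a_grid, dtype=float)
    if np.any(np.diff(a_grid) <= 0):
        raise ValueError("a_grid must be strictly increasing")
    dens = np.empty((a_grid.size, 4))
    outcomes = []
    zones = []
    for i, a in enumerate(a_grid):
        p = fp.base.replace(a=float(a))
        fpa = FourStrainParams(base=p, r_d=fp.r_d, r_n=fp.r_n, w=fp.w,
                               w_beta=fp.w_beta)
        X0, Y0 = _pair_attractor(p)
        z0 = np.array([max(X0, inoculum), max(Y0, inoculum), inoculum, inoculum])
        sol = solve_ivp(
            lambda t, z: four_strain_rhs(np.maximum(z, 0.0), fpa),
            (0.0, t_end), z0, method="LSODA", rtol=1e-8, atol=1e-12,
        )
        final = np.maximum(sol.y[:, -1], 0.0)
        dens[i] = final
        out = {}
        for j, s in ((2, "D"), (3, "N")):
            if final[j] > success_fold * inoculum:
                out[s] = "invaded"
            elif final[j] < failure_fold * inoculum:
                out[s] = "repelled"
            else:
                out[s] = "unresolved"
        outcomes.append(out)
        zones.append(_zone(final, inoculum, success_fold))
    return InvasionScan(a_grid=a_grid, densities=dens, outcomes=outcomes, zones=zones)
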
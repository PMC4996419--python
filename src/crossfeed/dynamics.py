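"""Deterministic trajectories, daily-dilution maps, fate grids and
relaxation diagnostics.

The continuous model is integrated with an adaptive stiff-capable solver;
densities are snapped to zero (with an event stop, then resumed) once they
fall below an extinction threshold, which prevents underflow chatter near the
absorbing axes.  The daily-dilution map emulates the batch protocol the
experiments actually use: grow for ``t_day`` with no death, then divide both
densities by the dilution factor.  Iterating this map is the batch analogue
of the continuous model with an effective death rate ``ln(D) / t_day``.

Relaxation diagnostics quantify the early-warning anisotropy: near the
saddle-node the slow eigenvector is radial (total density ``n`` relaxes
slowly at fixed ratio ``f``), near exclusion it is the constant-``n``
direction (``f`` relaxes slowly).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .equilibria import find_equilibria, jacobian_eigen
from .errors import CrossfeedError, IntegrationError
from .model import ModelParams, PopulationState, rhs_xy

__all__ = [
    "Trajectory",
    "integrate_continuous",
    "batch_dilution_map",
    "run_batch_protocol",
    "batch_equilibrium",
    "fate_grid",
    "relaxation_diagnostics",
]

#: densities below this are snapped to exactly zero during integration
EXTINCTION_SNAP = 1e-10
#: a trajectory endpoint within this distance of a stable fixed point
#: determines its terminal fate
FATE_TOL = 1e-4

DEFAULT_T_END = 500.0
#: default growth-period length of one batch day, ln(10)/0.5 ~ 4.605.
#: Chosen so the protocol's effective death rate ln(dilution)/t_day equals
#: the continuous model's default dilution death rate delta = 0.5 -- the
#: daily map then shares the continuous model's regime topology.  A
#: nutrient-saturated monoculture can complete ~6.6 doublings in such a day,
#: comfortably above the log2(10) ~ 3.3 needed to outpace ten-fold dilution.
DEFAULT_T_DAY = math.log(10.0) / 0.5


@dataclass
class Trajectory:
    """A sampled trajectory with derived observables.

    ``terminal_fate`` is one of coexistence / extinction / exclusion_x /
    exclusion_y / unresolved, where ``exclusion_x`` means strain X was
    excluded (Y persists) and vice versa.
    """

    t: np.ndarray
    X: np.ndarray
    Y: np.ndarray
    terminal_fate: str = "unresolved"

    @property
    def n(self) -> np.ndarray:
        return self.X + self.Y

    @property
    def f(self) -> np.ndarray:
        """Strain ratio X/Y; NaN wherever Y = 0."""
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(self.Y > 0, self.X / np.where(self.Y > 0, self.Y, 1.0), np.nan)

    def final_state(self) -> PopulationState:
        return PopulationState(float(self.X[-1]), float(self.Y[-1]))

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"t": self.t, "X": self.X, "Y": self.Y, "n": self.n, "f": self.f}
        )

    def to_csv(self, path) -> None:
        self.as_frame().to_csv(path, index=False)


def _integrate_raw(p: ModelParams, x0: float, y0: float, t_span, t_eval,
                   rtol: float = 1e-9, atol: float = 1e-12):
    """Piecewise integration with extinction snapping at 1e-10."""

    def field_fn(t, z):
        return rhs_xy(z[0], z[1], p)

    def ext_x(t, z):
        return z[0] - EXTINCTION_SNAP

    def ext_y(t, z):
        return z[1] - EXTINCTION_SNAP

    ext_x.terminal = ext_y.terminal = True
    ext_x.direction = ext_y.direction = -1.0

    t0, t1 = t_span
    z = np.array([x0, y0], dtype=float)
    # a variable already at zero stays at zero; disable its event
    ts_out, xs_out, ys_out = [], [], []
    while True:
        events = []
        if z[0] > EXTINCTION_SNAP:
            events.append(ext_x)
        if z[1] > EXTINCTION_SNAP:
            events.append(ext_y)
        eval_mask = (t_eval >= t0 - 1e-12) & (t_eval <= t1 + 1e-12)
        sol = solve_ivp(
            field_fn, (t0, t1), z, method="LSODA", rtol=rtol, atol=atol,
            t_eval=t_eval[eval_mask], events=events or None, dense_output=False,
        )
        if not sol.success:
            raise IntegrationError(
                f"integration failed at t={sol.t[-1] if sol.t.size else t0}: "
                f"{sol.message}",
                last_state=PopulationState(*np.maximum(sol.y[:, -1], 0.0))
                if sol.t.size else PopulationState(*np.maximum(z, 0.0)),
            )
        sol_y = np.asarray(sol.y, dtype=float)
        if sol_y.size == 0:
            sol_y = np.empty((2, 0))
        ts_out.append(np.asarray(sol.t, dtype=float))
        xs_out.append(sol_y[0])
        ys_out.append(sol_y[1])
        if sol.status != 1:  # reached t1 without an extinction event
            if sol_y.shape[1]:
                z = np.maximum(sol_y[:, -1], 0.0)
            break
        # resume from the earliest event, snapping the crossing variable to 0
        t0 = float(min(te[0] for te in sol.t_events if te.size))
        for te, ye in zip(sol.t_events, sol.y_events):
            if te.size:
                z = np.array(ye[0], dtype=float)
        z[z <= EXTINCTION_SNAP * (1 + 1e-9)] = 0.0
        z = np.maximum(z, 0.0)
        if t0 >= t1 - 1e-12:
            break
    t = np.concatenate(ts_out) if ts_out else np.array([])
    X = np.concatenate(xs_out) if xs_out else np.array([])
    Y = np.concatenate(ys_out) if ys_out else np.array([])
    # de-duplicate sample points possibly repeated across segments
    if t.size:
        keep = np.concatenate([[True], np.diff(t) > 0])
        t, X, Y = t[keep], X[keep], Y[keep]
    X = np.where(X < EXTINCTION_SNAP, 0.0, X)
    Y = np.where(Y < EXTINCTION_SNAP, 0.0, Y)
    return t, np.maximum(X, 0.0), np.maximum(Y, 0.0), z


def _classify_fate(p: ModelParams, x: float, y: float) -> str:
    for pt in find_equilibria(p, n_grid=4000):
        if not pt.stable:
            continue
        if math.hypot(x - pt.state.X, y - pt.state.Y) < FATE_TOL:
            return {
                "origin": "extinction",
                "interior": "coexistence",
                "x_axis": "exclusion_y",
                "y_axis": "exclusion_x",
            }[pt.kind]
    return "unresolved"


def integrate_continuous(
    params: ModelParams,
    initial: PopulationState,
    t_end: float = DEFAULT_T_END,
    dt_out: float = 1.0,
    rtol: float = 1e-9,
    atol: float = 1e-12,
) -> Trajectory:
    """Integrate the continuous model and classify the terminal fate."""
    if t_end <= 0:
        raise ValueError("t_end must be > 0")
    t_eval = np.arange(0.0, t_end + 0.5 * dt_out, dt_out)
    t_eval = t_eval[t_eval <= t_end]
    t, X, Y, zfin = _integrate_raw(params, initial.X, initial.Y, (0.0, t_end),
                                   t_eval, rtol, atol)
    if t.size == 0 or t[-1] < t_end - 1e-9:
        # extinction events can end sampling early; pad with the absorbed state
        t_pad = t_eval[t_eval > (t[-1] if t.size else -np.inf)]
        t = np.concatenate([t, t_pad])
        X = np.concatenate([X, np.full(t_pad.size, max(zfin[0], 0.0))])
        Y = np.concatenate([Y, np.full(t_pad.size, max(zfin[1], 0.0))])
    fate = _classify_fate(params, float(X[-1]), float(Y[-1]))
    return Trajectory(t=t, X=X, Y=Y, terminal_fate=fate)


def batch_dilution_map(
    params: ModelParams,
    state: PopulationState,
    dilution_factor: float = 10.0,
    t_day: float = DEFAULT_T_DAY,
    rtol: float = 1e-9,
    atol: float = 1e-12,
) -> PopulationState:
    """One day of batch growth followed by dilution.

    The death rate is forced to zero within the day -- in the batch protocol
    dilution IS the death process -- and both densities are divided by the
    dilution factor at the day boundary.
    """
    if dilution_factor <= 1:
        raise ValueError("dilution_factor must be > 1")
    grown = grow_one_day(params, state, t_day, rtol, atol)
    return PopulationState(grown.X / dilution_factor, grown.Y / dilution_factor)


def grow_one_day(params: ModelParams, state: PopulationState,
                 t_day: float = DEFAULT_T_DAY, rtol: float = 1e-9,
                 atol: float = 1e-12) -> PopulationState:
    """Within-day growth (no death, no dilution)."""
    p_day = params.replace(delta=0.0)
    t_eval = np.array([0.0, t_day])
    _, X, Y, zfin = _integrate_raw(p_day, state.X, state.Y, (0.0, t_day),
                                   t_eval, rtol, atol)
    return PopulationState(float(max(zfin[0], 0.0)), float(max(zfin[1], 0.0)))


def run_batch_protocol(
    params: ModelParams,
    initial: PopulationState,
    days: int,
    dilution_factor: float = 10.0,
    t_day: float = DEFAULT_T_DAY,
):
    """End-of-day (pre-dilution) states over a serial-dilution experiment.

    Returns a list of length ``days``; entry ``d`` is the measured state at
    the end of growth day ``d+1``, i.e. what spectrophotometry and flow
    cytometry would see just before the next dilution.
    """
    out = []
    state = initial
    for _ in range(days):
        grown = grow_one_day(params, state, t_day)
        out.append(grown)
        state = PopulationState(grown.X / dilution_factor, grown.Y / dilution_factor)
    return out


def batch_equilibrium(
    params: ModelParams,
    initial: PopulationState,
    dilution_factor: float = 10.0,
    t_day: float = DEFAULT_T_DAY,
    max_days: int = 300,
    tol: float = 1e-10,
) -> PopulationState:
    """Fixed point of the daily map reached from ``initial``.

    Iterates until the end-of-day state changes by less than ``tol`` (sup
    norm) or ``max_days`` is exhausted; returns the end-of-day (pre-dilution)
    state, the quantity the plate reader actually measures.
    """
    state = initial
    prev = None
    for _ in range(max_days):
        grown = grow_one_day(params, state, t_day)
        if prev is not None and max(abs(grown.X - prev.X), abs(grown.Y - prev.Y)) < tol:
            return grown
        prev = grown
        state = PopulationState(grown.X / dilution_factor, grown.Y / dilution_factor)
    return prev if prev is not None else initial


def fate_grid(
    params: ModelParams,
    n_values,
    f_values,
    t_end: float = DEFAULT_T_END,
) -> pd.DataFrame:
    """Terminal fate for every (initial total density, initial ratio) cell.

    Near the saddle-node, populations that start too small or too imbalanced
    are fated to extinction while balanced, sufficiently large ones coexist.
    Returns a tidy frame with columns n0, f0, fate.
    """
    n_values = np.asarray(n_values, dtype=float)
    f_values = np.asarray(f_values, dtype=float)
    if np.any(n_values <= 0) or np.any(f_values <= 0):
        raise ValueError("n and f grids must be positive")
    rows = []
    for n0 in n_values:
        for f0 in f_values:
            traj = integrate_continuous(
                params, PopulationState.from_nf(n0, f0), t_end=t_end, dt_out=t_end / 4
            )
            rows.append({"n0": n0, "f0": f0, "fate": traj.terminal_fate})
    return pd.DataFrame(rows)


def relaxation_diagnostics(params: ModelParams) -> dict:
    """Early-warning geometry at the stable coexistence point.

    Returns the fast/slow timescale ratio and the |cosine| alignment of the
    slow eigenvector with (i) the constant-f (radial) direction
    ``(X*, Y*)/||.||`` and (ii) the constant-n direction ``(1, -1)/sqrt(2)``.
    Near the saddle-node the radial alignment approaches 1 (total density is
    the slow variable); near exclusion the constant-n alignment approaches 1
    (the strain ratio is the slow variable).
    """
    interior = [
        pt for pt in find_equilibria(params) if pt.kind == "interior" and pt.stable
    ]
    if not interior:
        raise CrossfeedError(
            "no stable coexistence equilibrium exists at these parameters"
        )
    pt = interior[0]
    _, (slow, fast), V = jacobian_eigen(pt.state, params)
    v = np.real(V[:, 0])
    v = v / np.linalg.norm(v)
    radial = np.array([pt.state.X, pt.state.Y])
    radial = radial / np.linalg.norm(radial)
    const_n = np.array([1.0, -1.0]) / np.sqrt(2.0)
    return {
        "equilibrium": pt.state,
        "slow_eigenvalue": float(np.real(slow)),
        "fast_eigenvalue": float(np.real(fast)),
        "timescale_ratio": float(abs(np.real(fast)) / abs(np.real(slow))),
        "align_constant_f": float(abs(v @ radial)),
        "align_constant_n": float(abs(v @ const_n)),
    }
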
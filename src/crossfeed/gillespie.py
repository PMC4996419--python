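"""Exact stochastic simulation of the cross-feeding birth-death process.

The continuous model is the mean-field limit of a Markov jump process on
individual counts ``(x, y)`` with system size ``omega`` (individuals at
carrying capacity).  The canonical propensity split is used: the saturating
growth term times the logistic factor is the birth rate, the death/dilution
term is the death rate::

    X-birth  : r_x * x * g_x(y/omega + a) * max(0, 1 - (x + c*y)/omega)
    X-death  : delta * x
    Y-birth  : r_y * y * g_y(beta*x/omega + a) * max(0, 1 - (c*x + y)/omega)
    Y-death  : delta * y

The ``max(0, .)`` clamp keeps every propensity non-negative even for initial
conditions above carrying capacity.  The state (0, 0) is absorbing.  The
next event is sampled exactly (direct method); populations at this scale do
not need tau-leaping.  Demographic noise scales as ``1/sqrt(omega)``, so
small systems near the saddle-node show stochastic collapse even where the
deterministic model predicts coexistence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .dynamics import Trajectory
from .errors import InvalidParameterError, SeedCollisionError
from .model import ModelParams

__all__ = ["StochasticConfig", "simulate", "ensemble_stats", "EnsembleStats"]


@dataclass(frozen=True)
class StochasticConfig:
    """System size, seed and sampling grid for stochastic runs.

    ``omega`` is the number of individuals at carrying capacity; the default
    10^4 is large enough to track the deterministic model yet small enough to
    exhibit near-collapse fluctuations.
    """

    omega: int = 10_000
    seed: int = 0
    t_max: float = 50.0
    record_dt: float = 0.5

    def __post_init__(self):
        if self.omega < 10:
            raise InvalidParameterError("omega must be >= 10")
        if self.t_max <= 0:
            raise InvalidParameterError("t_max must be > 0")
        if self.record_dt <= 0:
            raise InvalidParameterError("record_dt must be > 0")


@njit(cache=True)
def _ssa_core(x0, y0, omega, r_x, r_y, kappa, beta, delta, a, c,
              t_max, record_dt, seed):  # pragma: no cover - jitted
    np.random.seed(seed)
    n_rec = int(np.floor(t_max / record_dt)) + 1
    xs = np.empty(n_rec, np.int64)
    ys = np.empty(n_rec, np.int64)
    x = x0
    y = y0
    t = 0.0
    idx = 0
    while idx < n_rec:
        gx = (y / omega + a) / (y / omega + a + kappa)
        capx = 1.0 - (x + c * y) / omega
        if capx < 0.0:
            capx = 0.0
        bx = r_x * x * gx * capx
        dx = delta * x
        gy = (beta * x / omega + a) / (beta * x / omega + a + kappa)
        capy = 1.0 - (c * x + y) / omega
        if capy < 0.0:
            capy = 0.0
        by = r_y * y * gy * capy
        dy = delta * y
        total = bx + dx + by + dy
        if total <= 0.0:
            while idx < n_rec:
                xs[idx] = x
                ys[idx] = y
                idx += 1
            break
        t_next = t - np.log(np.random.random()) / total
        while idx < n_rec and idx * record_dt < t_next:
            xs[idx] = x
            ys[idx] = y
            idx += 1
        u = np.random.random() * total
        if u < bx:
            x += 1
        elif u < bx + dx:
            x -= 1
        elif u < bx + dx + by:
            y += 1
        else:
            y -= 1
        t = t_next
    return xs, ys


def simulate(params: ModelParams, config: StochasticConfig,
             initial_counts) -> Trajectory:
    """One exact realization, sampled piecewise-constant at ``record_dt``.

    ``initial_counts`` are integer individuals ``(x0, y0)``; densities in the
    returned trajectory are counts divided by ``omega``.  A fixed seed gives
    a bit-identical event sequence.
    """
    x0, y0 = int(initial_counts[0]), int(initial_counts[1])
    if x0 < 0 or y0 < 0:
        raise InvalidParameterError("initial counts must be non-negative")
    if x0 > 2 * config.omega or y0 > 2 * config.omega:
        raise InvalidParameterError("initial counts must be <= 2*omega")
    xs, ys = _ssa_core(
        x0, y0, float(config.omega), params.r_x, params.r_y, params.kappa,
        params.beta, params.delta, params.a, params.c,
        config.t_max, config.record_dt, config.seed,
    )
    t = np.arange(xs.size) * config.record_dt
    X = xs / config.omega
    Y = ys / config.omega
    fate = "extinction" if xs[-1] == 0 and ys[-1] == 0 else "unresolved"
    return Trajectory(t=t, X=X, Y=Y, terminal_fate=fate)


@dataclass
class EnsembleStats:
    """Per-time-point statistics across independent stochastic replicates."""

    t: np.ndarray
    mean_X: np.ndarray
    mean_Y: np.ndarray
    var_n: np.ndarray
    var_f: np.ndarray  # across replicates; NaN where no replicate has Y > 0
    extinction_fraction: float
    n_replicates: int
    seeds: np.ndarray

    def to_dict(self) -> dict:
        return {
            "t": self.t.tolist(),
            "mean_X": self.mean_X.tolist(),
            "mean_Y": self.mean_Y.tolist(),
            "var_n": self.var_n.tolist(),
            "var_f": self.var_f.tolist(),
            "extinction_fraction": self.extinction_fraction,
            "n_replicates": self.n_replicates,
        }


def derive_seeds(master_seed: int, n: int) -> np.ndarray:
    """Deterministic, collision-checked per-replicate seeds (< 2^31)."""
    seeds = np.random.SeedSequence(master_seed).generate_state(n) % (2**31)
    return seeds.astype(np.int64)


def ensemble_stats(
    params: ModelParams,
    config: StochasticConfig,
    initial_counts,
    n_replicates: int,
    seeds=None,
) -> EnsembleStats:
    """Mean trajectory, variances and extinction fraction over replicates.

    Seeds are derived from ``config.seed`` unless given explicitly; duplicate
    seeds are rejected (two replicates sharing a seed would silently halve
    the ensemble).
    """
    if n_replicates < 2:
        raise InvalidParameterError("n_replicates must be >= 2")
    if seeds is None:
        seeds = derive_seeds(config.seed, n_replicates)
    seeds = np.asarray(seeds, dtype=np.int64)
    if seeds.size != n_replicates:
        raise InvalidParameterError("need one seed per replicate")
    if np.unique(seeds).size != seeds.size:
        raise SeedCollisionError("replicate seeds must be distinct")
    Xs, Ys = [], []
    n_extinct = 0
    t = None
    for s in seeds:
        cfg = StochasticConfig(omega=config.omega, seed=int(s),
                               t_max=config.t_max, record_dt=config.record_dt)
        traj = simulate(params, cfg, initial_counts)
        t = traj.t
        Xs.append(traj.X)
        Ys.append(traj.Y)
        if traj.X[-1] == 0 and traj.Y[-1] == 0:
            n_extinct += 1
    Xs = np.array(Xs)
    Ys = np.array(Ys)
    with np.errstate(divide="ignore", invalid="ignore"):
        fs = np.where(Ys > 0, Xs / np.where(Ys > 0, Ys, 1.0), np.nan)
    return EnsembleStats(
        t=t,
        mean_X=Xs.mean(axis=0),
        mean_Y=Ys.mean(axis=0),
        var_n=(Xs + Ys).var(axis=0, ddof=1),
        var_f=_nanvar(fs),
        extinction_fraction=n_extinct / n_replicates,
        n_replicates=n_replicates,
        seeds=seeds,
    )


def _nanvar(arr: np.ndarray) -> np.ndarray:
    out = np.full(arr.shape[1], np.nan)
    counts = np.sum(~np.isnan(arr), axis=0)
    ok = counts >= 2
    if np.any(ok):
        with np.errstate(invalid="ignore"):
            out[ok] = np.nanvar(arr[:, ok], axis=0, ddof=1)
    return out
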
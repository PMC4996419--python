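"""Designed condition sets for end-to-end validation of the pipeline.

Selects one supplementation level per interaction regime such that the
regime is unambiguous *for the daily-dilution protocol itself*: ground truth
is computed from the fixed points of the deterministic daily map (growth for
``t_day``, then dilution), which is what a plate experiment converges to --
not from the continuous model, whose boundaries sit at slightly different
supplementation levels.  The amensalism condition is found by bisecting the
level at which the Leu- strain's co-culture and monoculture equilibria
coincide exactly (the parasitism/competition boundary), the only place that
boundary regime is observable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dynamics import DEFAULT_T_DAY, batch_equilibrium
from .errors import BracketingError
from .model import ModelParams, PopulationState
from .regimes import RegimeLabel, label_from_equilibria

__all__ = ["ConditionDesign", "design_regime_conditions"]

_EXT = 1e-6


@dataclass(frozen=True)
class ConditionDesign:
    """One designed condition: a supplementation level and its ground truth."""

    label: RegimeLabel
    a: float
    co_equilibrium: PopulationState  # daily-map co-culture attractor (end-of-day)
    x_mono: float  # daily-map monoculture equilibria (end-of-day densities)
    y_mono: float


class _BatchTruth:
    """Memoized daily-map equilibria as functions of the supplementation level."""

    def __init__(self, params, dilution_factor, t_day, max_days=300):
        self.params = params
        self.dilution = dilution_factor
        self.t_day = t_day
        self.max_days = max_days
        self._cache = {}

    def equilibria(self, a):
        key = round(float(a), 12)
        if key not in self._cache:
            p = self.params.replace(a=float(a))
            co = batch_equilibrium(
                p, PopulationState(0.1, 0.1), self.dilution, self.t_day,
                self.max_days,
            )
            mx = batch_equilibrium(
                p, PopulationState(0.05, 0.0), self.dilution, self.t_day,
                self.max_days,
            )
            my = batch_equilibrium(
                p, PopulationState(0.0, 0.05), self.dilution, self.t_day,
                self.max_days,
            )
            self._cache[key] = (co, mx.X, my.Y)
        return self._cache[key]

    def label(self, a, rel_tol):
        co, xm, ym = self.equilibria(a)
        x_co = co.X if co.X > _EXT else 0.0
        y_co = co.Y if co.Y > _EXT else 0.0
        return label_from_equilibria(x_co, y_co, xm, ym, rel_tol)


def _bisect(pred, lo, hi, tol):
    p_lo = pred(lo)
    if p_lo == pred(hi):
        raise BracketingError(f"predicate constant on ({lo}, {hi})")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if pred(mid) == p_lo:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def design_regime_conditions(
    params: ModelParams | None = None,
    dilution_factor: float = 10.0,
    t_day: float = DEFAULT_T_DAY,
    rel_tol: float = 0.05,
    a_exclusion: float = 3.0,
    tol: float = 2e-4,
):
    """One condition per regime, each with its daily-map ground truth.

    Boundaries (co-culture viability, the two monoculture viabilities, the
    amensalism crossing) are bisected on the daily map; interval regimes are
    probed at representative midpoints found by scanning.  Returns the eight
    designs ordered along the supplementation axis.
    """
    params = params or ModelParams()
    truth = _BatchTruth(params, dilution_factor, t_day)

    def co_alive(a):
        co = truth.equilibria(a)[0]
        return min(co.X, co.Y) > _EXT

    def mx_alive(a):
        return truth.equilibria(a)[1] > _EXT

    def my_alive(a):
        return truth.equilibria(a)[2] > _EXT

    a_co = _bisect(co_alive, 0.05, 0.4, tol)
    a_mx = _bisect(mx_alive, a_co, 0.6, tol)
    a_my = _bisect(my_alive, a_mx, 0.8, tol)

    designs = {}

    def add(a):
        lab = truth.label(a, rel_tol)
        if lab.name not in designs:
            co, xm, ym = truth.equilibria(a)
            designs[lab.name] = ConditionDesign(
                label=lab, a=float(a), co_equilibrium=co, x_mono=xm, y_mono=ym
            )

    add(0.6 * a_co)  # collapse
    add(0.5 * (a_co + a_mx))  # obligatory mutualism
    add(0.5 * (a_mx + a_my))  # obligatory for one strain only
    # scan upward from the Y viability threshold for the remaining interval
    # regimes (facultative, parasitism, competition)
    for a in np.geomspace(a_my * 1.05, a_exclusion, 25):
        add(a)
        if len({"facultative_mutualism", "parasitism", "competition"}
               & designs.keys()) == 3:
            break
    add(a_exclusion)  # competitive exclusion

    # amensalism: the Leu- strain's co-culture density crosses its
    # monoculture density between parasitism and competition
    if "parasitism" in designs and "competition" in designs:
        def y_gains(a):
            co, _, ym = truth.equilibria(a)
            return co.Y > ym

        a_am = _bisect(
            y_gains, designs["parasitism"].a, designs["competition"].a, tol / 4
        )
        co, xm, ym = truth.equilibria(a_am)
        designs["amensalism"] = ConditionDesign(
            label=truth.label(a_am, rel_tol), a=float(a_am),
            co_equilibrium=co, x_mono=xm, y_mono=ym,
        )

    ordered = sorted(designs.values(), key=lambda d: d.a)
    return ordered
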
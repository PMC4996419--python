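"""Qualitative interaction-regime classification.

The interaction between the two strains is labeled by comparing the
co-culture attractor to the two monoculture equilibria: each strain is
benefitted (+), harmed (-), unaffected (0), or driven extinct (X) by its
partner.  Along the supplementation axis the model passes, in order, through
collapse of the mutualism, obligatory mutualism, obligatory/facultative
mutualism (one strain still requires the partner), facultative mutualism,
parasitism, competition, and competitive exclusion; amensalism sits exactly
on the parasitism/competition boundary.

Two tolerance conventions coexist deliberately.  ``classify_regime`` accepts
a relative neutrality band (``rel_tol``, default 1%): a strain whose
co-culture density is within the band of its monoculture density counts as
unaffected, which is what makes the boundary regime amensalism reportable at
all -- and is how it shows up in measured data, where uncertainty widens the
band.  The scan functions default to the strict band ``rel_tol = 0``, under
which amensalism has measure zero and a generic grid yields exactly the seven
robust regimes in canonical order, matching the model's regime diagram.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .equilibria import find_equilibria
from .errors import AmbiguousRegimeError
from .model import ModelParams, monoculture_equilibrium

__all__ = [
    "RegimeLabel",
    "REGIME_ORDER",
    "EFFECT_LEGEND",
    "label_from_equilibria",
    "classify_regime",
    "regime_scan",
    "RegimeInterval",
    "regime_map_2d",
    "RegimeMap",
    "is_canonical_subsequence",
    "MUTUALISTIC_REGIMES",
]

#: canonical low-to-high supplementation ordering of all eight labels
REGIME_ORDER = (
    "collapse_extinction",
    "obligatory_mutualism",
    "obligatory_facultative",
    "facultative_mutualism",
    "parasitism",
    "amensalism",
    "competition",
    "competitive_exclusion",
)

MUTUALISTIC_REGIMES = frozenset(
    {"obligatory_mutualism", "obligatory_facultative", "facultative_mutualism"}
)

#: colorbar-style legend: per-strain effect codes for each label family
EFFECT_LEGEND = {
    "collapse_extinction": "both strains go extinct (X, X)",
    "obligatory_mutualism": "both benefit and neither survives alone (+, +)",
    "obligatory_facultative": "both benefit; one survives alone (+, +)",
    "facultative_mutualism": "both benefit (+, +)",
    "parasitism": "one benefits, one is harmed (+, -)",
    "amensalism": "one unaffected, one harmed (0, -)",
    "competition": "both harmed (-, -)",
    "competitive_exclusion": "one strain driven extinct (0, X)",
}

#: extinction means an attractor density below this (normalized scale)
EXTINCTION_TOL = 1e-6


@dataclass(frozen=True)
class RegimeLabel:
    """An interaction label with per-strain effect codes (+, -, 0, X)."""

    name: str
    effect_x: str
    effect_y: str

    def __post_init__(self):
        assert self.name in REGIME_ORDER, self.name


def _effect_sign(co: float, mono: float, rel_tol: float) -> str:
    if co > mono * (1.0 + rel_tol):
        return "+"
    if co < mono * (1.0 - rel_tol):
        return "-"
    return "0"


def label_from_equilibria(
    x_co: float,
    y_co: float,
    x_mono: float,
    y_mono: float,
    rel_tol: float = 0.0,
    ext_tol: float = EXTINCTION_TOL,
) -> RegimeLabel:
    """Decision table mapping equilibrium densities to a regime label.

    Shared by the model-side classifier and the experimental-data classifier
    so that predictions and estimates are judged by the same rules.  Inputs
    are the co-culture attractor densities of each strain and the two
    monoculture equilibria (0 = not viable).
    """
    if not 0.0 <= rel_tol < 0.2:
        raise ValueError("rel_tol must lie in [0, 0.2)")
    coexist = x_co > ext_tol and y_co > ext_tol
    viable_x = x_mono > ext_tol
    viable_y = y_mono > ext_tol

    if coexist:
        if not viable_x and not viable_y:
            return RegimeLabel("obligatory_mutualism", "+", "+")
        if viable_x != viable_y:
            return RegimeLabel("obligatory_facultative", "+", "+")
        sx = _effect_sign(x_co, x_mono, rel_tol)
        sy = _effect_sign(y_co, y_mono, rel_tol)
        if sx == "-" and sy == "-":
            return RegimeLabel("competition", "-", "-")
        if {sx, sy} == {"+", "-"}:
            return RegimeLabel("parasitism", sx, sy)
        if "0" in (sx, sy) and "-" in (sx, sy):
            return RegimeLabel("amensalism", sx, sy)
        if "0" in (sx, sy) and "+" in (sx, sy):
            # commensal corner of the deadband; grouped with the beneficial
            # regimes since nobody is harmed
            return RegimeLabel("facultative_mutualism", sx, sy)
        if sx == "0" and sy == "0":
            return RegimeLabel("amensalism", sx, sy)
        return RegimeLabel("facultative_mutualism", "+", "+")

    if not viable_x and not viable_y:
        return RegimeLabel("collapse_extinction", "X", "X")
    # a winner exists but coexistence does not
    if x_co > ext_tol:
        return RegimeLabel("competitive_exclusion", "0", "X")
    if y_co > ext_tol:
        return RegimeLabel("competitive_exclusion", "X", "0")
    # co-culture collapsed although a monoculture would survive: the
    # interaction destroyed an otherwise viable strain
    return RegimeLabel("competitive_exclusion", "X" if viable_y else "0",
                       "X" if viable_x else "0")


def _co_attractor(params: ModelParams, n_grid: int):
    """Stable co-culture attractor densities and any interior multiplicity."""
    pts = find_equilibria(params, n_grid)
    interior = [p for p in pts if p.kind == "interior" and p.stable]
    if interior:
        return interior, pts
    axis = [p for p in pts if p.kind in ("x_axis", "y_axis") and p.stable]
    if axis:
        return axis[:1], pts
    return [next(p for p in pts if p.kind == "origin")], pts


def classify_regime(
    params: ModelParams, rel_tol: float = 0.01, n_grid: int = 10_000
) -> RegimeLabel:
    """Label the interaction at one parameter set.

    When a stable coexistence point exists it defines the label even if a
    stable axis or origin attractor coexists with it (such bistability is
    intrinsic to the obligate regime, where extinction is always locally
    stable).  If several stable interior points yield conflicting labels an
    :class:`AmbiguousRegimeError` carrying all candidates is raised.
    """
    attractors, _ = _co_attractor(params, n_grid)
    xm = monoculture_equilibrium(params, "x")
    ym = monoculture_equilibrium(params, "y")
    labels = [
        label_from_equilibria(a.state.X, a.state.Y, xm, ym, rel_tol)
        for a in attractors
    ]
    if len({l.name for l in labels}) > 1:
        raise AmbiguousRegimeError(
            f"{len(labels)} stable attractors with conflicting labels at "
            f"a={params.a}", candidates=labels,
        )
    return labels[0]


@dataclass(frozen=True)
class RegimeInterval:
    a_lo: float
    a_hi: float
    label: RegimeLabel


def regime_scan(params: ModelParams, a_grid, rel_tol: float = 0.0,
                n_grid: int = 10_000):
    """Ordered regime sequence along the supplementation axis.

    Adjacent grid points with the same label are merged into intervals.  With
    the strict default band the scan over (0, 1] on the default parameters
    yields the seven robust regimes in canonical order.  Grid points raising
    ambiguity errors are recorded as annotations, not failures; returns
    ``(intervals, annotations)``.
    """
    a_grid = np.asarray(a_grid, dtype=float)
    if np.any(np.diff(a_grid) <= 0):
        raise ValueError("a_grid must be strictly increasing")
    intervals = []
    annotations = []
    for a in a_grid:
        try:
            label = classify_regime(params.replace(a=a), rel_tol, n_grid)
        except AmbiguousRegimeError as err:
            annotations.append((float(a), err.candidates))
            label = err.candidates[0]
        if intervals and intervals[-1].label.name == label.name:
            last = intervals.pop()
            intervals.append(RegimeInterval(last.a_lo, float(a), last.label))
        else:
            intervals.append(RegimeInterval(float(a), float(a), label))
    return intervals, annotations


@dataclass
class RegimeMap:
    """2-D regime map over (a, second parameter)."""

    a_grid: np.ndarray
    axis_name: str
    axis_grid: np.ndarray
    labels: list  # labels[j][i] for axis_grid[j], a_grid[i]

    def as_frame(self) -> pd.DataFrame:
        rows = []
        for j, v in enumerate(self.axis_grid):
            for i, a in enumerate(self.a_grid):
                lab = self.labels[j][i]
                rows.append(
                    {
                        "a": a,
                        self.axis_name: v,
                        "label": lab.name,
                        "effect_x": lab.effect_x,
                        "effect_y": lab.effect_y,
                    }
                )
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.as_frame().to_csv(path, index=False)

    def row_label_sequence(self, j: int):
        """Distinct label names along a for one second-axis value."""
        names = [lab.name for lab in self.labels[j]]
        seq = [names[0]]
        for nm in names[1:]:
            if nm != seq[-1]:
                seq.append(nm)
        return seq

    def mutualistic_measure(self, j: int) -> float:
        """Total a-length of mutualistic cells in row j (trapezoid weights)."""
        widths = np.gradient(self.a_grid)
        mask = np.array(
            [lab.name in MUTUALISTIC_REGIMES for lab in self.labels[j]], dtype=float
        )
        return float(np.sum(widths * mask))


def regime_map_2d(
    base_params: ModelParams,
    a_grid,
    axis_name: str,
    axis_grid,
    rel_tol: float = 0.0,
    n_grid: int = 4_000,
) -> RegimeMap:
    """Regime label per cell of an (a x c) or (a x delta) grid.

    Used for the robustness maps: shrinking niche overlap enlarges the
    mutualistic region, and the ordering of regimes along a is preserved
    across a wide range of death rates.
    """
    if axis_name not in ("c", "delta"):
        raise ValueError("axis_name must be 'c' or 'delta'")
    a_grid = np.asarray(a_grid, dtype=float)
    axis_grid = np.asarray(axis_grid, dtype=float)
    labels = []
    for v in axis_grid:
        p_row = base_params.replace(**{axis_name: float(v)})
        row = []
        for a in a_grid:
            try:
                row.append(classify_regime(p_row.replace(a=float(a)), rel_tol, n_grid))
            except AmbiguousRegimeError as err:
                row.append(err.candidates[0])
        labels.append(row)
    return RegimeMap(a_grid=a_grid, axis_name=axis_name, axis_grid=axis_grid,
                     labels=labels)


def is_canonical_subsequence(names) -> bool:
    """Whether a label sequence is a subsequence of the canonical order."""
    it = iter(REGIME_ORDER)
    return all(nm in it for nm in names)
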
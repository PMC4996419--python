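"""Analysis of serial-dilution plate tables (real or synthetic).

The observables are daily optical densities and Leu- fractions.  Relative
fitness over one growth cycle is the odds-ratio fold change of the Leu-
strain::

    W = [f1 / (1 - f1)] / [f0 / (1 - f0)]

a convention that needs only cytometry fractions, is symmetric under strain
relabeling (swapping strains maps W to 1/W), and equals the ratio of the two
strains' fold growths.  log W is fitted linearly against the day-start Leu-
fraction; its zero crossing is the equilibrium fraction at which both
strains grow equally, with a percentile bootstrap confidence interval.
Tracks that visibly converge are summarized directly; tracks that do not are
extrapolated through that fitted crossing, and a fit with no crossing at all
is reported as exclusion evidence (one strain sweeps).  Experimental regime
calls apply the same decision table as the model-side classifier, fed with
estimated equilibria instead of analytic ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import (
    InsufficientDataError,
    NoEquilibriumError,
    UndefinedFitnessError,
)
from .experiment import OD_FLOOR
from .regimes import RegimeLabel, label_from_equilibria

__all__ = [
    "relative_fitness",
    "day_records",
    "equilibrium_fraction_bootstrap",
    "EquilibriumFractionEstimate",
    "detect_equilibrium",
    "TrackSummary",
    "fitness_disadvantage",
    "FitnessDisadvantageEstimate",
    "classify_experimental_regime",
    "split_tracks",
]


def relative_fitness(f0: float, f1: float) -> float:
    """Per-cycle relative fitness of the Leu- strain from two fractions.

    ``f0`` and ``f1`` are the Leu- fractions at the start and end of one
    growth cycle, both strictly inside (0, 1); boundary fractions leave the
    odds ratio undefined.  ``log W > 0`` means the Leu- strain gained.
    """
    for name, f in (("f0", f0), ("f1", f1)):
        if not 0.0 < f < 1.0:
            raise UndefinedFitnessError(
                f"{name}={f} is outside (0, 1); relative fitness is undefined "
                "at boundary fractions"
            )
    return (f1 / (1.0 - f1)) / (f0 / (1.0 - f0))


def day_records(track: pd.DataFrame, min_day: int = 1) -> pd.DataFrame:
    """(f_start, logW) pairs from consecutive days of one co-culture track.

    Dilution does not change the strain fraction, so the fraction measured at
    the end of day ``d-1`` is the day-``d`` starting fraction.  Days whose
    fractions touch the boundary (or are missing, e.g. extinct wells) are
    skipped.  ``min_day`` discards early cycles before carrying capacity is
    reached, where fitness still reflects transient density effects.
    """
    track = track.sort_values("day")
    days = track["day"].to_numpy()
    fracs = pd.to_numeric(track["fraction_y"], errors="coerce").to_numpy(float)
    rows = []
    for i in range(1, len(days)):
        if days[i] != days[i - 1] + 1 or days[i] < min_day:
            continue
        f0, f1 = fracs[i - 1], fracs[i]
        if not (0.0 < f0 < 1.0 and 0.0 < f1 < 1.0):
            continue
        rows.append(
            {"day": int(days[i]), "f_start": f0,
             "logW": math.log(relative_fitness(f0, f1))}
        )
    return pd.DataFrame(rows, columns=["day", "f_start", "logW"])


@dataclass(frozen=True)
class EquilibriumFractionEstimate:
    """Zero crossing of log fitness vs fraction, with bootstrap CI."""

    estimate: float
    ci_low: float
    ci_high: float
    slope: float
    intercept: float
    n_records: int
    n_boot: int

    def covers(self, truth: float) -> bool:
        return self.ci_low <= truth <= self.ci_high


def _linfit(f: np.ndarray, w: np.ndarray):
    fm, wm = f.mean(), w.mean()
    df = f - fm
    var = np.dot(df, df)
    if var == 0.0:
        return np.nan, np.nan
    slope = np.dot(df, w - wm) / var
    return slope, wm - slope * fm


def equilibrium_fraction_bootstrap(
    records: pd.DataFrame,
    n_boot: int = 2000,
    seed: int = 0,
    ci: float = 0.95,
) -> EquilibriumFractionEstimate:
    """Equilibrium Leu- fraction where both strains have equal fitness.

    Fits ``logW`` linearly against the day-start fraction and returns the
    zero crossing with a percentile bootstrap CI (records resampled with
    replacement).  If the fitted line does not change sign across the
    observed fraction range the well is sweeping toward one strain and a
    :class:`NoEquilibriumError` is raised carrying the sweep direction.
    """
    f = np.asarray(records["f_start"], dtype=float)
    w = np.asarray(records["logW"], dtype=float)
    n = f.size
    if n < 4:
        raise InsufficientDataError(
            f"need >= 4 fitness records to locate an equilibrium, got {n}"
        )
    if np.all(w > 0) or np.all(w < 0):
        raise NoEquilibriumError(
            "log relative fitness never changes sign: one strain sweeps",
            sweep_direction=int(np.sign(w.mean())),
        )
    slope, intercept = _linfit(f, w)
    lo_val = intercept + slope * f.min()
    hi_val = intercept + slope * f.max()
    if lo_val * hi_val > 0:
        raise NoEquilibriumError(
            "fitted fitness line has no zero crossing in the observed "
            "fraction range",
            sweep_direction=int(np.sign(w.mean())) or None,
        )
    estimate = -intercept / slope

    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    fb = f[idx]
    wb = w[idx]
    fbm = fb.mean(axis=1, keepdims=True)
    wbm = wb.mean(axis=1, keepdims=True)
    var = np.sum((fb - fbm) ** 2, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        slopes = np.sum((fb - fbm) * (wb - wbm), axis=1) / var
        inters = wbm[:, 0] - slopes * fbm[:, 0]
        crossings = -inters / slopes
    crossings = crossings[np.isfinite(crossings)]
    alpha = 0.5 * (1.0 - ci)
    lo, hi = np.quantile(crossings, [alpha, 1.0 - alpha])
    return EquilibriumFractionEstimate(
        estimate=float(estimate), ci_low=float(lo), ci_high=float(hi),
        slope=float(slope), intercept=float(intercept), n_records=n,
        n_boot=n_boot,
    )


@dataclass(frozen=True)
class TrackSummary:
    """Convergence call for one well's day series."""

    converged: bool
    extinct: bool
    od_eq: float
    fraction_eq: float  # NaN for monocultures / extinct wells


def detect_equilibrium(
    track: pd.DataFrame,
    window: int = 3,
    rel_change_tol: float = 0.1,
) -> TrackSummary:
    """Decide whether a well reached equilibrium over its final days.

    Converged means the relative spread of OD (and of the fraction, when
    present) over the last ``window`` days is below ``rel_change_tol``; the
    equilibrium is then the mean over that window.  A track at the detection
    floor, or still shedding at least half its density per day, is flagged
    extinct (a steadily diluted-away culture is not "converged" even though
    its readings stop changing once they hit the floor).
    """
    track = track.sort_values("day")
    od = pd.to_numeric(track["od"], errors="coerce").to_numpy(float)
    if od.size < window + 1:
        raise InsufficientDataError(
            f"track has {od.size} points; need at least window+1 = {window + 1}"
        )
    fracs = (
        pd.to_numeric(track["fraction_y"], errors="coerce").to_numpy(float)
        if "fraction_y" in track.columns
        else np.full(od.size, np.nan)
    )
    od_win = od[-(window + 1):]
    frac_win = fracs[-(window + 1):]
    at_floor = od[-1] < 5.0 * OD_FLOOR
    # a culture losing density steadily is being diluted away, however
    # slowly: fast decay (>= half per day) or a monotone >= 25% slide over
    # the window both flag extinction in progress
    fast_decay = od[-1] < od[-(window + 1)] * 0.5 ** window
    slow_slide = bool(np.all(np.diff(od_win) < 0)
                      and od[-1] < 0.75 * od[-(window + 1)])
    if at_floor or fast_decay or slow_slide:
        return TrackSummary(converged=False, extinct=True, od_eq=0.0,
                            fraction_eq=float("nan"))
    od_ok = (od_win.max() - od_win.min()) / od_win.mean() < rel_change_tol
    if np.all(np.isnan(frac_win)):
        frac_ok = True
        frac_eq = float("nan")
    else:
        # fraction drift is judged on the log-odds scale: a slow sweep at an
        # extreme fraction moves little in absolute fraction but steadily in
        # log odds, and equal-fitness equilibrium is a log-odds fixed point
        logit = np.log(np.clip(frac_win, 1e-9, None)
                       / np.clip(1.0 - frac_win, 1e-9, None))
        frac_ok = bool(np.nanmax(logit) - np.nanmin(logit) < rel_change_tol)
        frac_eq = float(np.nanmean(frac_win))
    return TrackSummary(
        converged=bool(od_ok and frac_ok),
        extinct=False,
        od_eq=float(od_win.mean()),
        fraction_eq=frac_eq,
    )


@dataclass(frozen=True)
class FitnessDisadvantageEstimate:
    """Per-day growth-rate disadvantage of the Leu- strain, with CI."""

    estimate: float
    ci_low: float
    ci_high: float
    n_records: int

    def covers(self, truth: float) -> bool:
        return self.ci_low <= truth <= self.ci_high


def fitness_disadvantage(
    co_tracks,
    dilution_factor: float = 10.0,
    min_day: int = 2,
    n_boot: int = 2000,
    seed: int = 0,
) -> FitnessDisadvantageEstimate:
    """Estimate the Leu- strain's relative growth-rate deficit.

    At saturating amino-acid levels cross-feeding is irrelevant and both
    strains' realized log fold growths are proportional to their maximal
    rates, so ``1 - ln(fold_Y)/ln(fold_X)`` per day estimates the fractional
    rate disadvantage ``1 - r_y/r_x``.  Fold growths combine the OD and the
    fractions across one dilution cycle.  Bootstrap over day records gives
    the percentile CI of the mean.
    """
    vals = []
    for track in co_tracks:
        track = track.sort_values("day")
        days = track["day"].to_numpy()
        od = pd.to_numeric(track["od"], errors="coerce").to_numpy(float)
        fr = pd.to_numeric(track["fraction_y"], errors="coerce").to_numpy(float)
        for i in range(1, len(days)):
            if days[i] != days[i - 1] + 1 or days[i] < min_day:
                continue
            f0, f1 = fr[i - 1], fr[i]
            if not (0.0 < f0 < 1.0 and 0.0 < f1 < 1.0):
                continue
            fold_x = od[i] * (1.0 - f1) / (od[i - 1] * (1.0 - f0) / dilution_factor)
            fold_y = od[i] * f1 / (od[i - 1] * f0 / dilution_factor)
            if fold_x <= 1.0 or fold_y <= 0.0:
                continue  # needs net growth of the reference strain
            vals.append(1.0 - math.log(fold_y) / math.log(fold_x))
    vals = np.asarray(vals)
    if vals.size < 4:
        raise InsufficientDataError(
            f"need >= 4 usable day records, got {vals.size}"
        )
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, vals.size, size=(n_boot, vals.size))
    means = vals[idx].mean(axis=1)
    lo, hi = np.quantile(means, [0.025, 0.975])
    return FitnessDisadvantageEstimate(
        estimate=float(vals.mean()), ci_low=float(lo), ci_high=float(hi),
        n_records=int(vals.size),
    )


def split_tracks(plate: pd.DataFrame, trp_uM: float):
    """One condition's (mono_x, mono_y, [co...]) tracks from a plate table."""
    cond = plate[np.isclose(plate["trp_uM"].astype(float), trp_uM)]
    mono_x = cond[cond["culture_type"] == "mono_x"]
    mono_y = cond[cond["culture_type"] == "mono_y"]
    cos = [g for _, g in cond[cond["culture_type"] == "co"].groupby("well")]
    return mono_x, mono_y, cos


def _mono_density(track: pd.DataFrame, window, rel_change_tol, od_per_density):
    summary = detect_equilibrium(track, window, rel_change_tol)
    if summary.extinct:
        return 0.0
    return summary.od_eq / od_per_density


def classify_experimental_regime(
    mono_x_track: pd.DataFrame,
    mono_y_track: pd.DataFrame,
    co_tracks,
    rel_tol: float = 0.05,
    window: int = 3,
    rel_change_tol: float = 0.1,
    od_per_density: float = 1.0,
    fraction_floor: float = 1e-3,
    n_boot: int = 2000,
    seed: int = 0,
) -> RegimeLabel:
    """Regime call for one condition from measured tracks.

    Applies the same decision table as the model-side classifier, with the
    monoculture and co-culture equilibria replaced by estimates: converged
    tracks are summarized over their final window; a co-culture whose
    fraction has not settled is extrapolated through the fitted
    equal-fitness crossing, and a fit with no crossing (one strain sweeping)
    is itself the exclusion call.  ``rel_tol`` is wider than the model-side
    default because estimates carry measurement uncertainty.
    """
    x_mono = _mono_density(mono_x_track, window, rel_change_tol, od_per_density)
    y_mono = _mono_density(mono_y_track, window, rel_change_tol, od_per_density)

    summaries = [detect_equilibrium(t, window, rel_change_tol) for t in co_tracks]
    live = [s for s in summaries if not s.extinct]
    if not live:
        return label_from_equilibria(0.0, 0.0, x_mono, y_mono, rel_tol)

    n_eq = float(np.mean([s.od_eq for s in live])) / od_per_density
    frac_converged = [
        s.fraction_eq for s in live if s.converged and not math.isnan(s.fraction_eq)
    ]
    if frac_converged:
        f_eq = float(np.mean(frac_converged))
    else:
        records = pd.concat(
            [day_records(t, min_day=1) for t in co_tracks], ignore_index=True
        )
        try:
            est = equilibrium_fraction_bootstrap(records, n_boot=n_boot, seed=seed)
            f_eq = min(max(est.estimate, 0.0), 1.0)
        except NoEquilibriumError as err:
            f_eq = 1.0 if (err.sweep_direction or 0) > 0 else 0.0
        except InsufficientDataError:
            # no usable fraction record at all: a monoculture-like co well
            f_eq = float("nan")
    if math.isnan(f_eq):
        f_eq = 0.0
    if f_eq < fraction_floor:
        x_co, y_co = n_eq, 0.0
    elif f_eq > 1.0 - fraction_floor:
        x_co, y_co = 0.0, n_eq
    else:
        x_co, y_co = n_eq * (1.0 - f_eq), n_eq * f_eq
    return label_from_equilibria(x_co, y_co, x_mono, y_mono, rel_tol)
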
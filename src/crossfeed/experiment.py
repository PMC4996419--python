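"""Synthetic plate-reader + flow-cytometry serial-dilution experiments.

Emulates the daily-dilution protocol: wells seeded with monocultures or
co-cultures at chosen total densities and Leu- fractions, grown for ~7 days
with 10x dilution into fresh medium each day, with optical density measured
by spectrophotometry (multiplicative lognormal noise) and strain fractions
by flow cytometry (a binomial draw of a finite cell sample, 10^4 cells by
default) at the end of every day.  Conditions are labeled by their
tryptophan concentration; leucine is always co-supplied at 8x.

The generator is fully reproducible under its seed and supports the exact
noise-free limit (``od_noise_sd = 0`` and ``cytometer_sample = None``), in
which records equal the deterministic daily map -- the regression anchor for
the estimation stage.
"""

from __future__ import annotations

import dataclasses
import io
import json
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dynamics import DEFAULT_T_DAY, run_batch_protocol
from .errors import InvalidParameterError, PlateSchemaError
from .model import (
    DEFAULT_CONCENTRATION_SCALE,
    ModelParams,
    PopulationState,
    map_concentration_to_a,
)

__all__ = ["ExperimentConfig", "simulate_plate", "write_plate", "read_plate",
           "PLATE_COLUMNS"]

PLATE_COLUMNS = ["well", "day", "trp_uM", "culture_type", "od",
                 "cells_x", "cells_y", "fraction_y"]

#: OD reading reported for wells whose density fell below detection
OD_FLOOR = 1e-4
#: density below which a well counts as extinct for measurement purposes
DENSITY_FLOOR = 1e-6


@dataclass(frozen=True)
class ExperimentConfig:
    """Design and instrument model of one synthetic plate experiment.

    ``conditions`` lists tryptophan concentrations in uM (leucine implied at
    8x).  ``co_initial`` lists (total density, Leu- fraction) seeds for
    co-culture wells; monoculture wells are seeded at ``mono_initial_n``.
    ``cytometer_sample = None`` means exact fractions (infinite-sample
    limit); ``od_noise_sd = 0`` disables OD noise.
    """

    days: int = 7
    dilution_factor: float = 10.0
    conditions: tuple = (1.0, 8.0, 32.0)
    co_initial: tuple = ((0.1, 0.5),)
    mono_initial_n: float = 0.05
    #: optional per-strain monoculture seeds (n_x, n_y) overriding
    #: ``mono_initial_n`` -- lets a designed experiment start viable
    #: monocultures at their own equilibrium
    mono_initial: tuple | None = None
    include_monocultures: bool = True
    od_noise_sd: float = 0.05
    cytometer_sample: int | None = 10_000
    od_per_density: float = 1.0
    t_day: float = DEFAULT_T_DAY
    concentration_scale: float = DEFAULT_CONCENTRATION_SCALE
    seed: int = 0

    def __post_init__(self):
        if self.days < 1:
            raise InvalidParameterError("days must be >= 1")
        if self.dilution_factor <= 1:
            raise InvalidParameterError("dilution_factor must be > 1")
        if self.cytometer_sample is not None and self.cytometer_sample < 1:
            raise InvalidParameterError("cytometer_sample must be >= 1 or None")
        if self.od_noise_sd < 0:
            raise InvalidParameterError("od_noise_sd must be >= 0")
        for trp in self.conditions:
            if trp < 0:
                raise InvalidParameterError("concentrations must be >= 0")
        if self.mono_initial is not None:
            if len(self.mono_initial) != 2 or any(n < 0 for n in self.mono_initial):
                raise InvalidParameterError(
                    "mono_initial must be a non-negative pair (n_x, n_y)"
                )
        for n0, fy in self.co_initial:
            if n0 <= 0 or not 0.0 <= fy <= 1.0:
                raise InvalidParameterError(
                    "co_initial entries must be (n0 > 0, fraction in [0,1])"
                )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["conditions"] = list(self.conditions)
        d["co_initial"] = [list(x) for x in self.co_initial]
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return f"{zlib.crc32(blob):08x}"


def _measure(rng, config: ExperimentConfig, state: PopulationState,
             co_culture: bool):
    """One well-day measurement: (od, cells_x, cells_y, fraction_y)."""
    n = state.n
    extinct = n < DENSITY_FLOOR
    od_true = OD_FLOOR if extinct else n * config.od_per_density
    if config.od_noise_sd > 0:
        od = od_true * rng.lognormal(0.0, config.od_noise_sd)
    else:
        od = od_true
    if not co_culture or extinct:
        return od, None, None, None
    p_y = state.Y / n
    if config.cytometer_sample is None:
        return od, None, None, p_y
    cells_y = int(rng.binomial(config.cytometer_sample, p_y))
    cells_x = config.cytometer_sample - cells_y
    return od, cells_x, cells_y, cells_y / config.cytometer_sample


def simulate_plate(config: ExperimentConfig, params: ModelParams) -> pd.DataFrame:
    """Run the full plate design and return the tidy record table.

    Each condition overrides the model's supplementation level through the
    concentration mapping.  Day 0 rows record the (measured) seeding state;
    days 1..``days`` record end-of-day growth, each followed by dilution.
    """
    rng = np.random.default_rng(config.seed)
    rows = []
    for ci, trp in enumerate(config.conditions):
        a = map_concentration_to_a(trp, config.concentration_scale)
        p = params.replace(a=a)
        wells = []
        if config.include_monocultures:
            n_x, n_y = config.mono_initial or (config.mono_initial_n,
                                               config.mono_initial_n)
            wells.append((f"c{ci:02d}_mx", "mono_x", PopulationState(n_x, 0.0)))
            wells.append((f"c{ci:02d}_my", "mono_y", PopulationState(0.0, n_y)))
        for wi, (n0, fy) in enumerate(config.co_initial):
            wells.append(
                (f"c{ci:02d}_co{wi}", "co",
                 PopulationState(n0 * (1.0 - fy), n0 * fy))
            )
        for well_id, ctype, state0 in wells:
            co = ctype == "co"
            od, cx, cy, fy = _measure(rng, config, state0, co)
            rows.append((well_id, 0, trp, ctype, od, cx, cy, fy))
            track = run_batch_protocol(
                p, state0, config.days, config.dilution_factor, config.t_day
            )
            for day, st in enumerate(track, start=1):
                od, cx, cy, fy = _measure(rng, config, st, co)
                rows.append((well_id, day, trp, ctype, od, cx, cy, fy))
    df = pd.DataFrame(rows, columns=PLATE_COLUMNS)
    df["cells_x"] = df["cells_x"].astype("Int64")
    df["cells_y"] = df["cells_y"].astype("Int64")
    df["fraction_y"] = df["fraction_y"].astype(float)
    return df


def write_plate(df: pd.DataFrame, path, config: ExperimentConfig | None = None) -> None:
    """Write the record table as CSV with a provenance header comment.

    The single header comment line carries a config hash and seed so a file
    can be traced back to the design that generated it; missing fractions
    (extinct wells, monocultures) are empty fields, never 0 or NaN text.
    """
    _validate_schema(df)
    meta = ""
    if config is not None:
        meta = f" config_hash={config.config_hash()} seed={config.seed}"
    buf = io.StringIO()
    df.to_csv(buf, index=False, na_rep="")
    with open(path, "w") as fh:
        fh.write(f"# crossfeed-plate{meta}\n")
        fh.write(buf.getvalue())


def read_plate(path) -> pd.DataFrame:
    """Read a plate CSV, enforcing schema and field invariants."""
    df = pd.read_csv(path, comment="#")
    _validate_schema(df)
    return df


def _validate_schema(df: pd.DataFrame) -> None:
    missing = [c for c in PLATE_COLUMNS if c not in df.columns]
    if missing:
        raise PlateSchemaError(f"plate table is missing column(s) {missing}")
    extra = [c for c in df.columns if c not in PLATE_COLUMNS]
    if extra:
        raise PlateSchemaError(f"plate table has unknown column(s) {extra}")
    if len(df) == 0:
        return
    frac = pd.to_numeric(df["fraction_y"], errors="coerce")
    bad = frac.notna() & ((frac < 0) | (frac > 1))
    if bad.any():
        raise PlateSchemaError(
            f"column 'fraction_y' outside [0, 1] in {int(bad.sum())} row(s)"
        )
    cx = pd.to_numeric(df["cells_x"], errors="coerce")
    cy = pd.to_numeric(df["cells_y"], errors="coerce")
    both = cx.notna() & cy.notna()
    if both.any():
        tot = (cx[both] + cy[both]).round().astype(int)
        if tot.nunique() > 1:
            raise PlateSchemaError(
                "column pair 'cells_x'/'cells_y' does not sum to a single "
                "cytometer sample size"
            )
        expected = cy[both] / tot
        if not np.allclose(expected, frac[both], atol=1e-9):
            raise PlateSchemaError(
                "column 'fraction_y' inconsistent with cell counts"
            )
    if (pd.to_numeric(df["od"], errors="coerce") < 0).any():
        raise PlateSchemaError("column 'od' has negative readings")
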
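"""Deterministic two-strain cross-feeding model.

Two auxotrophic budding-yeast strains are grown together: strain X (Trp-)
cannot make tryptophan but overproduces leucine, strain Y (Leu-) cannot make
leucine but overproduces tryptophan.  Each strain's per-capita growth rate is
the product of a saturating (Monod) benefit term -- driven by the partner's
density plus the supplemented amino-acid level ``a`` -- and a shared logistic
term, minus a constant death/dilution rate::

    dX/dt = r_x * X * (Y + a) / (Y + a + kappa) * (1 - X - c*Y) - delta * X
    dY/dt = r_y * Y * (b*X + a) / (b*X + a + kappa) * (1 - c*X - Y) - delta * Y

Densities are normalized so the shared carrying capacity is 1, and time is
dimensionless (``r_x = 1`` defines the unit).  ``beta`` encodes the asymmetry
of benefit (the Trp- strain leaks more of what its partner needs), and the
niche-overlap coefficient ``c`` (default 1, full overlap) scales how strongly
the partner's density counts against the shared carrying capacity; ``c = 1``
recovers the base model exactly.  ``c`` enters only the logistic term, not the
cross-feeding benefit.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from .errors import InvalidParameterError, NoThresholdError

__all__ = [
    "ModelParams",
    "PopulationState",
    "saturation_factor",
    "rhs",
    "rhs_xy",
    "monoculture_equilibrium",
    "monoculture_viability_threshold",
    "map_concentration_to_a",
    "DEFAULT_CONCENTRATION_SCALE",
]

#: Dimensionless amino-acid level per micromolar tryptophan (leucine is
#: supplied at 8x tryptophan throughout, so one coordinate suffices).  A pure
#: convention: it places the experimental obligate-mutualism condition
#: (1 uM tryptophan) near the model's obligate window (a ~ 0.1).
DEFAULT_CONCENTRATION_SCALE = 0.1

_CONFIG_KEYS = ("r_x", "r_y", "kappa", "beta", "delta", "a", "c")


@dataclass(frozen=True)
class ModelParams:
    """Rate and saturation constants of the two-strain model.

    Attributes
    ----------
    r_x, r_y : float
        Maximum growth rates of the Trp- (X) and Leu- (Y) strains, per unit
        time.  Defaults 1 and 0.925: the Leu- strain carries a ~7.5% growth
        disadvantage measured in saturating amino-acid competition.
    kappa : float
        Effective Monod constant shared by both benefit terms (default 0.12).
    beta : float
        Benefit asymmetry: the Leu- strain sees ``beta*X + a`` as its nutrient
        pool (default 2; the Trp- strain leaks more).
    delta : float
        Death rate imposed by dilution (default 0.5).
    a : float
        Supplemented amino-acid level, dimensionless (default 0).
    c : float
        Niche-overlap coefficient in [0, 1]; 1 = complete overlap (default).
    """

    r_x: float = 1.0
    r_y: float = 0.925
    kappa: float = 0.12
    beta: float = 2.0
    delta: float = 0.5
    a: float = 0.0
    c: float = 1.0

    def __post_init__(self):
        if not (self.r_x > 0 and self.r_y > 0):
            raise InvalidParameterError("growth rates r_x, r_y must be > 0")
        if not self.kappa > 0:
            raise InvalidParameterError("Monod constant kappa must be > 0")
        if not self.beta > 0:
            raise InvalidParameterError("benefit asymmetry beta must be > 0")
        if self.delta < 0:
            raise InvalidParameterError("death rate delta must be >= 0")
        if self.a < 0:
            raise InvalidParameterError("amino-acid level a must be >= 0")
        if not 0.0 <= self.c <= 1.0:
            raise InvalidParameterError("niche overlap c must lie in [0, 1]")

    def replace(self, **changes) -> "ModelParams":
        """Return a copy with the given fields replaced (re-validated)."""
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in _CONFIG_KEYS}

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        unknown = set(d) - set(_CONFIG_KEYS)
        if unknown:
            raise InvalidParameterError(
                f"unknown parameter keys: {sorted(unknown)}; "
                f"allowed: {list(_CONFIG_KEYS)}"
            )
        return cls(**{k: float(v) for k, v in d.items()})

    @classmethod
    def from_file(cls, path) -> "ModelParams":
        """Read a flat key-value config (YAML or JSON by extension)."""
        path = Path(path)
        text = path.read_text()
        if path.suffix == ".json":
            data = json.loads(text)
        else:
            data = yaml.safe_load(text)
        if not isinstance(data, dict):
            raise InvalidParameterError(f"{path}: expected a flat mapping")
        return cls.from_dict(data)

    def to_file(self, path) -> None:
        path = Path(path)
        if path.suffix == ".json":
            path.write_text(json.dumps(self.to_dict(), indent=2) + "\n")
        else:
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


@dataclass(frozen=True)
class PopulationState:
    """Densities of the two strains (carrying capacity normalized to 1).

    ``n`` (total) and ``f`` (ratio X/Y) are always derived, never stored.
    ``f`` is NaN when Y = 0 -- the ratio is undefined there, not infinite --
    and consumers must handle that sentinel.
    """

    X: float
    Y: float

    def __post_init__(self):
        if self.X < 0 or self.Y < 0:
            raise InvalidParameterError(
                f"densities must be non-negative, got ({self.X}, {self.Y})"
            )

    @property
    def n(self) -> float:
        """Total population density X + Y."""
        return self.X + self.Y

    @property
    def f(self) -> float:
        """Strain ratio X / Y; NaN when Y = 0."""
        return self.X / self.Y if self.Y > 0 else math.nan

    @classmethod
    def from_nf(cls, n: float, f: float) -> "PopulationState":
        """Build a state from total density ``n`` and ratio ``f = X/Y``."""
        if n < 0 or f < 0:
            raise InvalidParameterError("n and f must be non-negative")
        return cls(X=n * f / (1.0 + f), Y=n / (1.0 + f))


def saturation_factor(s, kappa):
    """Monod saturation ``s / (s + kappa)``.

    Monotone increasing in ``s``, equals 0 at ``s = 0``, 1/2 at
    ``s = kappa``, and tends to 1 from below as ``s`` grows.  Accepts scalars
    or arrays.
    """
    s = np.asarray(s, dtype=float)
    if np.any(s < 0):
        raise InvalidParameterError("nutrient level s must be >= 0")
    if not kappa > 0:
        raise InvalidParameterError("Monod constant kappa must be > 0")
    out = s / (s + kappa)
    return float(out) if out.ndim == 0 else out


def rhs_xy(X: float, Y: float, p: ModelParams):
    """Time derivatives (dX/dt, dY/dt) from bare floats (integrator path)."""
    gx = (Y + p.a) / (Y + p.a + p.kappa)
    gy = (p.beta * X + p.a) / (p.beta * X + p.a + p.kappa)
    dX = p.r_x * X * gx * (1.0 - X - p.c * Y) - p.delta * X
    dY = p.r_y * Y * gy * (1.0 - p.c * X - Y) - p.delta * Y
    return dX, dY


def rhs(state: PopulationState, params: ModelParams):
    """Time derivatives of the model at ``state``.

    The origin is a fixed point for every valid parameter set, and with no
    nutrient and no partner (``a = 0``, ``Y = 0``) the X equation reduces to
    pure decay at rate ``delta``.
    """
    return rhs_xy(state.X, state.Y, params)


def monoculture_equilibrium(params: ModelParams, strain: str) -> float:
    """Closed-form monoculture equilibrium density of one strain.

    With the partner absent the benefit term depends on ``a`` alone and the
    nonzero root of logistic-with-death growth is
    ``1 - delta / (r * a / (a + kappa))``, clipped at 0.  Returns 0 (not an
    error) whenever the strain cannot sustain itself, including ``a = 0``.
    """
    r = _strain_rate(params, strain)
    if params.a == 0.0:
        # no nutrient and no partner: only the extinct state remains
        # (degenerate when delta = 0 too: every density is then stationary,
        # and we report the infimum 0)
        return 0.0
    g = params.a / (params.a + params.kappa)
    return max(0.0, 1.0 - params.delta / (r * g))


def monoculture_viability_threshold(params: ModelParams, strain: str) -> float:
    """Critical amino-acid level above which a monoculture persists.

    Closed form ``a_crit = delta * kappa / (r - delta)``: the level at which
    the maximal nutrient-limited growth rate just balances death.  The
    monoculture equilibrium is 0 for ``a <= a_crit`` and positive above it.
    Returns 0 when ``delta = 0`` (any nutrient suffices without death).
    """
    r = _strain_rate(params, strain)
    if params.delta == 0.0:
        return 0.0
    if r <= params.delta:
        raise NoThresholdError(
            f"strain {strain!r} has max growth rate {r} <= death rate "
            f"{params.delta}: no finite viability threshold exists"
        )
    return params.delta * params.kappa / (r - params.delta)


def map_concentration_to_a(trp_uM, scale: float = DEFAULT_CONCENTRATION_SCALE):
    """Map a tryptophan concentration (uM) to the dimensionless level ``a``.

    Leucine is always co-supplied at 8x the tryptophan concentration (roughly
    the intracellular abundance ratio), so a single coordinate parameterizes
    the supplementation axis.  The mapping is linear, ``a = scale * trp_uM``;
    the default scale is a documented convention, not a fitted constant.
    """
    trp_uM = np.asarray(trp_uM, dtype=float)
    if np.any(trp_uM < 0):
        raise InvalidParameterError("concentration must be >= 0")
    if scale <= 0:
        raise InvalidParameterError("scale must be > 0")
    out = scale * trp_uM
    return float(out) if out.ndim == 0 else out


def _strain_rate(params: ModelParams, strain: str) -> float:
    s = strain.lower()
    if s in ("x", "trp-", "trp"):
        return params.r_x
    if s in ("y", "leu-", "leu"):
        return params.r_y
    raise InvalidParameterError(f"unknown strain {strain!r}; use 'x' or 'y'")
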
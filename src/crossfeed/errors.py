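"""Exception hierarchy for the crossfeed package."""


class CrossfeedError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(CrossfeedError, ValueError):
    """A parameter violates its domain constraints."""


class NoThresholdError(CrossfeedError):
    """A requested critical point does not exist for these parameters."""


class BracketingError(CrossfeedError):
    """A bisection bracket does not straddle the requested transition."""


class AmbiguousRegimeError(CrossfeedError):
    """Multiple stable attractors give conflicting interaction labels.

    The conflicting candidate labels are carried in ``candidates``.
    """

    def __init__(self, message, candidates=()):
        super().__init__(message)
        self.candidates = tuple(candidates)


class IntegrationError(CrossfeedError):
    """Numerical integration failed; ``last_state`` holds the last valid state."""

    def __init__(self, message, last_state=None):
        super().__init__(message)
        self.last_state = last_state


class SeedCollisionError(CrossfeedError):
    """Two stochastic replicates were asked to share an RNG seed."""


class InsufficientDataError(CrossfeedError):
    """A track is too short (or too sparse) for the requested estimate."""


class UndefinedFitnessError(CrossfeedError):
    """Relative fitness is undefined at boundary strain fractions (0 or 1)."""


class NoEquilibriumError(CrossfeedError):
    """The fitted fitness-vs-fraction relation has no zero crossing in range.

    This is evidence of competitive exclusion (one strain always wins), not a
    numerical failure, and callers may catch it to record the sweep direction.
    """

    def __init__(self, message, sweep_direction=None):
        super().__init__(message)
        #: +1 if the Leu- strain always gains, -1 if it always loses.
        self.sweep_direction = sweep_direction


class PlateSchemaError(CrossfeedError):
    """A plate table does not conform to the documented CSV schema."""


class ScenarioError(CrossfeedError):
    """A pipeline configuration is invalid or names an unknown scenario."""
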
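"""Exception hierarchy for neighwalk.

All errors raised on bad user input derive from :class:`NeighwalkError`
so callers can catch the package's failures with one clause; each concrete
class marks one contract from the public API.
"""


class NeighwalkError(Exception):
    """Base class for all neighwalk errors."""


class InvalidArgumentError(NeighwalkError, ValueError):
    """A function argument violates its precondition."""


class IslandError(NeighwalkError):
    """The adjacency graph is disconnected; the intrinsic CAR prior is
    undefined across components (islands are rejected by default)."""


class ConfigError(NeighwalkError):
    """Inconsistent generator or pipeline configuration (e.g. a true
    effect named for a covariate that does not exist)."""


class DegenerateVariableError(NeighwalkError, ValueError):
    """A variable has too few distinct values to be quartile-categorized."""


class DegenerateOutcomeError(NeighwalkError, ValueError):
    """An outcome vector cannot support the requested coding
    (e.g. all-zero walking minutes)."""


class MissingWeatherError(NeighwalkError, KeyError):
    """A day of the 8-day weather window is absent from the daily series."""


class IdentifiabilityError(NeighwalkError):
    """The requested model is not identifiable from the data provided
    (e.g. a neighborhood-level variance with a single neighborhood)."""


class CategorySupportError(NeighwalkError):
    """The ordinal outcome has too few observed categories."""


class InsufficientChainsError(NeighwalkError):
    """Convergence diagnostics need at least two chains."""


class ContractError(NeighwalkError):
    """An internal object is missing a component required downstream."""


class DegenerateScoreError(NeighwalkError):
    """The environmental risk score takes too few distinct values to be
    split into quartile categories."""
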
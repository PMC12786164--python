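"""Exception hierarchy for shelfkin.

All package-specific failures derive from :class:`ShelfkinError` so callers
can catch one base class at pipeline boundaries.
"""


class ShelfkinError(Exception):
    """Base class for all shelfkin errors."""


class SchemaError(ShelfkinError):
    """Input table is missing a required column or has a malformed header."""


class IntegrityError(ShelfkinError):
    """Duplicate (attribute, treatment, temperature, time, replicate) key."""


class NormalizationError(ShelfkinError):
    """Day-0 baseline missing or zero; the series cannot be normalized."""


class InsufficientDataError(ShelfkinError):
    """Too few time points, replicates or residuals for the requested fit."""


class SingularDesignError(ShelfkinError):
    """Degenerate regression design (e.g. all times identical)."""


class DomainError(ShelfkinError):
    """A value is outside the mathematical domain of the operation."""


class UnbalancedDesignError(ShelfkinError):
    """Factorial design is not balanced; the classical ANOVA engine requires
    equal cell counts."""


class UnreachableLimitError(ShelfkinError):
    """The quality limit lies on the wrong side of the starting value for the
    fitted direction of change."""
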
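"""Exception hierarchy shared across the package.

Every error raised by catercalc derives from :class:`CatercalcError`, so
callers (including the CLI) can distinguish domain failures from bugs.
"""

from __future__ import annotations


class CatercalcError(Exception):
    """Base class for all catercalc domain errors."""


class SchemaError(CatercalcError):
    """An input table is missing required columns or has conflicting ones."""


class RecordValidationError(CatercalcError):
    """A row violates a field-level invariant; the message names row and field."""


class DuplicateIdError(CatercalcError):
    """Two composition records share the same id."""


class UnresolvableIngredientError(CatercalcError):
    """An ingredient could not be matched at any resolution level."""

    def __init__(self, query: str, suggestions: list[str] | None = None):
        self.query = query
        self.suggestions = suggestions or []
        hint = f"; nearest known subclasses: {', '.join(self.suggestions)}" if self.suggestions else ""
        super().__init__(f"cannot resolve ingredient {query!r} at any level{hint}")


class InconsistentProximatesError(CatercalcError):
    """Proximate components exceed the total mass beyond tolerance."""


class MissingRatioError(CatercalcError):
    """No raw-to-cooked ratio is available for a (category, method) key."""


class ConfigError(CatercalcError):
    """Invalid configuration: unknown seasoning kind, non-positive reference, bad factors."""


class AlignmentError(CatercalcError):
    """Paired calculated/detected tables cannot be aligned row by row."""


class DomainError(CatercalcError):
    """An argument lies outside the mathematical domain of an operation."""


class DegenerateDishError(CatercalcError):
    """A dish has no mass to normalise by (estimated cooked weight of zero)."""


class FixtureIntegrityError(CatercalcError):
    """Packaged reference data failed its integrity checks."""
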
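"""Exception hierarchy.

Everything raised on purpose derives from :class:`TremorCmaError` so callers
(and the CLI) can distinguish model/configuration problems from bugs.
"""


class TremorCmaError(Exception):
    """Base class for all errors raised by this package."""


class CatalogValidationError(TremorCmaError, ValueError):
    """A catalog file or in-memory catalog violates its invariants."""


class CostLookupError(TremorCmaError, KeyError):
    """An (item_id, tariff_system) pair is not present in the catalog."""

    def __str__(self) -> str:  # KeyError quotes its message otherwise
        return self.args[0] if self.args else ""


class ConfigurationError(TremorCmaError, ValueError):
    """A scenario / analysis is configured inconsistently."""


class DomainError(TremorCmaError, ValueError):
    """A numeric argument lies outside its mathematical domain."""


class DegenerateFitError(TremorCmaError, ValueError):
    """The linear-consistency oracle received coincident abscissae."""


class AnalysisError(TremorCmaError, RuntimeError):
    """A statistical procedure cannot be carried out (e.g. zero variance)."""
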
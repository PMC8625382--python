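"""Exception hierarchy shared across the package."""


class PhytokinError(Exception):
    """Base class for all package errors."""


class ValidationError(PhytokinError, ValueError):
    """An input violates a documented precondition."""


class ConfigurationError(PhytokinError, ValueError):
    """Inconsistent configuration, e.g. a design temperature without a rate constant."""


class InsufficientDataError(PhytokinError, ValueError):
    """Too few usable observations for the requested fit."""


class SingularDesignError(PhytokinError, ValueError):
    """The regression design matrix is singular (e.g. a single distinct x value)."""


class UndefinedResultError(PhytokinError, ValueError):
    """The requested quantity is undefined for these inputs (e.g. half-life at k <= 0)."""


class NoCrossingError(PhytokinError, ValueError):
    """The dose-response fit never crosses 50% inhibition (non-positive slope)."""


class ParseError(PhytokinError, ValueError):
    """A data file could not be parsed into the expected table."""
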
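"""Exception hierarchy shared across the package."""


class NicheCoexistError(Exception):
    """Base class for all package errors."""


class SchemaError(NicheCoexistError):
    """A table is missing a mandatory column or has a malformed header."""


class ParseError(NicheCoexistError):
    """A cell could not be parsed as the declared type."""


class ValidationError(NicheCoexistError):
    """A value violates a domain invariant (closed vocabulary, sign, ...)."""


class DomainError(NicheCoexistError):
    """An argument is outside the mathematical domain of an operation."""


class DegenerateDataError(NicheCoexistError):
    """Input is formally valid but degenerate for the requested analysis."""


class ConfigError(NicheCoexistError):
    """A simulation or analysis configuration violates its invariants."""


class ContractError(NicheCoexistError):
    """A call violates an API contract (mismatched shapes, bad counts, ...)."""
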
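"""Exception types shared across the package."""


class GxeError(Exception):
    """Base class for all package-specific errors."""


class ParseError(GxeError, ValueError):
    """A delimited input file violates the expected layout."""


class BalanceError(GxeError, ValueError):
    """A design is unbalanced where a balanced layout is required."""


class InvalidInputError(GxeError, ValueError):
    """A numeric argument is outside its valid domain (non-finite Ct, etc.)."""


class SpecError(GxeError, ValueError):
    """A simulation specification violates its invariants."""
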
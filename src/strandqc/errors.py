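"""Exception types shared across the package."""


class StrandQCError(Exception):
    """Base class for all package-specific errors."""


class ParseError(StrandQCError, ValueError):
    """A record in an input file could not be parsed."""


class ValidationError(StrandQCError, ValueError):
    """A parsed object violates one of its invariants."""


class ConsistencyError(StrandQCError, ValueError):
    """Two inputs that must agree (e.g. panel table vs. sequences) do not."""
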
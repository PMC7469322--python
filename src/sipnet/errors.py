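"""Exception hierarchy shared across the package."""


class SipnetError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(SipnetError, ValueError):
    """An input violates a documented invariant."""


class FormatError(ValidationError):
    """A file does not conform to its declared dialect."""


class NodeNotFoundError(SipnetError, KeyError):
    """A queried node is absent from the graph."""


class OracleCapError(SipnetError, RuntimeError):
    """A brute-force oracle was asked to run above its size cap."""
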
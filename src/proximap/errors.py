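"""Exception hierarchy shared across the package."""


class ProximapError(Exception):
    """Base class for all package-specific errors."""


class FormatError(ProximapError):
    """A file did not conform to the expected tabular dialect."""


class ValidationError(ProximapError):
    """Parsed or computed values violate a documented invariant."""
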
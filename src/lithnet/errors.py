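"""Exception hierarchy.

``FormatError`` covers malformed external files, ``ValidationError`` covers
semantically invalid data or arguments, ``ConfigError`` covers invalid
generator/pipeline configurations.  All derive from ``LithnetError`` so
callers can catch the package's failures with one clause.
"""


class LithnetError(Exception):
    """Base class for all lithnet errors."""


class FormatError(LithnetError, ValueError):
    """A file does not conform to its declared format."""


class ValidationError(LithnetError, ValueError):
    """Data or arguments violate a documented invariant."""


class ConfigError(LithnetError, ValueError):
    """A configuration object violates its invariants."""
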
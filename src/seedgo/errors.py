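"""Exception hierarchy.

``SeedgoError`` covers everything a user can cause (bad files, bad
config, invalid arguments); anything else escaping the package is a bug.
"""


class SeedgoError(Exception):
    """Base class for user-facing errors."""


class FormatError(SeedgoError):
    """An input file violates its declared format or an invariant."""


class ConfigError(SeedgoError):
    """A pipeline configuration file is invalid."""
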
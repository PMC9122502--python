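"""Shared exception hierarchy.

Exit-code mapping used by the CLI: ConfigError -> 2, DataError -> 3.
"""


class SdmalError(Exception):
    """Base class for all package errors."""


class ConfigError(SdmalError):
    """Invalid configuration or parameter value."""


class DataError(SdmalError):
    """Malformed or empty input data."""


class VcfParseError(DataError):
    """A VCF record could not be interpreted."""


class EmptyInputError(DataError):
    """An input yielded zero usable records."""


class EmptyResultError(DataError):
    """A filter or analysis step removed every record."""
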
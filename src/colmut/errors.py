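"""Exception types shared across the package."""


class ColmutError(Exception):
    """Base class for package errors."""


class ConfigError(ColmutError, ValueError):
    """A simulation or scan configuration field is invalid."""


class FormatError(ColmutError, ValueError):
    """An input file does not match the expected tabular format."""


class DataError(ColmutError, ValueError):
    """Input data violate a contract (e.g. nonpositive gene length)."""


class InsufficientBackgroundError(ColmutError, RuntimeError):
    """Too few valid background draws to form an empirical null."""
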
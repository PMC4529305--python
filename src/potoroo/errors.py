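"""Exception types raised across the package."""


class PotorooError(Exception):
    """Base class for package errors."""


class SizingError(PotorooError):
    """A simulation cannot be placed within the requested genome size."""


class FormatError(PotorooError):
    """Malformed sequence, quality or table input."""


class GroupingError(PotorooError):
    """A transcript identifier cannot be assigned to a locus."""


class ConfigError(PotorooError):
    """Invalid configuration or parameter value."""
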
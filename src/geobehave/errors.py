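"""Exception hierarchy shared across the package.

Exit-code mapping used by the CLI: ConfigError -> 2, InputError -> 3.
"""


class GeobehaveError(Exception):
    """Base class for all package errors."""


class InputError(GeobehaveError):
    """Invalid input data: bad coordinates, malformed rows, invalid geohash codes."""


class ConfigError(GeobehaveError):
    """Invalid configuration: unknown categories, overlapping periods, bad thresholds."""


class InsufficientDataError(GeobehaveError):
    """A statistic is requested on fewer observations than it is defined for."""


class DegenerateDataError(GeobehaveError):
    """A statistic is undefined on the given data (e.g. zero variance)."""
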
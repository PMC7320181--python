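"""Exception hierarchy.

Two top-level families so the command line can map them to distinct exit
codes: configuration problems (bad parameters, unreadable config) versus
data problems (malformed files, degenerate inputs).
"""


class BodycompError(Exception):
    """Base class for all package errors."""


class ConfigError(BodycompError):
    """Invalid parameter or configuration value."""


class DataError(BodycompError):
    """Malformed or unusable input data."""


class FormatError(DataError):
    """A file does not match its expected format."""


class InvalidPolygonError(DataError):
    """A polygon is degenerate or self-intersecting."""


class DegenerateDataError(DataError):
    """Data whose variance structure makes the requested statistic undefined."""
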
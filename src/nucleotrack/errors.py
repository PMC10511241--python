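"""Exception hierarchy for nucleotrack.

All errors raised by the library derive from :class:`NucleotrackError` so
callers can catch pipeline failures with a single except clause.
"""


class NucleotrackError(Exception):
    """Base class for all nucleotrack errors."""


class FormatError(NucleotrackError):
    """Input table does not have the required layout (e.g. missing column)."""


class DataError(NucleotrackError):
    """Input values are unusable (duplicates, unparseable cells, gaps)."""


class ParameterError(NucleotrackError):
    """A parameter is out of its valid domain."""


class EstimationError(NucleotrackError):
    """An estimator has too little or degenerate data to run."""


class CoverageError(NucleotrackError):
    """A correction model does not cover every frame it is applied to."""


class ComparisonError(NucleotrackError):
    """Two results that must refer to the same data do not."""
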
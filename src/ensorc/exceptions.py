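"""Exception hierarchy for ensorc.

Everything derives from :class:`EnsorcError` so callers can catch the
package's failures with a single except clause; the subclasses map onto
the distinct failure modes of the pipeline stages.
"""


class EnsorcError(Exception):
    """Base class for all ensorc errors."""


class ConfigurationError(EnsorcError, ValueError):
    """An invalid configuration value (counts < 1, rates outside [0, 1], ...)."""


class AlignmentError(EnsorcError, ValueError):
    """Matrices that must share a time axis or dimension do not."""


class SeriesLengthError(EnsorcError, ValueError):
    """A series is too short for the requested delay embedding or lag."""


class ConditioningError(EnsorcError, ValueError):
    """A (near-)singular Gram matrix; usually fixed by a ridge penalty > 0."""


class DegenerateDataError(EnsorcError, ValueError):
    """Zero-variance or otherwise degenerate data where statistics are undefined."""
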
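"""Exception hierarchy for pbvent.

Every error raised on purpose by this package derives from :class:`PBVentError`
so callers can catch the whole family with one clause.
"""


class PBVentError(Exception):
    """Base class for all pbvent errors."""


class ParameterError(PBVentError, ValueError):
    """An invalid parameter value; the message names the offending field."""


class SeriesFormatError(PBVentError, ValueError):
    """A breath series or manifest file violates the expected CSV dialect."""


class InsufficientHistoryError(PBVentError, ValueError):
    """The series is too short for the requested pre-peak window."""


class DegenerateSeriesError(PBVentError, ValueError):
    """The data cannot support the requested fit (e.g. constant window)."""


class ResidueReached(PBVentError):
    """Signal used inside EMD: too few extrema remain to build envelopes."""
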
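"""Exception hierarchy shared across the package.

Every error raised by gabaclamp derives from :class:`GabaClampError` so callers
can catch pipeline failures with a single except clause while still
distinguishing contract violations (bad metadata, bad units) from data-driven
exclusions (too few events, unreachable fit windows).
"""


class GabaClampError(Exception):
    """Base class for all gabaclamp errors."""


class FormatError(GabaClampError, ValueError):
    """A file or container violates the sweep-set layout contract."""


class UnitError(GabaClampError, ValueError):
    """A trace carries the wrong unit for the requested operation."""


class StateError(GabaClampError, RuntimeError):
    """An operation was applied in an invalid object state (e.g. double LJP)."""


class ParameterError(GabaClampError, ValueError):
    """A model or protocol parameter is out of its admissible range."""


class DataError(GabaClampError, ValueError):
    """Trace content is unusable (non-finite samples, too short, no transient)."""


class WindowError(GabaClampError, ValueError):
    """A required measurement window cannot be placed on the trace."""


class InsufficientEventsError(GabaClampError, ValueError):
    """Fewer usable events/sweeps than the per-cell minimum; cell excluded."""


class ProtocolError(GabaClampError, ValueError):
    """A stimulation protocol is internally inconsistent or unreachable."""


class EstimationError(GabaClampError, ValueError):
    """A passive-property estimate cannot be formed from the given response."""


class SpecError(GabaClampError, ValueError):
    """A synthetic-cohort specification is infeasible."""


class DesignError(GabaClampError, ValueError):
    """A statistical design is degenerate (e.g. an empty factorial cell)."""
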
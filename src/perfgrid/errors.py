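"""Typed exceptions shared across the package.

Validation failures raise :class:`ValueError` subclasses so callers can catch
either the specific or the generic type; statistical degeneracy is kept
separate because a silent NaN inside a bootstrap loop would corrupt the
replicate distribution.
"""


class PerfGridError(Exception):
    """Base class for package-specific errors."""


class DegenerateLandmarksError(PerfGridError, ValueError):
    """Fovea and optic-disc landmarks coincide (no axis/scale is defined)."""


class IncompatibleSessionsError(PerfGridError, ValueError):
    """Two grading sessions cannot be paired (different image, grid, or grader)."""


class UngradableScoreError(PerfGridError, ValueError):
    """A perfusion score was requested for an UNGRADABLE cell."""


class UndefinedStatisticError(PerfGridError, ArithmeticError):
    """A statistic's denominator is zero (e.g. constant input to tau-b)."""


class DegenerateStatisticError(PerfGridError, ArithmeticError):
    """Expected disagreement is zero, so chance-corrected agreement is undefined."""


class BootstrapFailureError(PerfGridError, RuntimeError):
    """The statistic was undefined on too large a fraction of bootstrap replicates."""
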
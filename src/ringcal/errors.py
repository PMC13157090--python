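"""Exception hierarchy with stable CLI exit codes.

Exit-code contract: 0 success, 2 no ring found, 3 circle fit failed,
4 I/O or format problem, 5 configuration problem. Batch drivers triage
failures mechanically on these codes.
"""

from __future__ import annotations


class RingCalError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class FormatError(RingCalError):
    """Unreadable or structurally invalid input file."""

    exit_code = 4


class ParameterError(RingCalError):
    """An argument violates an operation's precondition."""

    exit_code = 5


class ConfigError(RingCalError):
    """Invalid or unknown configuration key/value."""

    exit_code = 5


class DegenerateGeometryError(RingCalError):
    """Input geometry is rank-deficient (e.g. collinear points for a plane)."""

    exit_code = 3


class NoRingFoundError(RingCalError):
    """No red cluster passed the ring-likeness tests.

    Carries per-cluster diagnostics so a failed scene can be triaged
    without rerunning.
    """

    exit_code = 2

    def __init__(self, message: str, diagnostics: list | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or []


class FitFailedError(RingCalError):
    """Circle fit did not reach the required inlier fraction."""

    exit_code = 3

    def __init__(self, message: str, best_inlier_frac: float | None = None):
        super().__init__(message)
        self.best_inlier_frac = best_inlier_frac


class AmbiguousOrientationError(RingCalError):
    """Plant centroid lies on the ring plane; up-direction undecidable."""

    exit_code = 3
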
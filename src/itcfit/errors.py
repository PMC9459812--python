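"""Named error kinds raised across the package."""


class ItcError(Exception):
    """Base class for all package errors."""


class ThermogramFormatError(ItcError):
    """Malformed thermogram file: missing header, columns or sidecar."""


class MonotonicityError(ThermogramFormatError):
    """Time axis not strictly increasing / not uniformly sampled."""


class ScheduleError(ItcError):
    """Invalid injection schedule (overlap, non-increasing starts, dV >= V0)."""


class BaselineError(ItcError):
    """Quiet window too short for baseline anchoring even after widening."""


class FitError(ItcError):
    """Nonlinear fit failed: non-identifiable data or no convergence."""


class ModelOrientationError(FitError):
    """Dose-response data oriented against the model (IA falling with dose)."""


class BracketingError(FitError):
    """Dose series does not bracket the 50% response level."""


class LedgerError(ItcError):
    """Heat ledger violates its invariants (zero denominator etc.)."""
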
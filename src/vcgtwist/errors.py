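"""Exception hierarchy shared across the pipeline."""


class VcgTwistError(Exception):
    """Base class for all package-specific errors."""


class LeadSetError(VcgTwistError):
    """Required ECG leads are missing or mislabelled."""


class SignalQualityError(VcgTwistError):
    """Signal is corrupt, flat or contains non-finite samples."""


class ResampleError(VcgTwistError):
    """Sampling rate too low or resampling misconfigured."""


class FilterConfigError(VcgTwistError):
    """Unstable or inconsistent filter configuration."""


class InsufficientBeatsError(VcgTwistError):
    """Fewer accepted beats than the minimum required."""


class DelineationError(VcgTwistError):
    """Fiducial points cannot be determined or violate ordering."""


class WindowError(VcgTwistError):
    """Analysis window too short or inconsistent with the delineation."""


class DegenerateSegmentError(VcgTwistError):
    """Segment has no usable signal content (rank 0 or zero-area vector)."""


class SpecError(VcgTwistError):
    """Invalid synthetic-signal or synthetic-cohort specification."""


class DataError(VcgTwistError):
    """Cohort table violates the schema or contains impossible values."""


class FitError(VcgTwistError):
    """Hazard-model fit failed (non-convergence, no information, separation)."""


class FormatError(VcgTwistError):
    """Unsupported or undeclared file format."""
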
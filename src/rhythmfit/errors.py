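"""Exception hierarchy shared across the package."""


class RhythmfitError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(RhythmfitError, ValueError):
    """Invalid user input: out-of-range parameter, malformed table, bad label."""


class ConfigurationError(RhythmfitError):
    """Inconsistent configuration, e.g. a gene without a simulation truth."""


class FitError(RhythmfitError):
    """Regression could not be carried out (rank-deficient design, too few points)."""


class CalibrationError(RhythmfitError):
    """Growth calibration or dosing failed (too few rows, non-positive density)."""
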
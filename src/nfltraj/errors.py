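"""Exception hierarchy for the nfltraj pipeline."""


class NflTrajError(Exception):
    """Base class for all package errors."""


class ConfigError(NflTrajError):
    """Invalid simulation or run configuration; message names the offending field."""


class StagingError(NflTrajError):
    """Raised when EYO staging inputs are missing or inconsistent."""


class QCError(NflTrajError):
    """Raised for invalid assay replicate values or transforms."""


class SpecError(NflTrajError):
    """Invalid spline specification (unordered or degenerate knots)."""


class FitError(NflTrajError):
    """Model fitting failed or a non-converged fit was used without force."""
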
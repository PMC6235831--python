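"""Exception hierarchy.

All package-specific errors derive from :class:`SynaptrainError` so callers can
catch one base class; validation errors additionally derive from ``ValueError``.
"""


class SynaptrainError(Exception):
    """Base class for all synaptrain errors."""


class FormatError(SynaptrainError):
    """A file does not conform to the expected on-disk format."""


class ValidationError(SynaptrainError, ValueError):
    """Input data violate a documented invariant (shape, range, convention)."""


class ConfigurationError(SynaptrainError):
    """A parameterization is inconsistent or unknown (e.g. bad preset name)."""


class CalibrationError(SynaptrainError):
    """A calibration target is unattainable within the search bracket."""

    def __init__(self, message: str, bracket: tuple | None = None):
        super().__init__(message)
        self.bracket = bracket


class EmptySampleError(SynaptrainError):
    """An operation that needs at least one observation received none."""
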
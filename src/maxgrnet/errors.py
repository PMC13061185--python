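"""Exception taxonomy shared across the package."""


class MaxGRNetError(Exception):
    """Base class for package errors."""


class ConfigurationError(MaxGRNetError, ValueError):
    """A config value is inconsistent (bad lengths, even blur kernel, ...)."""


class ValidationError(MaxGRNetError, ValueError):
    """Runtime input violates a precondition (non-finite values, bad shape)."""


class ShapeError(ValidationError):
    """Spatial dimensions incompatible with a partition or a layer."""


class DegenerateInputError(MaxGRNetError, ValueError):
    """Statistical input with no variation where variation is required."""


class LeakageError(MaxGRNetError, RuntimeError):
    """Train/evaluation subsets share samples (or augmented descendants)."""
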
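"""Exception hierarchy used across the package."""


class TavrsimError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(TavrsimError, ValueError):
    """An anatomy / device / solver parameter is outside its valid domain."""


class UnsupportedDeviceError(TavrsimError, KeyError):
    """Requested device model is not in the catalog."""


class CapacityError(TavrsimError, ValueError):
    """A calcium deposit request exceeds the capacity of its target region."""


class ConvergenceError(TavrsimError, RuntimeError):
    """Quasi-static contact solve failed to converge.

    Carries the residual history so the caller can diagnose the failure.
    """

    def __init__(self, message: str, residual_history=None):
        super().__init__(message)
        self.residual_history = list(residual_history or [])


class EmptyRegionError(TavrsimError, ValueError):
    """A region of interest contains no elements."""


class DegenerateInputError(TavrsimError, ValueError):
    """Statistical input is degenerate (single class, zero variance, ...)."""


class ConfigError(TavrsimError, ValueError):
    """A configuration file violates the schema; message carries the field path."""
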
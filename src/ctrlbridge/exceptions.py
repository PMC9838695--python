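"""Exception and warning types used across the package."""


class CtrlBridgeError(Exception):
    """Base class for all package errors."""


class InvalidArgumentError(CtrlBridgeError, ValueError):
    """An argument is out of the documented domain (non-finite, wrong sign, ...)."""


class StabilityError(CtrlBridgeError):
    """The drift matrix is not Hurwitz where a steady state is required."""


class ConvergenceError(CtrlBridgeError):
    """An iterative solve failed to reach its residual tolerance."""


class ConditioningError(CtrlBridgeError):
    """A matrix required to be well conditioned is numerically singular."""


class ConsistencyError(CtrlBridgeError):
    """Two algebraically equivalent computations disagree beyond tolerance."""


class ResolutionError(CtrlBridgeError):
    """A time grid or step size is too coarse for the requested accuracy."""


class LabelingError(CtrlBridgeError):
    """Required block labels are absent or empty."""


class InsufficientDataError(CtrlBridgeError):
    """Too few timepoints to estimate the requested quantity."""


class NonStationaryError(CtrlBridgeError):
    """Fitted discrete dynamics have an eigenvalue on or outside the unit circle."""


class BranchError(CtrlBridgeError):
    """Principal matrix logarithm is not real within tolerance."""


class SchemaError(CtrlBridgeError):
    """Structured inputs (ROI names, manifests) do not line up."""


class ConditioningWarning(UserWarning):
    """A computation proceeded on a poorly conditioned matrix."""


class AsymmetryWarning(UserWarning):
    """A nominally symmetric matrix showed asymmetry beyond tolerance."""
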
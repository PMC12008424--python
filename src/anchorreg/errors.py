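"""Exception hierarchy for anchorreg."""


class AnchorRegError(Exception):
    """Base class for all anchorreg errors."""


class InvalidParameterError(AnchorRegError, ValueError):
    """A parameter violates its documented constraints."""


class SingularTransformError(AnchorRegError, ValueError):
    """A transform matrix is singular (|det| below tolerance)."""


class DegenerateProjectionError(AnchorRegError, ValueError):
    """A projected point falls (numerically) at infinity (z ~ 0)."""

    def __init__(self, message: str, indices=None):
        super().__init__(message)
        self.indices = list(indices) if indices is not None else []


class DetectionFailureError(AnchorRegError, RuntimeError):
    """Feature detection could not find the expected structure."""


class PlacementFailureError(AnchorRegError, RuntimeError):
    """Rough model placement found no admissible pairing."""


class InsufficientDataError(AnchorRegError, ValueError):
    """Fewer correspondences than the estimator requires."""


class DegeneracyError(AnchorRegError, RuntimeError):
    """All sampled minimal subsets were geometrically degenerate."""
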
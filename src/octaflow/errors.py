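"""Exception hierarchy shared across the package."""


class OctaflowError(Exception):
    """Base class for all octaflow-specific errors."""


class DegenerateInputError(OctaflowError, ValueError):
    """Input carries no usable structure (e.g. a constant-intensity image)."""


class SegmentTooShortError(OctaflowError, ValueError):
    """Centerline has too few points for tangent estimation."""


class DegenerateSegmentError(OctaflowError, ValueError):
    """Centerline with zero chord length (closed loop)."""


class PhaseWrapError(OctaflowError, ValueError):
    """Doppler phase outside the principal interval (-pi, pi]."""


class SingularDesignError(OctaflowError, ValueError):
    """Model design matrix is rank deficient; names the collinear columns."""
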
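"""Exception hierarchy shared across the pipeline stages."""


class RingomicsError(Exception):
    """Base class for all package errors."""


class ValidationError(RingomicsError):
    """Invalid parameter or malformed input value."""


class GeometryError(RingomicsError):
    """Geometric constraint violated (e.g. tumor does not fit the grid)."""


class AlignmentError(RingomicsError):
    """Mask and volume do not share shape/spacing/origin."""


class DegenerateROIError(RingomicsError):
    """ROI is empty or too small for the requested computation."""


class SchemaError(RingomicsError):
    """A required column/feature/covariate is missing from tabular input."""


class SignatureEmptyError(RingomicsError):
    """LASSO kept no features at the selected penalty."""


class ConvergenceError(RingomicsError):
    """Iterative fit failed to converge; carries diagnostic context."""
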
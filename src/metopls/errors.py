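"""Exception hierarchy shared across the package."""


class MetoplsError(Exception):
    """Base class for all package-specific errors."""


class FormatError(MetoplsError):
    """Malformed input file: ragged rows, bad cells, missing columns."""


class DuplicateIdError(FormatError):
    """Duplicate sample or metabolite identifier."""


class SpecError(MetoplsError):
    """Invalid effect specification for the simulator."""


class MissingLODError(MetoplsError):
    """A metabolite in the table has no limit of detection on record."""


class DegenerateBridgeError(MetoplsError):
    """Bridge sample missing, unmeasured or zero in some batch."""


class DegenerateSampleError(MetoplsError):
    """A sample row with zero total concentration."""


class ConstantMetaboliteError(MetoplsError):
    """Zero-variance metabolite column where scaling is required."""


class NotCenteredError(MetoplsError):
    """Matrix handed to a latent model is not column-centered."""


class ConvergenceError(MetoplsError):
    """NIPALS iteration failed to converge within the iteration cap."""


class DegenerateYError(MetoplsError):
    """Response vector with zero variance."""


class RankError(MetoplsError):
    """Deflated X is rank-deficient; too many orthogonal components."""


class ShapeError(MetoplsError):
    """Dimension mismatch between model and new data."""


class FoldDegenerateError(MetoplsError):
    """A cross-validation fold with zero response variance."""


class DegenerateError(MetoplsError):
    """Degenerate statistical input (insufficient n, zero variance)."""


class DesignError(MetoplsError):
    """Study design does not support the requested analysis."""
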
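"""Exception types shared across the toolkit."""


class DataError(RuntimeError):
    """Raised when input data are malformed (non-finite fringes, grid mismatch...)."""


class DegenerateInputError(ValueError):
    """Raised when an input is formally valid but carries no usable signal
    (constant image passed to a correlator or a segmenter, collinear
    calibration displacements, all-identical metric values)."""


class NoInterfaceError(RuntimeError):
    """Raised when no water/tissue interface edge is found in an axial profile."""


class InfeasibleConstraintsError(RuntimeError):
    """Raised when ROI sampling constraints cannot be satisfied at all
    (empty eroded candidate mask with n > 0)."""
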
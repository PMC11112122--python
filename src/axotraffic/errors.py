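"""Exception types shared across the package.

All inherit from ValueError so callers can catch broadly; the subclasses
exist to make failure modes distinguishable in tests and CLI messages.
"""


class ParameterError(ValueError):
    """A generator or analysis parameter violates its stated constraints."""


class GeometryError(ValueError):
    """Degenerate ROI geometry (zero-length polyline, bad vertices)."""


class BoundsError(ValueError):
    """Coordinates fall outside the image or kymograph extent."""


class CalibrationError(ValueError):
    """Missing or inconsistent spatial/temporal calibration."""


class InputError(ValueError):
    """Malformed input data (non-contiguous frames, mismatched shapes)."""


class DegenerateInputError(ValueError):
    """Input is valid in form but carries no usable signal (zero variance)."""


class InsufficientDataError(ValueError):
    """Too few observations for the requested statistic."""
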
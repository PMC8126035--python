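"""Exception hierarchy.

Validation errors map to CLI exit code 2, I/O errors to exit code 3.
"""


class HemocountError(Exception):
    """Base class for all package errors."""


class ValidationError(HemocountError, ValueError):
    """Input violates a documented precondition or invariant."""


class FormatError(ValidationError):
    """An image file is readable but not an 8-bit 3-channel raster."""


class EmptyTrainingError(ValidationError):
    """No usable hemocyte pixels were supplied for calibration."""


class DegenerateVarianceError(ValidationError):
    """All observations identical; ANOVA mean squares are undefined."""


class PlacementError(HemocountError):
    """Synthetic object placement failed under the separation constraint."""

    def __init__(self, requested: int, achieved: int, kind: str):
        self.requested = requested
        self.achieved = achieved
        self.kind = kind
        super().__init__(
            f"could not place {requested} {kind} objects at the required "
            f"separation (placed {achieved}); enlarge the field or relax "
            f"min_separation"
        )
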
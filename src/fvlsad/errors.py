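"""Exception hierarchy for the FVL small-airway-disease toolchain.

Every failure mode that a batch run must survive maps to a distinct
subclass so the pipeline can record a per-input status instead of
aborting.
"""


class FvlsadError(Exception):
    """Base class for all package errors."""

    #: short machine-readable status token used in run manifests
    status = "error"


class InvalidInputError(FvlsadError):
    status = "invalid-input"


class PanelNotFoundError(FvlsadError):
    """No window on the page matched the locator glyph within threshold."""

    status = "panel-not-found"

    def __init__(self, message: str, best_distance: int | None = None):
        super().__init__(message)
        self.best_distance = best_distance


class CalibrationError(FvlsadError):
    """Axis digit not found, or the affine fit is degenerate."""

    status = "calibration-failed"

    def __init__(self, message: str, axis: str | None = None):
        super().__init__(message)
        self.axis = axis


class TraceError(FvlsadError):
    status = "trace-failed"


class DegenerateCurveError(FvlsadError):
    """Curve geometry admits no valid A-B segment (peak at/after 75% FVC)."""

    status = "degenerate-curve"


class InsufficientPointsError(FvlsadError):
    status = "insufficient-points"


class UndefinedRatioError(FvlsadError):
    """BC slope is exactly zero: log(BC/A-x) is undefined, not -inf."""

    status = "undefined-ratio"


class InsufficientDataError(FvlsadError):
    status = "insufficient-data"


class DegenerateVarianceError(FvlsadError):
    status = "degenerate-variance"


class InvalidSpecError(FvlsadError):
    """Synthetic curve specification is internally inconsistent."""

    status = "invalid-spec"


class InvalidLayoutError(FvlsadError):
    status = "invalid-layout"
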
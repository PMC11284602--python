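"""Exception hierarchy for the phenoplane pipeline."""


class PhenoplaneError(Exception):
    """Base class for all phenoplane errors."""


# --- fiducial / calibration -------------------------------------------------

class MarkerNotFound(PhenoplaneError):
    """No candidate fiducial quadrilateral passed the contrast/convexity screens."""


class AmbiguousMarker(PhenoplaneError):
    """More than one candidate fiducial survived screening."""


class DegenerateCorners(PhenoplaneError):
    """Three or more marker corners are collinear; no homography exists."""


class PointAtInfinity(PhenoplaneError):
    """Homogeneous coordinate vanished while mapping a point."""


# --- backends / traits ------------------------------------------------------

class BoxOutOfBounds(PhenoplaneError):
    """A detection box extends past the image bounds."""


class EmptyMask(PhenoplaneError):
    """A mask with no foreground was passed where content is required."""


class LabelMismatch(PhenoplaneError):
    """A detection with the wrong class label was passed to a trait operation."""


# --- weight model / stats ---------------------------------------------------

class DegenerateFit(PhenoplaneError):
    """Regression input is degenerate (e.g. constant predictor)."""


class InsufficientPairs(PhenoplaneError):
    """Too few paired observations for a validation statistic."""


class TooFewSamples(PhenoplaneError):
    """Fewer samples than clusters requested."""


class DegenerateGroups(PhenoplaneError):
    """Group comparison requested on data with zero total variance."""


# --- io ---------------------------------------------------------------------

class MalformedRow(PhenoplaneError):
    """An annotation CSV row could not be parsed.

    Carries the 1-based row number in ``row``.
    """

    def __init__(self, row: int, message: str = ""):
        self.row = row
        super().__init__(f"row {row}: {message}" if message else f"row {row}")


class MissingLabel(PhenoplaneError):
    """A v2 annotation region lacks the mandatory class label."""


class MalformedJSON(PhenoplaneError):
    """An annotation JSON file could not be parsed."""


# --- synthetic scenes -------------------------------------------------------

class PartOutOfFrame(PhenoplaneError):
    """A scene part (or the marker) does not fit inside the image frame."""
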
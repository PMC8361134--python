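"""Exception hierarchy shared by all analysis stages."""


class SpheromatrixError(Exception):
    """Base class for all package errors."""


class ConfigurationError(SpheromatrixError):
    """Metadata/configuration inconsistent with the data (e.g. axis mismatch)."""


class ParameterError(SpheromatrixError):
    """A parameter value violates its contract (e.g. non-positive length)."""


class SegmentationError(SpheromatrixError):
    """Spheroid could not be delineated; carries a qc flag string."""

    def __init__(self, flag: str = "segmentation_failed", msg: str | None = None):
        super().__init__(msg or flag)
        self.flag = flag


class EmptyRingError(SpheromatrixError):
    """A requested ring/shell contains no pixels or beads."""


class DegenerateSampleError(SpheromatrixError):
    """Statistical sample degenerate (e.g. all values equal the null value)."""
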
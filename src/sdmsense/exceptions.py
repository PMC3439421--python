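"""Exception hierarchy for sdmsense.

Every error raised by the library derives from :class:`SdmError`, so callers
(e.g. the factorial runner, which must never abort a whole grid because one
cell failed) can catch a single base class.
"""


class SdmError(Exception):
    """Base class for all sdmsense errors."""


class AlignmentError(SdmError):
    """Raster layers or grids do not share the same geometry."""


class DegenerateExtentError(SdmError):
    """An extent mask leaves no usable cells."""


class PartitionError(SdmError):
    """A train/test partition cannot honor its minimum-size constraints."""


class FitError(SdmError):
    """Model fitting received unusable inputs."""


class ProjectionError(SdmError):
    """A covariate layer required by the model is missing or unusable."""


class EvaluationError(SdmError):
    """An evaluation statistic is undefined for the given inputs."""


class SamplingError(SdmError):
    """Occurrence sampling is impossible (e.g. all-zero suitability)."""
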
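"""Exception hierarchy for the synapsekin pipeline.

Every anticipated failure mode raises a subclass of :class:`SynapsekinError`
so that batch drivers can catch one type, log the cell, and move on.
"""


class SynapsekinError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(SynapsekinError, ValueError):
    """A physical or geometric parameter is out of its valid range."""


class GeometryError(SynapsekinError, ValueError):
    """A generated or requested geometry is degenerate or inconsistent."""


class SegmentationError(SynapsekinError, RuntimeError):
    """Thresholding/labelling produced no usable object."""


class DetectionError(SynapsekinError, RuntimeError):
    """Punctum or landmark detection found nothing above the noise floor."""


class DegenerateFrameError(SynapsekinError, ValueError):
    """A frame is unusable for the requested correction (e.g. zero mean)."""


class DegenerateRatioError(SynapsekinError, ZeroDivisionError):
    """A ratio metric's denominator is zero."""


class AmbiguousShapeError(SynapsekinError, RuntimeError):
    """Surface curvature is too uniform to define a landmark."""


class ConfigError(SynapsekinError, ValueError):
    """Run configuration is incomplete or inconsistent."""
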
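"""2D cell and nucleus morphology on maximum z-projections.

Aspect ratio is major/minor axis of the second-moment-equivalent ellipse
(not a bounding box), solidity is mask area over convex-hull area; their
temporal summaries (percent CV of aspect ratio, median solidity) quantify
shape stability — blebbing, deforming cells score a high aspect-ratio CV
and low solidity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.measure import label, regionprops

from .core import Mask3D
from .errors import InvalidParameterError
from .kinetics import cv_percent

__all__ = ["ShapeSample", "project_max_z", "shape_sample", "summarize_shape"]


@dataclass
class ShapeSample:
    """Shape descriptors of one object in one frame."""

    time: float
    aspect_ratio: float
    solidity: float
    object: str = "cell"

    def __post_init__(self) -> None:
        if self.aspect_ratio < 1 or not (0 < self.solidity <= 1):
            raise InvalidParameterError(
                f"invalid shape sample: AR={self.aspect_ratio}, solidity={self.solidity}"
            )


def project_max_z(volume) -> np.ndarray:
    """Maximum z-projection; boolean masks project by logical OR."""
    if isinstance(volume, Mask3D):
        return volume.voxels.any(axis=0)
    arr = np.asarray(volume)
    if arr.ndim != 3:
        raise InvalidParameterError("expected a (z, y, x) stack")
    return arr.any(axis=0) if arr.dtype == bool else arr.max(axis=0)


def shape_sample(mask_2d: np.ndarray, time: float = 0.0, object: str = "cell") -> ShapeSample:
    """Aspect ratio and solidity of a 2D mask (largest object if several)."""
    mask_2d = np.asarray(mask_2d, bool)
    if mask_2d.sum() < 5:
        raise InvalidParameterError("mask below 5 pixels; shape metrics unreliable")
    lab = label(mask_2d)
    props = max(regionprops(lab), key=lambda p: p.area)
    minor = props.axis_minor_length
    if minor == 0:
        raise InvalidParameterError("degenerate (line-like) mask")
    return ShapeSample(
        time=time,
        aspect_ratio=float(props.axis_major_length / minor),
        solidity=float(props.solidity),
        object=object,
    )


def summarize_shape(samples, stat: str) -> float:
    """Temporal summary over ShapeSamples of one cell.

    ``cv_percent_aspect``: percent CV of the aspect ratio over time;
    ``median_solidity``: median 2D solidity.
    """
    samples = list(samples)
    if len(samples) < 2:
        raise InvalidParameterError("need at least 2 samples")
    if stat == "cv_percent_aspect":
        return cv_percent([s.aspect_ratio for s in samples])
    if stat == "median_solidity":
        return float(np.median([s.solidity for s in samples]))
    raise InvalidParameterError(f"unknown summary {stat!r}")
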
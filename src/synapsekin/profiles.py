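"""Droplet-referenced intensity profiles.

For high-resolution synapse snapshots the droplet mask is fitted to an
ellipsoid, the volume is rigidly re-oriented so the ellipsoid axes align
with the grid (longest on x, shortest on z), and intensity profiles are
extracted: a symmetric radial scan of the synapse face (azimuthally
averaged about the synapse axis) and an axial front-to-rear linescan
normalized for cell length.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from .core import Mask3D
from .errors import GeometryError, InvalidParameterError

__all__ = [
    "Ellipsoid",
    "ProfileCurve",
    "fit_ellipsoid",
    "align_to_ellipsoid",
    "radial_synapse_profile",
    "axial_polarity_profile",
]


@dataclass
class Ellipsoid:
    """Solid ellipsoid: center (um), semi-axes a >= b >= c (um), rotation.

    ``axes`` rows are the unit principal directions in (z, y, x)
    coordinates, ordered longest to shortest; the matrix is proper
    orthonormal.
    """

    center: np.ndarray
    semi_axes: np.ndarray
    axes: np.ndarray

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, float)
        self.semi_axes = np.asarray(self.semi_axes, float)
        self.axes = np.asarray(self.axes, float)
        if np.any(self.semi_axes <= 0):
            raise InvalidParameterError("semi-axes must be positive")
        if not np.all(np.diff(self.semi_axes) <= 1e-9):
            raise InvalidParameterError("semi-axes must be sorted a >= b >= c")


@dataclass
class ProfileCurve:
    """1D intensity profile: radial (um) or axial (normalized length)."""

    abscissa: np.ndarray
    values: np.ndarray
    kind: str = "radial"


def fit_ellipsoid(droplet_mask: Mask3D) -> Ellipsoid:
    """Moment-based ellipsoid fit of a solid voxel mask.

    Centroid plus principal axes of the voxel inertia tensor; for a solid
    ellipsoid the second moment along a principal axis is ``a^2 / 5``, so
    semi-axes are ``sqrt(5) x`` the principal standard deviations.  Robust
    on filled masks and needs no initialization.
    """
    vox = droplet_mask.voxels
    if not vox.any():
        raise GeometryError("empty droplet mask")
    _, n = ndi.label(vox)
    if n != 1:
        raise GeometryError(f"mask has {n} components; fit one droplet at a time")
    pos = np.argwhere(vox) * np.asarray(droplet_mask.voxel_size)
    center = pos.mean(axis=0)
    cov = np.cov((pos - center).T, bias=True)
    evals, evecs = np.linalg.eigh(cov)  # ascending
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    if evals[-1] <= 1e-12:
        raise GeometryError("degenerate (planar) mask cannot define an ellipsoid")
    axes = evecs.T  # rows = principal directions, longest first
    if np.linalg.det(axes) < 0:
        axes[-1] *= -1.0
    return Ellipsoid(center, np.sqrt(5.0 * evals), axes)


def align_to_ellipsoid(volume: np.ndarray, ellipsoid: Ellipsoid, voxel_size) -> np.ndarray:
    """Rigidly re-orient a volume so the ellipsoid axes match the grid.

    The ellipsoid center maps to the grid center and the principal axes
    to (x, y, z) with the longest on x and the shortest on z (the synapse
    viewing axis).  Trilinear resampling; apply the identical transform
    to every channel of an acquisition.
    """
    vs = np.asarray([voxel_size] * 3, float) if np.isscalar(voxel_size) else np.asarray(voxel_size, float)
    shape = np.asarray(volume.shape)
    out_center = (shape - 1) / 2.0 * vs
    # output physical offset (dz, dy, dx) -> input offset
    # dz along shortest axis (axes[2]), dy along middle, dx along longest
    m = np.column_stack([ellipsoid.axes[2], ellipsoid.axes[1], ellipsoid.axes[0]])

    zi, yi, xi = np.meshgrid(*[np.arange(n) * d for n, d in zip(shape, vs)], indexing="ij")
    off = np.stack([zi - out_center[0], yi - out_center[1], xi - out_center[2]])
    inp = np.tensordot(m, off, axes=(1, 0)) + ellipsoid.center[:, None, None, None]
    coords = inp / vs[:, None, None, None]
    return ndi.map_coordinates(volume, coords, order=1, mode="constant", cval=0.0)


def radial_synapse_profile(
    aligned_volume: np.ndarray,
    voxel_size,
    n_planes: int = 25,
    center=None,
) -> ProfileCurve:
    """Symmetric radial scan of the synapse face.

    Averages ``n_planes`` z-planes centered on the (aligned) ellipsoid
    center, then bins the projection by in-plane radius from the synapse
    axis (bin width one pixel) with full azimuthal averaging — the 3D
    extension of averaging the two directions of a symmetric linescan.
    The curve is normalized to its maximum.
    """
    vs = np.asarray([voxel_size] * 3, float) if np.isscalar(voxel_size) else np.asarray(voxel_size, float)
    shape = np.asarray(aligned_volume.shape)
    if center is None:
        center = (shape - 1) / 2.0
    center = np.asarray(center, float)
    z0 = int(round(center[0]))
    half = n_planes // 2
    lo, hi = max(0, z0 - half), min(shape[0], z0 + half + 1)
    proj = aligned_volume[lo:hi].mean(axis=0)
    if proj.max() <= 0:
        raise InvalidParameterError("all-zero projection; no profile to extract")

    yy, xx = np.meshgrid(np.arange(shape[1]), np.arange(shape[2]), indexing="ij")
    r = np.hypot((yy - center[1]) * vs[1], (xx - center[2]) * vs[2])
    bin_w = float(min(vs[1], vs[2]))
    bins = (r / bin_w).astype(int)
    n_bins = bins.max() + 1
    sums = np.bincount(bins.ravel(), weights=proj.ravel(), minlength=n_bins)
    counts = np.bincount(bins.ravel(), minlength=n_bins)
    prof = sums / np.maximum(counts, 1)
    prof /= prof.max()
    return ProfileCurve(np.arange(n_bins) * bin_w, prof, kind="radial")


def axial_polarity_profile(
    channel: np.ndarray,
    cell_mask: Mask3D,
    synapse_axis,
    plane_sel: np.ndarray | None = None,
    n_bins: int = 20,
) -> ProfileCurve:
    """Front-to-rear linescan along the synapse axis, length-normalized.

    Voxel intensities inside the cell mask (optionally restricted to
    selected z-planes around the synapse) are summed in equal-width slabs
    orthogonal to ``synapse_axis`` (droplet center -> cell centroid, i.e.
    pointing rearward).  The abscissa runs from exactly 0 (synapse end)
    to exactly 1 (cell rear).
    """
    axis = np.asarray(synapse_axis, float)
    axis /= np.linalg.norm(axis)
    vox = cell_mask.voxels
    if plane_sel is not None:
        vox = vox & plane_sel[:, None, None]
    if not vox.any():
        raise InvalidParameterError("cell mask empty in the selected planes")
    idx = np.argwhere(vox)
    pos = idx * np.asarray(cell_mask.voxel_size)
    s = pos @ axis
    s_lo, s_hi = s.min(), s.max()
    if s_hi <= s_lo:
        raise InvalidParameterError("cell has no extent along the synapse axis")
    u = (s - s_lo) / (s_hi - s_lo)
    b = np.minimum((u * n_bins).astype(int), n_bins - 1)
    vals = channel[tuple(idx.T)]
    sums = np.bincount(b, weights=vals, minlength=n_bins)
    return ProfileCurve(np.linspace(0.0, 1.0, n_bins), sums, kind="axial")


def plot_profiles(profiles_by_condition: dict, ax=None, xlabel: str | None = None):
    """Per-condition mean +/- SEM profile curves on a shared abscissa.

    ``profiles_by_condition`` maps a condition name to a list of
    :class:`ProfileCurve` objects with identical abscissae.  Returns the
    matplotlib axes.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for name, curves in profiles_by_condition.items():
        x = curves[0].abscissa
        stack = np.stack([c.values for c in curves])
        mean = stack.mean(axis=0)
        sem = stack.std(axis=0, ddof=1) / np.sqrt(len(curves)) if len(curves) > 1 else 0 * mean
        ax.plot(x, mean, label=name)
        ax.fill_between(x, mean - sem, mean + sem, alpha=0.3)
    kind = next(iter(profiles_by_condition.values()))[0].kind
    ax.set_xlabel(xlabel or ("radius (um)" if kind == "radial" else "normalized cell length"))
    ax.set_ylabel("normalized intensity")
    ax.legend()
    return ax
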
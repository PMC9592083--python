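"""Synapse-referenced intensity metrics.

Everything measured relative to the cell-droplet contact: antigen
recruitment on the droplet surface, shell enrichment of cytosolic
reporters within a fixed-width layer of the droplet, front/back polarity
ratios, detection of cortical actin maxima on z-projections, whole-cell
channel ratios (acetylated / total tubulin), and the two-droplet
multi-synapse count and actin-asymmetry scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from .core import DistanceField, KineticTrace, Mask3D, VolumeSeries
from .errors import DegenerateRatioError, InvalidParameterError

__all__ = [
    "ShellSpec",
    "SHELL_PRESETS",
    "EnrichmentTrace",
    "antigen_recruitment",
    "shell_enrichment",
    "front_back_ratio",
    "actin_maxima",
    "intensity_ratio_whole_cell",
    "count_synapses",
    "synapse_asymmetry",
]


@dataclass(frozen=True)
class ShellSpec:
    """A fixed-width layer around the droplet surface.

    ``normalization`` controls the denominators: ``cell_total`` divides by
    the whole-cell intensity sum (fractional enrichment), ``t0`` divides
    the trace by its value at cell arrival, ``both`` applies the two in
    sequence, ``none`` reports raw shell sums.  ``planes`` restricts the
    measurement axially: all planes, the single droplet-center plane, or
    ``k`` planes at spacing ``plane_dz`` centered on the synapse.
    """

    width: float = 2.0
    normalization: str = "both"
    planes: str = "all_3d"
    n_planes: int = 1
    plane_dz: float | None = None

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise InvalidParameterError("shell width must be positive")
        if self.normalization not in ("cell_total", "t0", "both", "none"):
            raise InvalidParameterError(f"unknown normalization {self.normalization!r}")
        if self.planes not in ("all_3d", "single_plane", "n_planes"):
            raise InvalidParameterError(f"unknown plane selection {self.planes!r}")
        if self.n_planes < 1:
            raise InvalidParameterError("n_planes must be >= 1")


# Named presets matching the reporter-specific recipes.
SHELL_PRESETS = {
    "actin2um": ShellSpec(width=2.0, normalization="both", planes="all_3d"),
    "dag1um": ShellSpec(width=1.0, normalization="t0", planes="all_3d"),
    "gefh1_1um_1plane": ShellSpec(width=1.0, normalization="cell_total", planes="single_plane"),
    "exoc7_1um_6planes": ShellSpec(
        width=1.0, normalization="cell_total", planes="n_planes", n_planes=6, plane_dz=0.34
    ),
}


@dataclass
class EnrichmentTrace:
    """Per-frame dimensionless enrichment values for one cell."""

    times: np.ndarray
    values: np.ndarray
    t0_index: int = 0
    normalization: str = "none"
    metric_name: str = ""

    def as_kinetic(self, cell_id: str = "") -> KineticTrace:
        return KineticTrace(self.times, self.values, self.metric_name, cell_id)


# ---------------------------------------------------------------------------
# Geometry helpers
# ---------------------------------------------------------------------------

def _surface_voxels(mask: np.ndarray) -> np.ndarray:
    return mask & ~ndi.binary_erosion(mask)


def _plane_selector(shape_z: int, spec: ShellSpec, center_z: int, dz: float) -> np.ndarray:
    """Boolean z-plane selection for a ShellSpec."""
    sel = np.zeros(shape_z, bool)
    if spec.planes == "all_3d":
        sel[:] = True
    elif spec.planes == "single_plane":
        sel[center_z] = True
    else:
        step = 1 if spec.plane_dz is None else max(1, int(round(spec.plane_dz / dz)))
        half = (spec.n_planes - 1) // 2
        idx = center_z + step * (np.arange(spec.n_planes) - half)
        sel[np.clip(idx, 0, shape_z - 1)] = True
    return sel


# ---------------------------------------------------------------------------
# Antigen recruitment
# ---------------------------------------------------------------------------

def antigen_recruitment(
    series: VolumeSeries,
    droplet_mask: Mask3D,
    cell_center_um,
    antigen_channel: str = "antigen",
    t0: int = 0,
    cap_half_angle: float = 60.0,
    n_planes: int = 3,
) -> EnrichmentTrace:
    """Synapse-pole over opposite-pole antigen intensity ratio.

    Per frame the droplet-surface voxels on the three planes through the
    droplet center (center plane +/- 1) are split into the cap facing the
    cell (angle from the droplet-center -> cell-center axis at most
    ``cap_half_angle``) and the antipodal cap; mean intensities are
    ratioed and the trace is normalized by its value at cell arrival
    ``t0``.  A spatially uniform droplet therefore scores exactly 1 at
    every frame.
    """
    chan = series.channel(antigen_channel)
    vs = np.asarray(series.voxel_size)
    surf = _surface_voxels(droplet_mask.voxels)
    d_center = droplet_mask.centroid_um()
    axis = np.asarray(cell_center_um, float) - d_center
    nrm = np.linalg.norm(axis)
    if nrm == 0:
        raise InvalidParameterError("cell center coincides with droplet center")
    axis /= nrm

    idx = np.argwhere(surf)
    rel = idx * vs - d_center
    r = np.linalg.norm(rel, axis=1)
    with np.errstate(invalid="ignore"):
        cosang = (rel @ axis) / np.where(r > 0, r, np.inf)
    cth = np.cos(np.deg2rad(cap_half_angle))

    center_z = int(round(d_center[0] / vs[0]))
    half = n_planes // 2
    z_ok = np.abs(idx[:, 0] - center_z) <= half
    syn = z_ok & (cosang >= cth)
    opp = z_ok & (cosang <= -cth)
    if not syn.any() or not opp.any():
        raise InvalidParameterError("no surface voxels in one of the caps; widen the cap or planes")
    syn_idx = tuple(idx[syn].T)
    opp_idx = tuple(idx[opp].T)

    values = np.empty(series.n_frames)
    for t in range(series.n_frames):
        vol = chan[t]
        opp_mean = vol[opp_idx].mean()
        if opp_mean == 0:
            raise DegenerateRatioError(f"frame {t}: zero opposite-side intensity")
        values[t] = vol[syn_idx].mean() / opp_mean
    if values[t0] == 0:
        raise DegenerateRatioError("zero ratio at cell arrival")
    values = values / values[t0]
    return EnrichmentTrace(series.times, values, t0, "t0", "antigen_recruitment")


# ---------------------------------------------------------------------------
# Shell enrichment
# ---------------------------------------------------------------------------

def shell_enrichment(
    series: VolumeSeries,
    channel: str,
    cell_masks,
    droplet_field: DistanceField,
    spec: ShellSpec = SHELL_PRESETS["actin2um"],
    t0: int = 0,
) -> EnrichmentTrace:
    """Channel intensity within ``spec.width`` um of the droplet surface.

    Per frame: the sum of the channel over cell voxels whose droplet
    distance is at most the shell width, optionally divided by the
    whole-cell sum (``cell_total``) and/or by the value at arrival
    (``t0``).  ``cell_masks`` is one mask per frame, or a single static
    mask.
    """
    chan = series.channel(channel)
    dz = series.voxel_size[0]
    in_shell = droplet_field.values <= spec.width
    if isinstance(cell_masks, Mask3D):
        cell_masks = [cell_masks] * series.n_frames
    # synapse center z: droplet-proximal plane = plane of minimum field value
    center_z = int(np.unravel_index(np.argmin(droplet_field.values), droplet_field.values.shape)[0])
    plane_sel = _plane_selector(series.data.shape[2], spec, center_z, dz)

    values = np.empty(series.n_frames)
    for t, cmask in enumerate(cell_masks):
        cm = cmask.voxels & plane_sel[:, None, None]
        shell_vox = cm & in_shell
        if not shell_vox.any():
            warnings.warn(f"frame {t}: shell does not intersect the cell; enrichment set to 0")
            values[t] = 0.0
            continue
        num = chan[t][shell_vox].sum()
        if spec.normalization in ("cell_total", "both"):
            den = chan[t][cm].sum()
            if den == 0:
                raise DegenerateRatioError(f"frame {t}: zero cell-total intensity")
            values[t] = num / den
        else:
            values[t] = num
    if spec.normalization in ("t0", "both"):
        if values[t0] == 0:
            raise DegenerateRatioError("zero enrichment at arrival; cannot t0-normalize")
        values = values / values[t0]
    return EnrichmentTrace(series.times, values, t0, spec.normalization, f"shell_{spec.width}um")


# ---------------------------------------------------------------------------
# Polarity and whole-cell ratios
# ---------------------------------------------------------------------------

def front_back_ratio(
    volume: np.ndarray,
    cell_mask: Mask3D,
    synapse_axis,
    plane_sel: np.ndarray | None = None,
) -> float:
    """Front (synapse-proximal) over back intensity ratio.

    Cell voxels (optionally restricted to selected z-planes) are split by
    the plane through the cell centroid orthogonal to ``synapse_axis``
    (cell center -> droplet center); returns front-sum / back-sum.
    Flipping the axis returns the reciprocal.
    """
    axis = np.asarray(synapse_axis, float)
    axis /= np.linalg.norm(axis)
    vs = np.asarray(cell_mask.voxel_size)
    vox = cell_mask.voxels
    if plane_sel is not None:
        vox = vox & plane_sel[:, None, None]
    if not vox.any():
        raise InvalidParameterError("cell mask empty in the selected planes")
    idx = np.argwhere(vox)
    pos = idx * vs
    centroid = pos.mean(axis=0)
    side = (pos - centroid) @ axis
    vals = volume[tuple(idx.T)]
    front = vals[side > 0].sum()
    back = vals[side <= 0].sum()
    if back == 0:
        raise DegenerateRatioError("zero back-half intensity")
    return float(front / back)


def intensity_ratio_whole_cell(channel_a: np.ndarray, channel_b: np.ndarray, cell_mask: Mask3D) -> float:
    """Integrated channel-a over channel-b intensity within the cell mask.

    Used for the acetylated-tubulin / total-tubulin ratio.
    """
    if channel_a.shape != channel_b.shape or channel_a.shape != cell_mask.voxels.shape:
        raise InvalidParameterError("channels and mask must share one geometry")
    b = channel_b[cell_mask.voxels].sum()
    if b == 0:
        raise DegenerateRatioError("zero denominator-channel intensity")
    return float(channel_a[cell_mask.voxels].sum() / b)


# ---------------------------------------------------------------------------
# Actin maxima on z-projections
# ---------------------------------------------------------------------------

def actin_maxima(
    projection: np.ndarray,
    cell_mask_2d: np.ndarray,
    droplet_mask_2d: np.ndarray,
    pixel_size: float,
    prominence: float | None = None,
):
    """Count cortical F-actin maxima and their mean distance to the droplet.

    Operates on maximum z-projections.  Maxima are plateaus surviving
    h-maxima suppression at height ``prominence`` (default: 3x the robust
    noise s.d. of the projection) inside the cell mask; the distance of
    each maximum to the droplet boundary is measured on the 2D Euclidean
    distance map.  Returns ``(count, mean_distance_um)`` with the distance
    ``None`` when no maximum is found.
    """
    from skimage.morphology import h_maxima

    if not cell_mask_2d.any():
        raise InvalidParameterError("empty cell mask")
    img = np.asarray(projection, float)
    if prominence is None:
        med = np.median(img)
        prominence = 3.0 * 1.4826 * np.median(np.abs(img - med))
    if prominence <= 0:
        prominence = 1e-6
    peaks = h_maxima(img, prominence) & cell_mask_2d
    lab, n = ndi.label(peaks)
    if n == 0:
        return 0, None
    centroids = np.asarray(ndi.center_of_mass(peaks, lab, index=np.arange(1, n + 1)))
    dist2d = ndi.distance_transform_edt(~droplet_mask_2d.astype(bool), sampling=(pixel_size, pixel_size))
    dists = ndi.map_coordinates(dist2d, centroids.T, order=1)
    return int(n), float(np.mean(dists))


# ---------------------------------------------------------------------------
# Multi-synapse scoring
# ---------------------------------------------------------------------------

def count_synapses(
    cell_mask: Mask3D,
    droplet_masks,
    contact_width: float = 1.0,
) -> int:
    """Number of distinct cell-droplet contact areas (immune synapses).

    Contact regions are connected components of cell voxels within
    ``contact_width`` um of any droplet.  Two droplets engaged through a
    single contiguous contact cap count as one synapse; droplets on
    opposite cell poles count as two.  Returns 0 (with a warning) when
    the cell touches no droplet.
    """
    fields = [ndi.distance_transform_edt(~m.voxels, sampling=m.voxel_size) for m in droplet_masks]
    near_any = np.any([f <= contact_width for f in fields], axis=0)
    contact = cell_mask.voxels & near_any
    lab, n = ndi.label(contact)
    if n == 0:
        warnings.warn("cell contacts no droplet")
        return 0
    count = 0
    for i in range(1, n + 1):
        comp = lab == i
        if any((f[comp] <= contact_width).any() for f in fields):
            count += 1
    return count


def per_synapse_shell_enrichment(
    volume: np.ndarray,
    cell_mask: Mask3D,
    droplet_masks,
    width: float = 2.0,
) -> list[float]:
    """Fractional shell enrichment computed separately for each droplet.

    The shell is restricted, per droplet, to voxels nearer that droplet
    than any other (a Voronoi split of the contact zone), so the two
    synapses of a two-droplet cell are scored independently.  Each value
    is the shell intensity sum over the whole-cell sum.
    """
    fields = [ndi.distance_transform_edt(~m.voxels, sampling=m.voxel_size) for m in droplet_masks]
    stack = np.stack(fields)
    nearest = np.argmin(stack, axis=0)
    total = volume[cell_mask.voxels].sum()
    if total == 0:
        raise DegenerateRatioError("zero whole-cell intensity")
    out = []
    for i, f in enumerate(fields):
        shell = cell_mask.voxels & (f <= width) & (nearest == i)
        out.append(float(volume[shell].sum() / total))
    return out


def synapse_asymmetry(enrichment_a: float, enrichment_b: float) -> float:
    """Absolute difference of per-synapse enrichments (order-independent)."""
    return float(abs(enrichment_a - enrichment_b))
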
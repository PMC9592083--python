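"""Nucleus invagination detection and orientation angles.

The B-cell nucleus is bean-shaped with one marked invagination.  The
nucleus mask is turned into a triangulated surface, per-vertex mean
curvature is computed with the cotangent Laplace-Beltrami operator, and
the invagination is the surface point of minimal mean curvature (the most
concave point), tracked frame-to-frame by nearest-neighbor when several
candidate minima exist (multi-lobed nuclei).

Orientation is quantified as theta_N, the angle at the cell center
between the rays to the invagination apex and to the droplet center;
the same operation with the centrosome position in place of the apex
yields theta_centrosome.  Sign convention for curvature: a convex sphere
is positive everywhere (H = 1/R), concave dents are negative.
"""

from __future__ import annotations

import warnings

import numpy as np
import trimesh
from scipy import ndimage as ndi
from scipy.stats import spearmanr
from skimage.measure import marching_cubes

from .core import KineticTrace, Mask3D
from .errors import AmbiguousShapeError, GeometryError, InvalidParameterError

__all__ = [
    "extract_surface",
    "mean_curvature",
    "detect_invagination",
    "orientation_angle",
    "angle_correlation",
]


def extract_surface(nucleus_mask: Mask3D, smoothing_iters: int = 10) -> trimesh.Trimesh:
    """Triangulated, smoothed isosurface of a nucleus mask.

    The binary indicator is blurred (sigma 1 voxel) so the 0.5 level set
    interpolates the voxel boundary sub-voxel-accurately, then marching
    cubes with physical voxel spacing, then Taubin smoothing (volume-
    preserving, so curvature is not biased by shrinkage).  The mask must
    be a single connected component.
    """
    vox = nucleus_mask.voxels
    if not vox.any():
        raise GeometryError("empty nucleus mask")
    _, n = ndi.label(vox)
    if n != 1:
        raise GeometryError(f"nucleus mask has {n} connected components, need exactly 1")
    padded = ndi.gaussian_filter(np.pad(vox, 1).astype(float), sigma=1.0)
    verts, faces, _, _ = marching_cubes(padded, 0.5, spacing=nucleus_mask.voxel_size)
    verts -= np.asarray(nucleus_mask.voxel_size)  # undo padding offset
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=True)
    if mesh.volume < 0:
        mesh.invert()
    if smoothing_iters > 0:
        trimesh.smoothing.filter_taubin(mesh, lamb=0.5, nu=0.53, iterations=smoothing_iters)
    if not mesh.is_watertight:
        warnings.warn("extracted nucleus surface is not watertight")
    return mesh


def mean_curvature(mesh: trimesh.Trimesh, field_smoothing: int = 15) -> np.ndarray:
    """Per-vertex mean curvature (1/um) via the cotangent Laplacian.

    ``H_i n_i = (1 / 4 A_i) * sum_j (cot a_ij + cot b_ij)(x_i - x_j)``
    with Meyer mixed (Voronoi) vertex areas ``A_i``, projected on the
    outward vertex normal so a convex sphere is positive (H = 1/R).
    Marching-cubes meshes have irregular triangles that make the raw
    pointwise estimate noisy, so the scalar field is regularized by
    ``field_smoothing`` passes of area-weighted neighbor averaging —
    enough to localize landmarks without flattening a dent's signature.
    """
    v = np.asarray(mesh.vertices, float)
    f = np.asarray(mesh.faces, int)
    areas = mesh.area_faces
    if np.any(areas <= 1e-14):
        bad = np.nonzero(areas <= 1e-14)[0]
        raise GeometryError(f"degenerate faces at indices {bad[:10].tolist()}")

    n_v = len(v)
    lap = np.zeros((n_v, 3))
    voronoi_area = np.zeros(n_v)

    # cotangent weights and Voronoi area, accumulated per face corner
    for a, b, c in ((0, 1, 2), (1, 2, 0), (2, 0, 1)):
        i, j, k = f[:, a], f[:, b], f[:, c]
        u1 = v[i] - v[k]
        u2 = v[j] - v[k]
        cross = np.cross(u1, u2)
        cot = (u1 * u2).sum(axis=1) / np.linalg.norm(cross, axis=1)
        # edge (i, j) gets cot of the angle at k
        np.add.at(lap, i, (0.5 * cot)[:, None] * (v[i] - v[j]))
        np.add.at(lap, j, (0.5 * cot)[:, None] * (v[j] - v[i]))
        edge2 = ((v[i] - v[j]) ** 2).sum(axis=1)
        np.add.at(voronoi_area, i, 0.125 * cot * edge2)
        np.add.at(voronoi_area, j, 0.125 * cot * edge2)

    # obtuse triangles can make Voronoi areas non-positive; fall back to
    # barycentric thirds there
    bary = np.zeros(n_v)
    for a in range(3):
        np.add.at(bary, f[:, a], areas / 3.0)
    vertex_area = np.where(voronoi_area > 1e-12, voronoi_area, bary)

    normals = np.asarray(mesh.vertex_normals, float)
    h = 0.5 / vertex_area * (lap * normals).sum(axis=1)
    if not np.isfinite(h).all():
        raise GeometryError("non-finite curvature (degenerate mesh region)")

    if field_smoothing > 0:
        import scipy.sparse as sp

        e = mesh.edges_unique
        w = sp.coo_matrix(
            (np.ones(2 * len(e)), (np.r_[e[:, 0], e[:, 1]], np.r_[e[:, 1], e[:, 0]])),
            shape=(n_v, n_v),
        ).tocsr()
        denom = w @ vertex_area
        for _ in range(field_smoothing):
            h = (w @ (h * vertex_area)) / denom
    return h


def detect_invagination(
    mesh: trimesh.Trimesh,
    curvature: np.ndarray | None = None,
    previous_point=None,
    candidate_band: float = 0.10,
    flatness_band: float = 0.05,
) -> np.ndarray:
    """Position (um) of the invagination: the minimal-mean-curvature vertex.

    When several local curvature minima lie within ``candidate_band``
    (fraction of the global minimum) and a ``previous_point`` is given,
    the candidate nearest to the previous frame's apex is chosen —
    the nearest-neighbor tracking correction for multi-lobed nuclei.
    Without a previous point the global minimum wins (ties: lowest vertex
    index, with a warning).  A surface whose curvature range is below
    ``flatness_band`` of its mean magnitude has no defined invagination.
    """
    h = mean_curvature(mesh) if curvature is None else np.asarray(curvature, float)
    rng = h.max() - h.min()
    mean_mag = np.abs(h).mean()
    if mean_mag == 0 or rng < flatness_band * mean_mag:
        raise AmbiguousShapeError("curvature nearly constant; no invagination")

    h_min = h.min()
    band_hi = h_min + candidate_band * abs(h_min)

    # vertex-local minima within the candidate band
    neigh = mesh.vertex_neighbors
    candidates = [
        i
        for i in np.nonzero(h <= band_hi)[0]
        if all(h[i] <= h[j] for j in neigh[i])
    ]
    if not candidates:
        candidates = [int(np.argmin(h))]
    verts = np.asarray(mesh.vertices)
    if previous_point is not None and len(candidates) > 1:
        prev = np.asarray(previous_point, float)
        d = np.linalg.norm(verts[candidates] - prev, axis=1)
        return verts[candidates[int(np.argmin(d))]].copy()
    global_min = [i for i in candidates if h[i] == h_min]
    if len(global_min) > 1:
        warnings.warn("multiple exact curvature minima; returning lowest vertex index")
    pick = global_min[0] if global_min else candidates[int(np.argmin(h[candidates]))]
    return verts[pick].copy()


def orientation_angle(apex, vertex_point, target) -> float:
    """Planar angle (deg) at ``vertex_point`` between rays to apex and target.

    With apex = invagination position, vertex = cell center, target =
    droplet center this is theta_N; substituting the centrosome position
    for the apex gives theta_centrosome.  Always in [0, 180].
    """
    u = np.asarray(apex, float) - np.asarray(vertex_point, float)
    w = np.asarray(target, float) - np.asarray(vertex_point, float)
    nu, nw = np.linalg.norm(u), np.linalg.norm(w)
    if nu == 0 or nw == 0:
        raise InvalidParameterError("coincident points do not define an angle")
    c = np.clip(np.dot(u, w) / (nu * nw), -1.0, 1.0)
    return float(np.degrees(np.arccos(c)))


def angle_correlation(theta_n_series, theta_c_series, t_max: float = 15 * 60.0) -> float:
    """Spearman rank correlation of paired theta_N / theta_centrosome series.

    Traces are restricted to the first ``t_max`` seconds (15 min default,
    the window over which the two organelles co-orient).  Plain arrays
    are correlated as given.
    """
    if isinstance(theta_n_series, KineticTrace):
        sel = theta_n_series.times <= t_max
        a = theta_n_series.values[sel]
        b = theta_c_series.values[sel] if isinstance(theta_c_series, KineticTrace) else np.asarray(theta_c_series)[sel]
    else:
        a = np.asarray(theta_n_series, float)
        b = np.asarray(theta_c_series, float)
    if a.shape != b.shape or a.size < 3:
        raise InvalidParameterError("need paired series of length >= 3")
    if np.all(a == a[0]) or np.all(b == b[0]):
        raise InvalidParameterError("correlation undefined for a constant series")
    rho, _ = spearmanr(a, b)
    return float(rho)
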
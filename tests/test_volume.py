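"""Image preparation and segmentation: oracles and phantom recovery."""

import numpy as np
import pytest

from synapsekin.core import Mask3D
from synapsekin.errors import (
    DegenerateFrameError,
    DetectionError,
    InvalidParameterError,
    SegmentationError,
)
from synapsekin.volume import (
    bleach_correct,
    detect_punctum,
    distance_map,
    huang_threshold,
    organelle_distance,
    resample_isotropic,
    segment_cell,
    segment_droplet,
    to_isotropic,
)
from conftest import make_series


def _jaccard(a, b):
    return (a & b).sum() / (a | b).sum()


class TestBleachCorrect:
    def test_constant_series_unchanged(self):
        data = np.full((3, 1, 4, 8, 8), 7.0)
        s = make_series(data)
        for method in ("simple_ratio", "histogram_matching"):
            out = bleach_correct(s, "ch0", method)
            np.testing.assert_allclose(out.data, data)

    def test_simple_ratio_restores_frame_means(self):
        rng = np.random.default_rng(0)
        data = rng.uniform(1, 10, (3, 1, 4, 8, 8))
        for t, scale in enumerate((1.0, 0.5, 0.25)):
            data[t] *= scale * 100 / data[t].mean()
        s = make_series(data)
        out = bleach_correct(s, "ch0", "simple_ratio")
        means = out.data[:, 0].mean(axis=(1, 2, 3))
        np.testing.assert_allclose(means, means[0])

    def test_histogram_matching_quantile_oracle(self):
        """Sorted intensities of a matched frame equal frame 0's sorted values."""
        rng = np.random.default_rng(1)
        ref = rng.uniform(0, 100, (2, 10, 10))
        bleached = 0.4 * rng.uniform(0, 100, (2, 10, 10))
        s = make_series(np.stack([ref, bleached])[:, None])
        out = bleach_correct(s, "ch0", "histogram_matching")
        np.testing.assert_allclose(np.sort(out.data[1, 0].ravel()),
                                   np.sort(ref.ravel()), rtol=1e-6)

    def test_zero_mean_frame_rejected(self):
        data = np.ones((2, 1, 2, 4, 4))
        data[1] = 0.0
        with pytest.raises(DegenerateFrameError):
            bleach_correct(make_series(data), "ch0", "simple_ratio")


class TestIsotropic:
    def test_identity_at_native_spacing(self):
        rng = np.random.default_rng(2)
        data = rng.uniform(0, 1, (1, 1, 6, 6, 6))
        s = make_series(data, voxel_size=(0.5, 0.5, 0.5))
        out = to_isotropic(s, 0.5)
        np.testing.assert_allclose(out.data, data)

    def test_linear_ramp_interpolates_exactly(self):
        z = np.arange(21, dtype=float)
        vol = np.broadcast_to(z[:, None, None], (21, 4, 4)).copy()
        out = resample_isotropic(vol, (0.7, 0.35, 0.35), 0.35)
        expected_z = np.arange(out.shape[0]) * 0.35 / 0.7
        np.testing.assert_allclose(out[:, 0, 0], expected_z, atol=1e-9)

    def test_extent_preserving_plane_count(self):
        vol = np.zeros((21, 4, 4))
        out = resample_isotropic(vol, (0.7, 0.35, 0.35), 0.35)
        assert out.shape == (41, 4, 4)  # z doubled, y/x already at target

    def test_idempotent_at_same_spacing(self):
        rng = np.random.default_rng(3)
        s = make_series(rng.uniform(0, 1, (1, 1, 8, 10, 10)), voxel_size=(0.7, 0.35, 0.35))
        once = to_isotropic(s, 0.35)
        twice = to_isotropic(once, 0.35)
        np.testing.assert_allclose(twice.data, once.data, atol=1e-12)


def _huang_brute_force(image, nbins=256):
    """Direct fuzzy-entropy scan from the definition, used as an oracle."""
    data = np.asarray(image, float).ravel()
    lo, hi = data.min(), data.max()
    hist, edges = np.histogram(data, nbins, (lo, hi))
    centers = 0.5 * (edges[:-1] + edges[1:])
    c = hi - lo
    scores = []
    for t in range(nbins - 1):
        fg = hist[t + 1:]
        bg = hist[: t + 1]
        if bg.sum() == 0 or fg.sum() == 0:
            continue
        mu0 = (bg * centers[: t + 1]).sum() / bg.sum()
        mu1 = (fg * centers[t + 1:]).sum() / fg.sum()
        s = 0.0
        for g, n in zip(centers, hist):
            if n == 0:
                continue
            mu = 1.0 / (1.0 + abs(g - (mu0 if g <= centers[t] else mu1)) / c)
            if 1e-12 < mu < 1 - 1e-12:
                s += n * (-mu * np.log(mu) - (1 - mu) * np.log(1 - mu))
        scores.append((s, t))
    best_s = min(s for s, _ in scores)
    best_t = min(t for s, t in scores if s <= best_s + 1e-9 * (1.0 + abs(best_s)))
    return edges[best_t + 1]


class TestHuangThreshold:
    def test_matches_brute_force_on_bimodal_image(self):
        rng = np.random.default_rng(4)
        img = np.concatenate([rng.normal(30, 8, 4000), rng.normal(180, 15, 2000)])
        img = np.clip(img, 0, 255).reshape(60, 100)
        assert huang_threshold(img) == pytest.approx(_huang_brute_force(img))

    def test_scale_invariance(self):
        rng = np.random.default_rng(5)
        img = np.concatenate([rng.normal(20, 5, 3000), rng.normal(120, 10, 1500)])
        t1 = huang_threshold(img)
        t2 = huang_threshold(img * 3.5)
        assert t2 == pytest.approx(3.5 * t1, rel=1e-6)

    def test_constant_image_rejected(self):
        with pytest.raises(SegmentationError):
            huang_threshold(np.ones((5, 5)))


class TestSegmentDroplet:
    def test_jaccard_vs_ground_truth(self, doublet):
        _, series, truth = doublet
        mask = segment_droplet(series)
        assert _jaccard(mask.voxels, truth.droplet_mask.voxels) >= 0.9

    def test_two_droplets_returned_separately(self):
        shape = (16, 40, 40)
        vs = (0.5, 0.5, 0.5)
        zz, yy, xx = np.meshgrid(*[np.arange(n) * 0.5 for n in shape], indexing="ij")
        d1 = (zz - 4) ** 2 + (yy - 5) ** 2 + (xx - 5) ** 2 <= 9
        d2 = (zz - 4) ** 2 + (yy - 14) ** 2 + (xx - 14) ** 2 <= 9
        img = 100.0 * (d1 | d2)
        s = make_series(img[None, None], voxel_size=vs, names=("antigen",))
        masks = segment_droplet(s, multi_droplet=True)
        assert len(masks) == 2

    def test_flat_channel_fails(self):
        s = make_series(np.zeros((1, 1, 4, 8, 8)), names=("antigen",))
        with pytest.raises(SegmentationError):
            segment_droplet(s)


class TestSegmentCell:
    def test_recovers_phantom_cell(self, doublet):
        """Huang sits just above background, so the mask is a slightly
        dilated superset of the true cell: near-total recall, bounded
        Jaccard."""
        _, series, truth = doublet
        mask = segment_cell(series)[0]
        true = truth.cell_mask.voxels
        recall = (mask.voxels & true).sum() / true.sum()
        assert recall >= 0.95
        assert _jaccard(mask.voxels, true) >= 0.6

    def test_intensity_scale_invariance(self, doublet):
        _, series, _ = doublet
        scaled = make_series(series.data * 7.3, series.voxel_size,
                             names=series.channel_names)
        m1 = segment_cell(series)[0]
        m2 = segment_cell(scaled)[0]
        assert _jaccard(m1.voxels, m2.voxels) > 0.99

    def test_empty_field_input_fails(self):
        s = make_series(np.zeros((1, 1, 4, 8, 8)), names=("cytoplasm",))
        with pytest.raises(SegmentationError):
            segment_cell(s)


class TestDetectPunctum:
    def test_single_spot_within_one_voxel(self, doublet):
        params, series, truth = doublet
        pos = detect_punctum(series, "centrosome", 1)
        assert np.all(np.abs(pos - truth.centrosome_position[1])
                      <= np.asarray(params.voxel_size))

    def test_brighter_of_two_spots_wins(self):
        vol = np.zeros((1, 1, 9, 15, 15))
        vol[0, 0, 4, 3, 3] = 100.0
        vol[0, 0, 4, 11, 11] = 200.0
        s = make_series(vol, names=("spot",))
        pos = detect_punctum(s, "spot", 0)
        np.testing.assert_allclose(pos, [4.0, 11.0, 11.0])

    def test_flat_channel_fails(self):
        s = make_series(np.ones((1, 1, 4, 8, 8)), names=("spot",))
        with pytest.raises(DetectionError):
            detect_punctum(s, "spot", 0)


class TestDistanceMap:
    def test_adjacent_voxel_distance_is_spacing(self):
        vox = np.zeros((5, 5, 5), bool)
        vox[2, 2, 2] = True
        field = distance_map(Mask3D(vox, (0.4, 0.4, 0.4)))
        assert field.values[2, 2, 3] == pytest.approx(0.4)
        assert field.values[2, 2, 2] == 0.0

    def test_matches_exhaustive_search_on_11cube(self):
        rng = np.random.default_rng(6)
        vox = rng.uniform(size=(11, 11, 11)) < 0.08
        vox[5, 5, 5] = True
        vs = (0.7, 0.35, 0.35)
        field = distance_map(Mask3D(vox, vs))
        src = np.argwhere(vox) * np.asarray(vs)
        for idx in np.argwhere(~vox):
            d = np.linalg.norm(src - idx * np.asarray(vs), axis=1).min()
            assert field.values[tuple(idx)] == pytest.approx(d, abs=1e-9)

    def test_lipschitz_between_neighbors(self):
        vox = np.zeros((9, 9, 9), bool)
        vox[4, 4, 4] = True
        vs = (0.5, 0.5, 0.5)
        field = distance_map(Mask3D(vox, vs))
        v = field.values
        for axis in range(3):
            diffs = np.abs(np.diff(v, axis=axis))
            assert diffs.max() <= vs[axis] + 1e-9

    def test_empty_mask_rejected(self):
        with pytest.raises(InvalidParameterError):
            distance_map(Mask3D(np.zeros((3, 3, 3), bool), (1, 1, 1)))


class TestOrganelleDistance:
    def test_contact_gives_zero(self):
        vox = np.zeros((7, 7, 7), bool)
        vox[3, 3, 3] = True
        field = distance_map(Mask3D(vox, (0.5, 0.5, 0.5)))
        organ = np.zeros((7, 7, 7), bool)
        organ[3, 3, 3] = True
        assert organelle_distance(Mask3D(organ, (0.5, 0.5, 0.5)), field, "min") == 0.0

    def test_phantom_shell_mean_distance(self, doublet_iso):
        """Organelle puncta programmed at a known shell distance recover it."""
        params, series, truth = doublet_iso
        field = distance_map(truth.droplet_mask)
        for t in range(params.n_frames):
            measured = organelle_distance(truth.organelle_positions[t], field, "point")
            assert measured == pytest.approx(truth.organelle_mean_distance[t],
                                             abs=max(params.voxel_size))

    def test_point_evaluation_at_voxel_center(self):
        vox = np.zeros((7, 7, 7), bool)
        vox[3, 3, 3] = True
        field = distance_map(Mask3D(vox, (0.5, 0.5, 0.5)))
        assert organelle_distance((1.5, 1.5, 0.5), field, "point") == \
            pytest.approx(field.values[3, 3, 1])
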
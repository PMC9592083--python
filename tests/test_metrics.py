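"""Synapse-referenced intensity metrics: oracles and symmetry properties."""

import numpy as np
import pytest

from synapsekin.core import Mask3D
from synapsekin.errors import DegenerateRatioError, InvalidParameterError
from synapsekin.metrics import (
    SHELL_PRESETS,
    ShellSpec,
    actin_maxima,
    antigen_recruitment,
    count_synapses,
    front_back_ratio,
    intensity_ratio_whole_cell,
    per_synapse_shell_enrichment,
    shell_enrichment,
    synapse_asymmetry,
)
from synapsekin.volume import distance_map
from conftest import make_series


def _sphere(shape, vs, center, radius):
    zz, yy, xx = np.meshgrid(*[np.arange(n) * v for n, v in zip(shape, vs)], indexing="ij")
    return (zz - center[0]) ** 2 + (yy - center[1]) ** 2 + (xx - center[2]) ** 2 <= radius ** 2


class TestAntigenRecruitment:
    def _two_cap_series(self, cap_factors):
        """Droplet whose synapse cap is scaled by a per-frame factor."""
        shape, vs = (17, 30, 30), (0.5, 0.5, 0.5)
        center = np.array([4.0, 7.25, 7.25])
        drop = _sphere(shape, vs, center, 3.0)
        cell_center = center + np.array([0.0, 0.0, 6.0])
        zz, yy, xx = np.meshgrid(*[np.arange(n) * v for n, v in zip(shape, vs)], indexing="ij")
        rel = np.stack([zz - center[0], yy - center[1], xx - center[2]])
        r = np.sqrt((rel ** 2).sum(0))
        with np.errstate(invalid="ignore"):
            cosang = rel[2] / np.where(r > 0, r, np.inf)
        cap = cosang >= np.cos(np.deg2rad(60))
        frames = []
        for f in cap_factors:
            img = 100.0 * drop * np.where(cap, f, 1.0)
            frames.append(img[None])
        s = make_series(np.stack(frames), voxel_size=vs, names=("antigen",))
        return s, Mask3D(drop, vs, "droplet"), cell_center

    def test_uniform_droplet_scores_one(self, doublet):
        """A spatially uniform, time-constant droplet sits at the reference
        line: recruitment exactly 1 at every frame."""
        params = type(doublet[0])(n_frames=4, antigen_accumulation=np.ones(4), seed=1)
        from synapsekin.phantom import generate_doublet

        series, truth = generate_doublet(params)
        tr = antigen_recruitment(series, truth.droplet_mask, truth.cell_mask.centroid_um())
        np.testing.assert_allclose(tr.values, 1.0, atol=1e-9)

    def test_two_cap_phantom_ratio(self):
        s, drop, cc = self._two_cap_series([1.0, 2.0])
        tr = antigen_recruitment(s, drop, cc)
        assert tr.values[0] == pytest.approx(1.0)
        assert tr.values[1] == pytest.approx(2.0, rel=1e-6)

    def test_t0_normalization_arithmetic(self):
        s, drop, cc = self._two_cap_series([2.0, 4.0])
        tr = antigen_recruitment(s, drop, cc)
        assert tr.values[1] == pytest.approx(2.0, rel=1e-6)

    def test_recovers_programmed_accumulation(self, doublet):
        """On a noise-free phantom the trace follows the programmed
        synapse/opposite ratio within 5%."""
        params, series, truth = doublet
        tr = antigen_recruitment(series, truth.droplet_mask, truth.cell_mask.centroid_um())
        programmed = truth.antigen_ratio / truth.antigen_ratio[0]
        np.testing.assert_allclose(tr.values, programmed, rtol=0.05)


class TestShellEnrichment:
    def _toy(self, width=2.0, normalization="cell_total"):
        shape, vs = (15, 15, 15), (1.0, 1.0, 1.0)
        drop = np.zeros(shape, bool)
        drop[7, 7, 2] = True
        cell = _sphere(shape, vs, (7, 7, 9), 5.0)
        field = distance_map(Mask3D(drop, vs))
        img = np.ones(shape)
        s = make_series(np.broadcast_to(img, (2, 1) + shape).copy(), voxel_size=vs,
                        names=("reporter",))
        spec = ShellSpec(width=width, normalization=normalization)
        return s, cell, field, spec

    def test_uniform_intensity_equals_voxel_count_ratio(self):
        s, cell, field, spec = self._toy(width=4.0)
        tr = shell_enrichment(s, "reporter", Mask3D(cell, (1, 1, 1)), field, spec)
        shell_count = (cell & (field.values <= 4.0)).sum()
        assert tr.values[0] == pytest.approx(shell_count / cell.sum())

    def test_full_containment_gives_one(self):
        s, cell, field, spec = self._toy(width=100.0)
        tr = shell_enrichment(s, "reporter", Mask3D(cell, (1, 1, 1)), field, spec)
        assert tr.values[0] == pytest.approx(1.0)

    def test_t0_normalized_trace_starts_at_one(self, doublet):
        _, series, truth = doublet
        field = distance_map(truth.droplet_mask)
        tr = shell_enrichment(series, "cytoplasm", truth.cell_mask, field,
                              SHELL_PRESETS["actin2um"])
        assert tr.values[0] == pytest.approx(1.0)

    def test_monotone_in_width(self):
        widths = [1.0, 2.0, 4.0, 8.0]
        vals = []
        for w in widths:
            s, cell, field, spec = self._toy(width=w)
            tr = shell_enrichment(s, "reporter", Mask3D(cell, (1, 1, 1)), field, spec)
            vals.append(tr.values[0])
        assert all(a <= b + 1e-12 for a, b in zip(vals, vals[1:]))

    def test_scale_invariance_when_normalized(self):
        s, cell, field, spec = self._toy(width=3.0)
        tr1 = shell_enrichment(s, "reporter", Mask3D(cell, (1, 1, 1)), field, spec)
        s2 = make_series(s.data * 9.1, s.voxel_size, names=s.channel_names)
        tr2 = shell_enrichment(s2, "reporter", Mask3D(cell, (1, 1, 1)), field, spec)
        np.testing.assert_allclose(tr1.values, tr2.values)


class TestFrontBackRatio:
    def _grid(self):
        vox = np.ones((4, 6, 8), bool)
        vol = np.ones((4, 6, 8))
        vol[:, :, 4:] = 3.0  # front half (larger x) three times brighter
        return vol, Mask3D(vox, (1.0, 1.0, 1.0))

    def test_uniform_symmetric_cell_is_one(self):
        vol = np.ones((4, 6, 8))
        mask = Mask3D(np.ones((4, 6, 8), bool), (1, 1, 1))
        assert front_back_ratio(vol, mask, (0, 0, 1)) == pytest.approx(1.0)

    def test_hand_built_half_labeled_grid(self):
        vol, mask = self._grid()
        assert front_back_ratio(vol, mask, (0, 0, 1)) == pytest.approx(3.0)

    def test_axis_flip_gives_reciprocal(self):
        vol, mask = self._grid()
        fwd = front_back_ratio(vol, mask, (0, 0, 1))
        rev = front_back_ratio(vol, mask, (0, 0, -1))
        assert rev == pytest.approx(1.0 / fwd)


class TestActinMaxima:
    def _spot(self, img, y, x, amp=100.0, sigma=2.0):
        yy, xx = np.meshgrid(np.arange(img.shape[0]), np.arange(img.shape[1]),
                             indexing="ij")
        img += amp * np.exp(-((yy - y) ** 2 + (xx - x) ** 2) / (2 * sigma ** 2))

    def test_single_spot_at_droplet_boundary(self):
        img = np.zeros((40, 40))
        drop = np.zeros((40, 40), bool)
        drop[15:25, 2:12] = True
        self._spot(img, 20, 12)
        count, dist = actin_maxima(img, np.ones((40, 40), bool), drop, 0.5,
                                   prominence=10.0)
        assert count == 1
        assert dist == pytest.approx(0.0, abs=0.5)

    def test_mean_distance_of_programmed_spots(self):
        px = 1.0
        img = np.zeros((30, 60))
        drop = np.zeros((30, 60), bool)
        drop[:, :4] = True
        for x in (4, 8, 12):  # distances 0, 4, 8 um from the droplet edge
            self._spot(img, 15, x, sigma=1.0)
        count, dist = actin_maxima(img, np.ones_like(drop), drop, px, prominence=10.0)
        assert count == 3
        assert dist == pytest.approx(4.0, abs=1.0)

    def test_flat_image_reports_no_maxima(self):
        count, dist = actin_maxima(np.zeros((20, 20)), np.ones((20, 20), bool),
                                   np.zeros((20, 20), bool), 1.0, prominence=5.0)
        assert count == 0 and dist is None

    def test_empty_cell_mask_rejected(self):
        with pytest.raises(InvalidParameterError):
            actin_maxima(np.zeros((10, 10)), np.zeros((10, 10), bool),
                         np.zeros((10, 10), bool), 1.0)


class TestWholeCellRatio:
    def test_identity_and_linearity(self):
        mask = Mask3D(np.ones((3, 4, 4), bool), (1, 1, 1))
        a = np.random.default_rng(7).uniform(1, 5, (3, 4, 4))
        assert intensity_ratio_whole_cell(a, a, mask) == pytest.approx(1.0)
        assert intensity_ratio_whole_cell(2 * a, a, mask) == pytest.approx(2.0)

    def test_hand_sums(self):
        mask = Mask3D(np.ones((1, 2, 5), bool), (1, 1, 1))
        a = np.full((1, 2, 5), 50.0)   # sums 500
        b = np.full((1, 2, 5), 20.0)   # sums 200
        assert intensity_ratio_whole_cell(a, b, mask) == pytest.approx(2.5)

    def test_zero_denominator_rejected(self):
        mask = Mask3D(np.ones((1, 2, 2), bool), (1, 1, 1))
        with pytest.raises(DegenerateRatioError):
            intensity_ratio_whole_cell(np.ones((1, 2, 2)), np.zeros((1, 2, 2)), mask)


class TestCountSynapses:
    VS = (0.5, 0.5, 0.5)

    def _scene(self, drop_centers, cell_center=(5.0, 7.0, 7.0), cell_r=4.0):
        shape = (21, 28, 28)
        cell = _sphere(shape, self.VS, cell_center, cell_r)
        drops = [Mask3D(_sphere(shape, self.VS, c, 2.0), self.VS, "droplet")
                 for c in drop_centers]
        for d in drops:
            cell &= ~d.voxels
        return Mask3D(cell, self.VS, "cell"), drops

    def test_opposite_poles_count_two(self):
        cell, drops = self._scene([(5.0, 7.0, 1.5), (5.0, 7.0, 12.5)])
        assert count_synapses(cell, drops) == 2

    def test_adjacent_droplets_single_contact(self):
        cell, drops = self._scene([(5.0, 5.0, 1.8), (5.0, 9.0, 1.8)])
        assert count_synapses(cell, drops) == 1

    def test_one_droplet_out_of_contact(self):
        cell, drops = self._scene([(5.0, 7.0, 1.5), (5.0, 7.0, 13.0)],
                                  cell_r=3.0, cell_center=(5.0, 7.0, 6.0))
        assert count_synapses(cell, drops) == 1

    def test_no_contact_warns_and_returns_zero(self):
        cell, drops = self._scene([(5.0, 7.0, 1.0)], cell_center=(15.0, 7.0, 12.0),
                                  cell_r=2.0)
        with pytest.warns(UserWarning):
            assert count_synapses(cell, drops) == 0


class TestAsymmetry:
    def test_values_and_symmetry(self):
        assert synapse_asymmetry(2.0, 1.0) == 1.0
        assert synapse_asymmetry(1.0, 2.0) == 1.0
        assert synapse_asymmetry(1.5, 1.5) == 0.0

    def test_per_synapse_voronoi_split(self):
        shape, vs = (11, 11, 21), (1.0, 1.0, 1.0)
        d1 = np.zeros(shape, bool); d1[5, 5, 2] = True
        d2 = np.zeros(shape, bool); d2[5, 5, 18] = True
        cell = np.ones(shape, bool)
        vol = np.ones(shape)
        vol[:, :, :10] = 3.0  # synapse 1 side brighter
        e = per_synapse_shell_enrichment(
            vol, Mask3D(cell, vs), [Mask3D(d1, vs), Mask3D(d2, vs)], width=2.0)
        assert len(e) == 2
        assert e[0] > e[1]
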
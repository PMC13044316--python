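"""Generator geometry, rendering physics, and the analytic contact oracle."""

import dataclasses

import numpy as np
import pytest
from skimage.filters import threshold_otsu

import lysoclust as lc
from conftest import toy_truth
from lysoclust.synthgen import _chain_partition


class TestContactOracle:
    @pytest.mark.parametrize("disks,expected", [
        # tangent disks: distance equals radius sum -> in contact
        ([(10, 10, 2), (10, 14, 2)], 1.0),
        # 1 px of clearance -> no contact at tol 0
        ([(10, 10, 2), (10, 15, 2)], 0.0),
        # pair in contact plus one distant disk -> 2/3
        ([(10, 10, 2), (10, 14, 2), (30, 30, 2)], 2 / 3),
    ])
    def test_hand_geometries(self, disks, expected):
        truth = toy_truth(disks)
        table = lc.truth_contact_fraction(truth, tol_px=0.0)
        assert table["index"].iloc[0] == pytest.approx(expected)

    def test_single_vesicle_undefined(self):
        table = lc.truth_contact_fraction(toy_truth([(10, 10, 3)]))
        assert np.isnan(table["index"].iloc[0])

    def test_relabeling_invariance(self):
        disks = [(10, 10, 3), (10, 17, 3), (40, 40, 4), (22, 30, 3)]
        base = lc.truth_contact_fraction(toy_truth(disks))
        perm = lc.truth_contact_fraction(toy_truth(disks[::-1]))
        assert base["index"].iloc[0] == perm["index"].iloc[0]

    def test_negative_tolerance_rejected(self):
        with pytest.raises(ValueError):
            lc.truth_contact_fraction(toy_truth([(5, 5, 2)]), tol_px=-1)


class TestSceneConstruction:
    def test_no_chains_means_zero_index(self):
        spec = lc.SceneSpec(image_shape=(160, 160), n_cells=1,
                            vesicles_per_cell=3, clustered_fraction=0.0,
                            min_isolated_gap=6.0, seed=1)
        truth = lc.make_scene(spec)
        assert len(truth.vesicles) == 3
        assert all(v.chain_id is None for v in truth.vesicles)
        assert lc.truth_contact_fraction(truth)["index"].iloc[0] == 0.0

    def test_single_full_chain_gives_index_one(self):
        spec = lc.SceneSpec(image_shape=(160, 160), n_cells=1,
                            vesicles_per_cell=3, clustered_fraction=1.0,
                            chain_size_rule=("fixed", 3), seed=1)
        truth = lc.make_scene(spec)
        assert lc.truth_contact_fraction(truth)["index"].iloc[0] == 1.0

    def test_chain_partition_realizes_requested_fraction(self):
        # 7 chains of 4 + 12 isolated out of 40 -> oracle index 28/40 = 0.7
        spec = lc.SceneSpec(image_shape=(512, 512), n_cells=1,
                            vesicles_per_cell=40, clustered_fraction=0.7,
                            chain_size_rule=("fixed", 4), seed=2)
        truth = lc.make_scene(spec)
        assert sum(v.chain_id is not None for v in truth.vesicles) == 28
        assert lc.truth_contact_fraction(truth)["index"].iloc[0] == \
            pytest.approx(28 / 40)

    @pytest.mark.parametrize("frac", [0.0, 0.4, 0.7, 1.0])
    def test_construction_soundness_any_fraction(self, frac):
        # oracle index == (#chain members)/(#vesicles) exactly, because
        # isolated vesicles keep a gap larger than the contact tolerance
        spec = lc.preset_spec("clustered" if frac > 0.5 else "dispersed",
                              n_cells=2, seed=9, contact_fraction=frac)
        truth = lc.make_scene(spec)
        table = lc.truth_contact_fraction(truth)
        for cell in truth.cells:
            members = [v for v in truth.vesicles if v.cell_id == cell.cell_id]
            n_chain = sum(v.chain_id is not None for v in members)
            row = table[table["cell"] == cell.cell_id].iloc[0]
            assert row["n_contacting"] == n_chain
            assert row["index"] == pytest.approx(n_chain / len(members))

    def test_isolated_vesicles_respect_gap(self):
        spec = lc.preset_spec("dispersed", n_cells=2, seed=4)
        truth = lc.make_scene(spec)
        vs = truth.vesicles
        for i, a in enumerate(vs):
            for b in vs[i + 1:]:
                if a.chain_id is not None and a.chain_id == b.chain_id:
                    continue
                d = np.hypot(a.center[0] - b.center[0],
                             a.center[1] - b.center[1])
                assert d >= a.radius + b.radius + spec.min_isolated_gap - 1e-9

    def test_determinism_bit_identical(self):
        spec = lc.preset_spec("clustered", n_cells=2, seed=12)
        t1, t2 = lc.make_scene(spec), lc.make_scene(spec)
        assert t1.vesicles == t2.vesicles
        np.testing.assert_array_equal(t1.vesicle_mask, t2.vesicle_mask)
        np.testing.assert_array_equal(lc.render_scene(t1), lc.render_scene(t2))

    def test_infeasible_packing_raises(self):
        spec = lc.SceneSpec(image_shape=(48, 48), n_cells=1,
                            vesicles_per_cell=200, min_isolated_gap=8.0,
                            seed=0)
        with pytest.raises(lc.PlacementInfeasibleError):
            lc.make_scene(spec)

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            lc.SceneSpec(clustered_fraction=1.5).validate()
        with pytest.raises(ValueError):
            lc.SceneSpec(vesicle_radius_range=(1.0, 5.0)).validate()
        with pytest.raises(ValueError):
            lc.SceneSpec(psf_sigma=-1.0).validate()

    def test_chain_partition_never_leaves_singleton(self):
        rng = np.random.default_rng(0)
        for n in (5, 11, 40):
            for frac in (0.3, 0.5, 0.9):
                sizes = _chain_partition(rng, n, frac, ("uniform", 3, 5))
                assert all(s >= 2 for s in sizes)
                assert sum(sizes) == round(frac * n)


class TestRendering:
    def test_identity_rendering_without_psf(self):
        spec = lc.SceneSpec(image_shape=(64, 64), n_cells=1,
                            vesicles_per_cell=1,
                            vesicle_radius_range=(5.0, 5.0), psf_sigma=0.0,
                            noise=lc.NOISE_OFF, seed=3)
        truth = lc.make_scene(spec)
        img = lc.render_scene(truth)
        support = img[1] > lc.NOISE_OFF.background_level
        np.testing.assert_array_equal(support, truth.vesicle_mask > 0)

    def test_empty_scene_is_flat_background(self):
        truth = toy_truth([])
        quiet = dataclasses.replace(truth.spec, noise=lc.NOISE_OFF)
        img = lc.render_scene(truth, quiet)
        np.testing.assert_allclose(img[1], lc.NOISE_OFF.background_level)

    def test_blurred_disk_area_survives_otsu(self):
        spec = lc.SceneSpec(image_shape=(96, 96), n_cells=1,
                            vesicles_per_cell=1,
                            vesicle_radius_range=(5.0, 5.0), psf_sigma=1.0,
                            noise=lc.NOISE_OFF, seed=3)
        truth = lc.make_scene(spec)
        img = lc.render_scene(truth)[1]
        area = np.count_nonzero(img > threshold_otsu(img))
        assert area == pytest.approx(np.pi * 25, rel=0.15)

    def test_blur_conserves_integral(self):
        spec = lc.preset_spec("dispersed", n_cells=1, seed=5,
                              noise=lc.NOISE_OFF)
        truth = lc.make_scene(spec)
        img = lc.render_scene(truth)[1]
        signal = img.sum() - lc.NOISE_OFF.background_level * img.size
        expected = truth.spec.peak_intensity * np.count_nonzero(
            truth.vesicle_mask > 0)
        # chain overlap is absent here, so mask area == summed disk area
        assert signal == pytest.approx(expected, rel=0.005)

    def test_noise_is_seed_deterministic(self):
        spec = lc.preset_spec("dispersed", n_cells=1, seed=6)
        truth = lc.make_scene(spec)
        np.testing.assert_array_equal(lc.render_scene(truth),
                                      lc.render_scene(truth))


class TestColocPair:
    def _base(self):
        spec = lc.preset_spec("dispersed", n_cells=1, seed=8,
                              noise=lc.NOISE_OFF)
        return lc.make_scene(spec)

    def test_alpha_one_identity(self):
        truth = self._base()
        ch1, ch2, _ = lc.make_coloc_pair(
            truth, lc.ColocSpec(alpha=1.0, noise=lc.NOISE_OFF, seed=42))
        np.testing.assert_array_equal(ch1, ch2)

    def test_alpha_zero_independent(self):
        truth = self._base()
        ch1, ch2, _ = lc.make_coloc_pair(
            truth, lc.ColocSpec(alpha=0.0, noise=lc.NOISE_OFF, seed=42))
        assert not np.array_equal(ch1, ch2)
        # channel 2 must not simply rescale channel 1's structure
        assert lc.pearson_r(ch1, ch2) < 0.9

    def test_pearson_monotone_in_alpha(self):
        truth = self._base()
        rs = [lc.pearson_r(*lc.make_coloc_pair(
            truth, lc.ColocSpec(alpha=a, noise=lc.NOISE_OFF, seed=42))[:2])
            for a in (0.0, 0.5, 1.0)]
        assert rs[0] < rs[1] < rs[2]
        assert rs[2] == pytest.approx(1.0)

    def test_invalid_alpha_rejected(self):
        with pytest.raises(ValueError):
            lc.ColocSpec(alpha=1.2).validate()
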
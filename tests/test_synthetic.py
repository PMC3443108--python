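"""Generator contracts: determinism, geometry arithmetic, bead planting
constraints, tiling consistency, cohort sampling and flow-table composition."""

import numpy as np
import pytest

from plaquebeads import (
    BEAD_CHANNEL,
    BeadSpec,
    CapacityError,
    CohortSpec,
    ConfigurationError,
    Effect,
    FlowComposition,
    GroupSpec,
    SceneConfig,
    generate_cohort,
    generate_flow_events,
    generate_scene,
    plant_beads,
    tile_scene,
)

from conftest import quiet_config


class TestSceneGeometry:
    def test_voxel_grid_is_ceil_of_extent_over_step(self):
        cfg = SceneConfig(width_um=100, height_um=100, depth_um=230,
                          pixel_size_um=0.25, z_step_um=10)
        assert cfg.grid_shape == (23, 400, 400)

    @pytest.mark.parametrize("bad", [
        dict(width_um=0), dict(depth_um=-5), dict(pixel_size_um=0),
        dict(z_step_um=0),
    ])
    def test_invalid_geometry_rejected(self, bad):
        with pytest.raises(ConfigurationError):
            SceneConfig(**bad)

    def test_zero_background_zero_noise_gives_zero_volumes(self):
        scene = generate_scene(quiet_config(30, 30, 20), seed=4)
        for vol in scene.volumes.values():
            assert np.all(vol == 0)

    def test_same_seed_reproduces_scene_bitwise(self):
        cfg = SceneConfig(width_um=30, height_um=30, depth_um=20)
        a = generate_scene(cfg, seed=12)
        b = generate_scene(cfg, seed=12)
        for ch in cfg.channels:
            np.testing.assert_array_equal(a.volumes[ch], b.volumes[ch])

    def test_volumes_nonnegative_and_consistent(self):
        cfg = SceneConfig(width_um=30, height_um=30, depth_um=20)
        scene = generate_scene(cfg, seed=2)
        shapes = {v.shape for v in scene.volumes.values()}
        assert shapes == {cfg.grid_shape}
        assert all((v >= 0).all() for v in scene.volumes.values())


class TestPlantBeads:
    def test_zero_beads_is_identity(self, quiet_scene, bead_spec):
        before = {ch: v.copy() for ch, v in quiet_scene.volumes.items()}
        plant_beads(quiet_scene, 0, bead_spec, seed=1)
        assert len(quiet_scene.truth) == 0
        for ch in before:
            np.testing.assert_array_equal(quiet_scene.volumes[ch], before[ch])

    def test_count_and_lateral_separation(self, quiet_scene, bead_spec):
        plant_beads(quiet_scene, 50, bead_spec, clump_fraction=0.0, seed=3)
        beads = quiet_scene.truth.beads
        assert len(beads) == 50
        # brute-force pairwise lateral distances
        for i in range(50):
            for j in range(i + 1, 50):
                d = np.hypot(beads[i, 0] - beads[j, 0],
                             beads[i, 1] - beads[j, 1])
                assert d >= 3.0 - 1e-9

    def test_beads_only_in_bead_channel(self, quiet_scene, bead_spec):
        plant_beads(quiet_scene, 10, bead_spec, clump_fraction=0.0, seed=5)
        for ch, vol in quiet_scene.volumes.items():
            assert (vol.max() > 0) == (ch == BEAD_CHANNEL)

    def test_centers_inside_scene(self, quiet_scene, bead_spec):
        plant_beads(quiet_scene, 40, bead_spec, clump_fraction=0.1, seed=6)
        cfg = quiet_scene.config
        beads = quiet_scene.truth.beads
        assert (beads[:, 0] >= 0).all() and (beads[:, 0] <= cfg.width_um).all()
        assert (beads[:, 1] >= 0).all() and (beads[:, 1] <= cfg.height_um).all()
        assert (beads[:, 2] >= 0).all() and (beads[:, 2] <= cfg.depth_um).all()

    def test_clump_members_within_one_diameter(self, quiet_scene, bead_spec):
        plant_beads(quiet_scene, 60, bead_spec, clump_fraction=0.2, seed=8)
        truth = quiet_scene.truth
        ids = truth.clump_id
        assert (ids >= 0).sum() >= 2
        for cid in np.unique(ids[ids >= 0]):
            members = truth.beads[ids == cid]
            assert len(members) in (2, 3)
            for i in range(len(members)):
                for j in range(i + 1, len(members)):
                    assert np.linalg.norm(members[i] - members[j]) <= \
                        bead_spec.diameter_um + 1e-9

    def test_two_section_visibility(self, bead_spec, params):
        """Axially elongated bead images cross the detection threshold in at
        least two 10 um-spaced sections, whatever the bead's depth."""
        scene = generate_scene(quiet_config(50, 50, 60), seed=9)
        plant_beads(scene, 30, bead_spec, clump_fraction=0.0, seed=10)
        vol = scene.volumes[BEAD_CHANNEL]
        p = scene.config.pixel_size_um
        for x, y, z in scene.truth.beads:
            i, j = int(x / p), int(y / p)
            window = vol[:, max(0, j - 3):j + 4, max(0, i - 3):i + 4]
            planes_above = (window.max(axis=(1, 2)) > params.threshold).sum()
            assert planes_above >= 2

    def test_capacity_error_when_scene_too_small(self, bead_spec):
        scene = generate_scene(quiet_config(8, 8, 20), seed=0)
        with pytest.raises(CapacityError):
            plant_beads(scene, 100, bead_spec, clump_fraction=0.0, seed=1)

    def test_determinism(self, bead_spec):
        truths = []
        for _ in range(2):
            scene = generate_scene(quiet_config(), seed=3)
            plant_beads(scene, 25, bead_spec, clump_fraction=0.1, seed=4)
            truths.append(scene.truth.beads)
        np.testing.assert_array_equal(truths[0], truths[1])


class TestTileScene:
    def test_single_tile_is_full_scene(self, noisy_scene):
        ts = tile_scene(noisy_scene, 1, 1, 0.0)
        assert ts.layout.tile_shape_px == noisy_scene.config.grid_shape[1:]
        for ch in noisy_scene.config.channels:
            np.testing.assert_array_equal(ts.tiles[(0, 0)][ch],
                                          noisy_scene.volumes[ch])

    def test_offset_formula_and_shared_strip(self, noisy_scene):
        ts = tile_scene(noisy_scene, 1, 2, 0.1)
        (h, w) = ts.layout.tile_shape_px
        off_x = ts.layout.offsets[(0, 1)][0]
        assert off_x == round(0.9 * w)
        left = ts.tiles[(0, 0)][BEAD_CHANNEL]
        right = ts.tiles[(0, 1)][BEAD_CHANNEL]
        # the shared strip is voxelwise identical in both tiles
        np.testing.assert_array_equal(left[:, :, off_x:], right[:, :, :w - off_x])
        assert left[:, :, off_x:].shape[2] > 0

    def test_tiles_reconstruct_scene_region(self, noisy_scene):
        ts = tile_scene(noisy_scene, 2, 2, 0.1)
        h, w = ts.layout.tile_shape_px
        out_h, out_w = ts.layout.composite_shape_px
        vol = noisy_scene.volumes[BEAD_CHANNEL]
        rebuilt = np.zeros((vol.shape[0], out_h, out_w))
        for (r, c), (ox, oy) in ts.layout.offsets.items():
            rebuilt[:, oy:oy + h, ox:ox + w] = ts.tiles[(r, c)][BEAD_CHANNEL]
        np.testing.assert_array_equal(rebuilt, vol[:, :out_h, :out_w])

    def test_truth_beads_in_overlap_present_in_both_tiles(self, planted_tileset):
        ts, truth = planted_tileset
        (h, w) = ts.layout.tile_shape_px
        off_x = ts.layout.offsets[(0, 1)][0]
        p = ts.pixel_size_um
        in_strip = [
            (x, y, z) for x, y, z in truth.beads
            if off_x * p + 1 < x < w * p - 1 and 1 < y < h * p - 1
        ]
        assert in_strip  # fixture scene should exercise the overlap
        for x, y, z in in_strip:
            left = ts.tiles[(0, 0)][BEAD_CHANNEL]
            right = ts.tiles[(0, 1)][BEAD_CHANNEL]
            i_l, j = int(x / p), int(y / p)
            i_r = i_l - off_x
            assert left[:, j, i_l].max() > 0
            assert right[:, j, i_r].max() > 0

    def test_too_fine_grid_rejected(self, noisy_scene):
        with pytest.raises(ConfigurationError):
            tile_scene(noisy_scene, 1, 40, 0.1)


class TestCohort:
    def test_group_means_recovered(self):
        spec = CohortSpec(
            groups=(GroupSpec("day1", 5, 20.0), GroupSpec("day5", 5, 60.0)),
            seed=123,
            scene=quiet_config(),
            clump_fraction=0.0,
        )
        counts = {"day1": [], "day5": []}
        for rep in range(4):
            cohort = generate_cohort(
                CohortSpec(groups=spec.groups, seed=123 + rep,
                           scene=spec.scene, clump_fraction=0.0))
            for label, _aid, _tiles, truth in cohort:
                counts[label].append(len(truth))
        for label, mean in (("day1", 20.0), ("day5", 60.0)):
            vals = np.array(counts[label], dtype=float)
            se = np.sqrt(mean / len(vals))  # Poisson
            assert abs(vals.mean() - mean) < 3 * se

    def test_single_animal_zero_mean_is_empty(self):
        spec = CohortSpec(groups=(GroupSpec("g", 1, 0.0),), seed=1,
                          scene=quiet_config())
        [(label, aid, tiles, truth)] = generate_cohort(spec)
        assert label == "g" and len(truth) == 0

    def test_fold_ratio_effect_resolves_means(self):
        spec = CohortSpec(
            groups=(GroupSpec("day1", 2, 20.0), GroupSpec("day5", 2)),
            effects=(Effect("fold_ratio", 3.0, group="day5", reference="day1"),),
            scene=quiet_config(),
        )
        assert spec.resolved_means() == {"day1": 20.0, "day5": 60.0}

    def test_reduction_effect_resolves_means(self):
        spec = CohortSpec(
            groups=(GroupSpec("vehicle", 3, 60.0), GroupSpec("statin", 3)),
            effects=(Effect("reduction_percent", 37.0,
                            group="statin", reference="vehicle"),),
            scene=quiet_config(),
        )
        assert spec.resolved_means()["statin"] == pytest.approx(0.63 * 60.0)

    def test_unknown_group_label_rejected(self):
        with pytest.raises(ConfigurationError):
            CohortSpec(
                groups=(GroupSpec("a", 1, 5.0),),
                effects=(Effect("fold_ratio", 2.0, group="b", reference="a"),),
            )


class TestFlowEvents:
    def test_class_counts_sum_to_n_events(self):
        table = generate_flow_events(FlowComposition(n_events=5000), seed=2)
        assert len(table) == 5000

    def test_composition_recovered(self):
        comp = FlowComposition(n_events=20000)
        table = generate_flow_events(comp, seed=3)
        is_mono = table["true_class"].str.startswith("mono")
        live = table["true_class"] != "debris"
        frac = is_mono.sum() / live.sum()
        se = np.sqrt(0.127 * 0.873 / live.sum())
        assert abs(frac - 0.127) < 3 * se

    def test_zero_beadpos_means_no_elevated_fitc(self):
        comp = FlowComposition(n_events=2000, beadpos_fraction_of_monocytes=0.0)
        table = generate_flow_events(comp, seed=4)
        assert not table["true_class"].str.contains("beadpos").any()
        assert (table["fitc"] < 400).all()

    def test_determinism(self):
        comp = FlowComposition(n_events=1000)
        a = generate_flow_events(comp, seed=9)
        b = generate_flow_events(comp, seed=9)
        assert a.equals(b)

    def test_beadpos_cannot_exceed_gr1lo(self):
        with pytest.raises(ConfigurationError):
            FlowComposition(gr1lo_fraction_of_monocytes=0.1,
                            beadpos_fraction_of_monocytes=0.2)
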
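"""Spot-detector behaviour: projections, size gating, threshold
calibration and best-focus selection, checked against planted ground truth
and hand-computed expectations."""

import numpy as np
import pytest

from plaquebeads import (
    BEAD_CHANNEL,
    BeadSpec,
    DetectionParams,
    best_focus_plane,
    calibrate_threshold,
    detect_spots,
    generate_scene,
    plant_beads,
    sum_projection,
)
from plaquebeads.detect import Detection
from plaquebeads.synthetic import _render_bead

from conftest import quiet_config

PIXEL = 0.25


def _bead_image(centers_and_specs, shape_um=(40, 40), depth_um=40):
    """Render beads at chosen positions into a quiet scene and project."""
    cfg = quiet_config(*shape_um, depth_um)
    scene = generate_scene(cfg, seed=0)
    vol = scene.volumes[BEAD_CHANNEL]
    for center, spec in centers_and_specs:
        _render_bead(vol, np.asarray(center, dtype=float), spec, cfg)
    return sum_projection(vol), scene


class TestSumProjection:
    def test_all_zero_stack(self):
        assert np.all(sum_projection(np.zeros((4, 5, 5))) == 0)

    def test_single_plane_identity(self):
        plane = np.arange(12.0).reshape(3, 4)
        np.testing.assert_array_equal(sum_projection(plane[None]), plane)

    def test_constant_planes_sum(self):
        stack = np.stack([np.full((3, 3), v) for v in (1.0, 2.0, 4.0)])
        np.testing.assert_array_equal(sum_projection(stack), np.full((3, 3), 7.0))

    def test_no_saturation_on_narrow_dtype(self):
        stack = np.full((300, 4, 4), 255, dtype=np.uint8)
        assert sum_projection(stack).max() == 300 * 255

    def test_empty_stack_rejected(self):
        with pytest.raises(ValueError):
            sum_projection(np.zeros((0, 4, 4)))
        with pytest.raises(ValueError):
            sum_projection(np.zeros((4, 4)))

    def test_linearity(self):
        rng = np.random.default_rng(0)
        stack = rng.uniform(0, 10, size=(5, 8, 8))
        np.testing.assert_allclose(sum_projection(3.7 * stack),
                                   3.7 * sum_projection(stack))


class TestDetectSpots:
    def test_size_gate_keeps_only_bead_sized_spots(self, params):
        """Of three spots with diameters 0.3, 1.0 and 2.5 um, only the
        1 um one passes the 0.5-1.5 um equivalent-diameter gate."""
        image, _ = _bead_image([
            ((10.125, 10.125, 20), BeadSpec(diameter_um=0.3,
                                            lateral_sigma_um=0.05)),
            ((20, 20, 20), BeadSpec(diameter_um=1.0)),
            ((30, 30, 20), BeadSpec(diameter_um=2.5, lateral_sigma_um=0.3)),
        ])
        dets = [d for d in detect_spots(image, params, PIXEL)
                if not d.clump_flag]
        assert len(dets) == 1
        assert abs((dets[0].x_px + 0.5) * PIXEL - 20) < 0.5

    def test_blank_image_gives_no_detections(self, params):
        assert detect_spots(np.zeros((64, 64)), params, PIXEL) == []

    def test_recall_and_centroids_on_planted_truth(self, params, bead_spec):
        scene = generate_scene(quiet_config(), seed=1)
        plant_beads(scene, 20, bead_spec, clump_fraction=0.0, seed=2)
        image = sum_projection(scene.volumes[BEAD_CHANNEL])
        dets = detect_spots(image, params, PIXEL)
        assert len(dets) == 20
        truth = scene.truth.beads
        for det in dets:
            x = (det.x_px + 0.5) * PIXEL
            y = (det.y_px + 0.5) * PIXEL
            assert np.hypot(truth[:, 0] - x, truth[:, 1] - y).min() < PIXEL

    def test_size_filter_invariant(self, noisy_scene, params):
        image = sum_projection(noisy_scene.volumes[BEAD_CHANNEL])
        for det in detect_spots(image, params, PIXEL):
            if not det.clump_flag:
                assert params.min_diameter_um <= det.equivalent_diameter_um
                assert det.equivalent_diameter_um <= params.max_diameter_um

    def test_raising_threshold_never_increases_count(self, noisy_scene):
        image = sum_projection(noisy_scene.volumes[BEAD_CHANNEL])
        counts = [
            len(detect_spots(image, DetectionParams(threshold=t), PIXEL))
            for t in (10, 15, 20, 40, 80, 200)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_clump_never_dropped_or_overcounted(self, params):
        """Three beads within one diameter merge into a single bright spot:
        the detector may resolve it into at most three detections but must
        report at least one and never more than the true multiplicity."""
        image, _ = _bead_image([
            ((20.0, 20.0, 20), BeadSpec()),
            ((20.8, 20.0, 20), BeadSpec()),
            ((20.4, 20.7, 20), BeadSpec()),
        ])
        dets = detect_spots(image, params, PIXEL)
        assert 1 <= len(dets) <= 3


class TestCalibrateThreshold:
    def _reference_images(self):
        """20 true beads of peak ~8 over zero background, plus faint
        speckles that only survive the lowest threshold."""
        rng = np.random.default_rng(5)
        image, scene = _bead_image(
            [((x, y, 20), BeadSpec(peak_intensity=8.0 / 1.2))
             for x, y in rng.uniform(4, 36, size=(20, 2))
             ],
        )
        # faint 2x2 speckles: in-range diameter, below threshold 5
        for _ in range(30):
            i, j = rng.integers(4, 150, size=2)
            image[j:j + 2, i:i + 2] += 3.0
        return image

    def test_exhaustive_scan_oracle(self):
        params = DetectionParams(threshold=1.0)
        image = self._reference_images()
        grid = [1.0, 5.0, 10.0]
        # independent oracle: brute-force scan of the same grid
        errs = {
            t: abs(len(detect_spots(image, DetectionParams(threshold=t), PIXEL))
                   - 20)
            for t in grid
        }
        expected = min(sorted(grid), key=lambda t: (errs[t], t))
        got = calibrate_threshold([image], [20], grid, params, PIXEL)
        assert got == expected == 5.0
        # sanity on the scan itself: low threshold over-counts, high misses
        assert errs[1.0] > 0 and errs[10.0] == 20

    def test_tie_breaks_toward_smallest_threshold(self, params):
        image, _ = _bead_image([((20, 20, 20), BeadSpec())])
        got = calibrate_threshold([image], [1], [40.0, 20.0, 30.0],
                                  params, PIXEL)
        assert got == 20.0

    def test_two_reference_sets_minimize_summed_error(self):
        """With one sparse and one dense reference composite, the chosen
        threshold minimises the summed absolute count error over both."""
        params = DetectionParams()
        rng = np.random.default_rng(8)
        imgs, refs = [], []
        for n in (5, 15):
            centers = []
            while len(centers) < n:
                c = rng.uniform(5, 35, size=2)
                if all(np.hypot(*(c - o)) > 4 for o in centers):
                    centers.append(c)
            img, _ = _bead_image([((x, y, 20), BeadSpec()) for x, y in centers])
            imgs.append(img)
            refs.append(n)
        grid = [5.0, 15.0, 500.0]
        got = calibrate_threshold(imgs, refs, grid, params, PIXEL)
        errs = [
            sum(abs(len(detect_spots(im, DetectionParams(threshold=t), PIXEL))
                    - r) for im, r in zip(imgs, refs))
            for t in grid
        ]
        assert got == grid[int(np.argmin(errs))]

    def test_empty_inputs_rejected(self, params):
        with pytest.raises(ValueError):
            calibrate_threshold([], [], [1.0], params, PIXEL)
        with pytest.raises(ValueError):
            calibrate_threshold([np.zeros((8, 8))], [1], [], params, PIXEL)


class TestBestFocus:
    def _stack_with_peak(self, peak_plane, nz=9):
        stack = np.zeros((nz, 32, 32))
        profile = np.exp(-((np.arange(nz) - peak_plane) ** 2) / 4.0)
        yy, xx = np.mgrid[:32, :32]
        spot = np.exp(-((yy - 16) ** 2 + (xx - 16) ** 2) / 8.0)
        return stack + 50.0 * profile[:, None, None] * spot[None]

    def _detection(self):
        return Detection(tile_index=(0, 0), x_px=16.0, y_px=16.0,
                         peak_intensity=50.0, equivalent_diameter_um=1.0)

    def test_argmax_over_planes(self):
        stack = self._stack_with_peak(peak_plane=5)
        assert best_focus_plane(stack, self._detection(), 5.0, PIXEL) == 5

    def test_single_plane_stack(self):
        stack = self._stack_with_peak(peak_plane=0, nz=1)
        assert best_focus_plane(stack, self._detection(), 5.0, PIXEL) == 0

    def test_threshold_above_peak_filters_out(self):
        stack = self._stack_with_peak(peak_plane=5)
        assert best_focus_plane(stack, self._detection(), 1e6, PIXEL) is None

    def test_footprint_outside_stack_rejected(self):
        det = Detection(tile_index=(0, 0), x_px=100.0, y_px=5.0,
                        peak_intensity=1.0, equivalent_diameter_um=1.0)
        with pytest.raises(ValueError):
            best_focus_plane(np.zeros((3, 32, 32)), det, 1.0, PIXEL)
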
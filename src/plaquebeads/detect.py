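"""Bead-sized spot detection on sum projections of z-stacks.

The detector mirrors a classic particle-counting workflow: estimate a
smooth local background, threshold the brightness above it, take
8-connected components, and keep components whose equivalent-circle
diameter falls inside the bead size bounds (0.5–1.5 µm by default).
Oversized components are split at internal intensity maxima when the
maxima are separable; otherwise they are emitted once and flagged as a
clump of beads.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.measure import label as sk_label
from skimage.segmentation import watershed

from .config import DetectionParams

__all__ = [
    "Detection",
    "sum_projection",
    "detect_spots",
    "calibrate_threshold",
    "best_focus_plane",
]


@dataclass
class Detection:
    """One candidate bead.

    ``x_px``/``y_px`` are sub-pixel intensity-weighted centroids in the
    tile's index space (integer values at pixel centres, x along columns).
    Global micron coordinates are filled in by :func:`plaquebeads.mosaic.to_global`.
    """

    tile_index: Tuple[int, int]
    x_px: float
    y_px: float
    peak_intensity: float
    equivalent_diameter_um: float
    x_um: Optional[float] = None
    y_um: Optional[float] = None
    z_best: Optional[int] = None
    clump_flag: bool = False


def sum_projection(stack: np.ndarray) -> np.ndarray:
    """Pixelwise sum of a (z, y, x) stack along z, in float64 so that no
    saturation can occur regardless of the input dtype."""
    stack = np.asarray(stack)
    if stack.ndim != 3 or stack.shape[0] < 1:
        raise ValueError("stack must be a (z, y, x) array with >= 1 plane")
    return stack.sum(axis=0, dtype=np.float64)


def local_background(image: np.ndarray, radius_px: int) -> np.ndarray:
    """Median-filter background estimate with the given radius.

    For large radii the median is computed on a block-averaged copy of the
    image and expanded back, which is orders of magnitude faster and
    indistinguishable for backgrounds that vary slowly compared to a bead
    footprint.
    """
    image = np.asarray(image, dtype=np.float64)
    radius_px = max(1, int(radius_px))
    if radius_px <= 6:
        return ndi.median_filter(image, size=2 * radius_px + 1, mode="nearest")
    b = max(2, radius_px // 5)
    ny, nx = image.shape
    py, px = (-ny) % b, (-nx) % b
    padded = np.pad(image, ((0, py), (0, px)), mode="edge")
    blocks = padded.reshape(padded.shape[0] // b, b, padded.shape[1] // b, b)
    coarse = blocks.mean(axis=(1, 3))
    r = max(1, math.ceil(radius_px / b))
    coarse_bg = ndi.median_filter(coarse, size=2 * r + 1, mode="nearest")
    return np.repeat(np.repeat(coarse_bg, b, axis=0), b, axis=1)[:ny, :nx]


def _equivalent_diameter_um(area_px: int, pixel_size_um: float) -> float:
    return 2.0 * math.sqrt(area_px / math.pi) * pixel_size_um


def _measure(diff: np.ndarray, mask: np.ndarray, tile_index: Tuple[int, int],
             pixel_size_um: float, clump: bool) -> Detection:
    ys, xs = np.nonzero(mask)
    w = np.clip(diff[ys, xs], 0.0, None)
    total = w.sum()
    if total <= 0:  # degenerate: unweighted centroid
        cy, cx = ys.mean(), xs.mean()
    else:
        cy, cx = (ys * w).sum() / total, (xs * w).sum() / total
    return Detection(
        tile_index=tile_index,
        x_px=float(cx),
        y_px=float(cy),
        peak_intensity=float(diff[ys, xs].max()),
        equivalent_diameter_um=_equivalent_diameter_um(len(ys), pixel_size_um),
        clump_flag=clump,
    )


def detect_spots(
    image: np.ndarray,
    params: DetectionParams,
    pixel_size_um: float,
    tile_index: Tuple[int, int] = (0, 0),
) -> List[Detection]:
    """Detect bead-sized spots in a 2D image.

    Pixels brighter than ``local background + threshold`` are grouped into
    8-connected components.  Each component is then sized at half of its own
    peak brightness (never below the threshold), which makes the measured
    equivalent diameter independent of how bright the bead happens to be —
    the same way an observer sizes a bead image by its visible core, not by
    its faint skirt.  Half-max cores within the diameter bounds become
    detections with intensity-weighted sub-pixel centroids; undersized ones
    are discarded as noise; oversized ones are watershed-split at internal
    maxima when possible, else kept once with ``clump_flag`` set.
    """
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be > 0")
    image = np.asarray(image, dtype=np.float64)
    radius_px = max(1, round(params.local_background_radius_um / pixel_size_um))
    diff = image - local_background(image, radius_px)
    mask = diff > params.threshold
    if not mask.any():
        return []
    labels = sk_label(mask, connectivity=2)
    min_d, max_d = params.min_diameter_um, params.max_diameter_um
    min_sep_px = max(1, round(min_d / pixel_size_um))
    out: List[Detection] = []
    for lab, region in enumerate(ndi.find_objects(labels), start=1):
        if region is None:
            continue
        # work on the bounding box of each component
        component = labels[region] == lab
        sub_diff = diff[region]
        level = max(params.threshold, 0.5 * sub_diff[component].max())
        cores = sk_label(component & (sub_diff >= level), connectivity=2)
        for core_lab, core_region in enumerate(ndi.find_objects(cores), start=1):
            if core_region is None:
                continue
            core = cores == core_lab
            area = int(core.sum())
            d_eq = _equivalent_diameter_um(area, pixel_size_um)
            if d_eq < min_d:
                continue
            if d_eq <= max_d:
                det = _measure(sub_diff, core, tile_index,
                               pixel_size_um, clump=False)
                _shift(det, region)
                out.append(det)
                continue
            out.extend(_split_clump(sub_diff, core, region, tile_index,
                                    pixel_size_um, min_d, max_d, min_sep_px))
    out.sort(key=lambda d: (d.y_px, d.x_px))
    return out


def _shift(det: Detection, region: Tuple[slice, slice]) -> None:
    det.y_px += region[0].start
    det.x_px += region[1].start


def _split_clump(sub_diff, component, region, tile_index, pixel_size_um,
                 min_d, max_d, min_sep_px) -> List[Detection]:
    """Attempt to split an oversized component at internal intensity maxima."""
    masked = np.where(component, sub_diff, 0.0)
    peaks = peak_local_max(masked, min_distance=min_sep_px,
                           exclude_border=False,
                           labels=component.astype(np.int32))
    dets: List[Detection] = []
    if len(peaks) >= 2:
        markers = np.zeros(component.shape, dtype=np.int32)
        for i, (py, px) in enumerate(peaks, start=1):
            markers[py, px] = i
        frag_labels = watershed(-masked, markers=markers, mask=component)
        for lab in range(1, len(peaks) + 1):
            frag = frag_labels == lab
            area = int(frag.sum())
            if area == 0:
                continue
            d_eq = _equivalent_diameter_um(area, pixel_size_um)
            if min_d <= d_eq <= max_d:
                det = _measure(sub_diff, frag, tile_index, pixel_size_um,
                               clump=True)
                _shift(det, region)
                dets.append(det)
        if dets:
            return dets
    det = _measure(sub_diff, component, tile_index, pixel_size_um, clump=True)
    _shift(det, region)
    return [det]


def calibrate_threshold(
    projections: Sequence[np.ndarray],
    reference_counts: Sequence[int],
    threshold_grid: Sequence[float],
    params: DetectionParams,
    pixel_size_um: float,
) -> float:
    """Pick the threshold whose automated counts best match reference counts.

    The reference counts play the role of counts obtained by visual
    inspection of representative composite images.  The returned grid value
    minimises the summed absolute count error; ties break toward the
    smallest threshold.
    """
    if len(projections) == 0 or len(threshold_grid) == 0:
        raise ValueError("projections and threshold_grid must be non-empty")
    if len(projections) != len(reference_counts):
        raise ValueError("projections and reference_counts must have equal length")
    best_t, best_err = None, None
    for t in sorted(float(t) for t in threshold_grid):
        trial = DetectionParams(
            min_diameter_um=params.min_diameter_um,
            max_diameter_um=params.max_diameter_um,
            threshold=t,
            local_background_radius_um=params.local_background_radius_um,
        )
        err = sum(
            abs(len(detect_spots(img, trial, pixel_size_um)) - int(ref))
            for img, ref in zip(projections, reference_counts)
        )
        if best_err is None or err < best_err:
            best_t, best_err = t, err
    return best_t


def best_focus_plane(
    stack: np.ndarray,
    detection: Detection,
    focus_threshold: float,
    pixel_size_um: float,
) -> Optional[int]:
    """Index of the z-plane where the detection's signal is brightest.

    The per-plane signal is the mean background-subtracted intensity over a
    disk footprint of the detection's radius (background: median of a
    surrounding ring).  Returns ``None`` if no plane reaches
    ``focus_threshold`` — the higher cutoff used so that only the plane of
    best focus survives.  Ties resolve to the lowest z-index.
    """
    stack = np.asarray(stack, dtype=np.float64)
    if stack.ndim != 3:
        raise ValueError("stack must be (z, y, x)")
    nz, ny, nx = stack.shape
    cy, cx = int(round(detection.y_px)), int(round(detection.x_px))
    if not (0 <= cy < ny and 0 <= cx < nx):
        raise ValueError("detection footprint lies outside the stack")
    r = max(1, round(detection.equivalent_diameter_um / 2 / pixel_size_um))
    yy, xx = np.ogrid[:ny, :nx]
    dist2 = (yy - cy) ** 2 + (xx - cx) ** 2
    foot = dist2 <= r**2
    ring = (dist2 > (r + 2) ** 2) & (dist2 <= (r + 6) ** 2)
    if not ring.any():  # tiny image: fall back to everything outside the foot
        ring = ~foot
    signal = np.empty(nz)
    for k in range(nz):
        plane = stack[k]
        signal[k] = plane[foot].mean() - float(np.median(plane[ring]))
    z = int(np.argmax(signal))
    if signal[z] < focus_threshold:
        return None
    return z
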
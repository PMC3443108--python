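"""Presentation artifacts: axial-distortion-corrected reconstructions,
bead dilation overlays and Gaussian channel smoothing.

These operations change how the data *look*, never what is counted: bead
counts computed before and after any of them are identical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Sequence, Tuple

import numpy as np
from scipy import ndimage as ndi

from .config import BEAD_CHANNEL, ConfigurationError
from .detect import Detection
from .mosaic import TileSet, stitch

__all__ = [
    "CorrectedVolume",
    "reconstruct_corrected",
    "detection_mask",
    "dilate_detections",
    "smooth_channel",
]


@dataclass
class CorrectedVolume:
    """Stitched (z, y, x) volumes in which the bead channel has been
    replaced by single-plane bead markers at best-focus positions."""

    volumes: Dict[str, np.ndarray]
    marker_diameter_um: float
    pixel_size_um: float
    z_step_um: float


def reconstruct_corrected(
    tileset: TileSet,
    detections_with_z: Sequence[Detection],
    marker_diameter_um: float = 1.0,
) -> CorrectedVolume:
    """Build a 3D reconstruction with axially collapsed beads.

    A low-NA objective in scattering tissue smears a 1 µm bead over many
    z-sections.  To correct the distortion, the bead channel is zeroed and
    every detection is re-rendered as a uniform disk of
    ``marker_diameter_um`` in the single plane of best focus (``z_best``),
    at the intensity of the detection's peak.  Overlapping markers
    composite by maximum (union), and the other channels are stitched
    through unchanged.
    """
    for det in detections_with_z:
        if det.z_best is None:
            raise ValueError("every detection must carry z_best")
        if det.x_um is None or det.y_um is None:
            raise ValueError("every detection must carry global coordinates")
    layout = tileset.layout
    nz = next(iter(tileset.tiles.values()))[tileset.channels[0]].shape[0]
    volumes: Dict[str, np.ndarray] = {}
    for ch in tileset.channels:
        planes = [
            stitch({rc: tileset.tiles[rc][ch][k] for rc in tileset.tiles},
                   layout).image
            for k in range(nz)
        ]
        volumes[ch] = np.stack(planes, axis=0)
    bead_vol = np.zeros_like(volumes[BEAD_CHANNEL])
    radius_px = marker_diameter_um / 2.0 / tileset.pixel_size_um
    for det in detections_with_z:
        cx = det.x_um / tileset.pixel_size_um - 0.5
        cy = det.y_um / tileset.pixel_size_um - 0.5
        _stamp_disk_max(bead_vol[det.z_best], (cy, cx), radius_px,
                        det.peak_intensity)
    volumes[BEAD_CHANNEL] = bead_vol
    return CorrectedVolume(
        volumes=volumes,
        marker_diameter_um=marker_diameter_um,
        pixel_size_um=tileset.pixel_size_um,
        z_step_um=tileset.z_step_um,
    )


def _stamp_disk_max(plane: np.ndarray, center: Tuple[float, float],
                    radius_px: float, value: float) -> None:
    cy, cx = center
    r = max(radius_px, 0.5)
    y0 = max(0, int(math.floor(cy - r)))
    y1 = min(plane.shape[0], int(math.ceil(cy + r)) + 1)
    x0 = max(0, int(math.floor(cx - r)))
    x1 = min(plane.shape[1], int(math.ceil(cx + r)) + 1)
    if y0 >= y1 or x0 >= x1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    inside = (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
    region = plane[y0:y1, x0:x1]
    region[inside] = np.maximum(region[inside], value)


def detection_mask(
    shape: Tuple[int, int],
    detections: Sequence[Detection],
    pixel_size_um: float,
    diameter_um: float,
) -> np.ndarray:
    """Binary union of disks of ``diameter_um`` stamped at the detections'
    global positions (overlaps merge; nothing ever sums)."""
    mask = np.zeros(shape, dtype=bool)
    r = diameter_um / 2.0 / pixel_size_um
    for det in detections:
        if det.x_um is None or det.y_um is None:
            raise ValueError("detections must carry global coordinates")
        cx = det.x_um / pixel_size_um - 0.5
        cy = det.y_um / pixel_size_um - 0.5
        y0 = max(0, int(math.floor(cy - r)))
        y1 = min(shape[0], int(math.ceil(cy + r)) + 1)
        x0 = max(0, int(math.floor(cx - r)))
        x1 = min(shape[1], int(math.ceil(cx + r)) + 1)
        if y0 >= y1 or x0 >= x1:
            continue
        yy, xx = np.mgrid[y0:y1, x0:x1]
        mask[y0:y1, x0:x1] |= (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
    return mask


def dilate_detections(
    image: np.ndarray,
    detections: Sequence[Detection],
    pixel_size_um: float,
    display_diameter_um: float = 20.0,
    value: "float | None" = None,
) -> np.ndarray:
    """Overlay display-sized bead markers on a composite image.

    A 1 µm bead is invisible at whole-plaque scale, so each detection is
    dilated to ``display_diameter_um`` (20 µm by default) for presentation.
    Markers are a binary union set to ``value`` (default: the image maximum,
    or 1 on an empty image); with no detections the image is returned
    unchanged.
    """
    if display_diameter_um <= 0:
        raise ConfigurationError("display_diameter_um must be > 0")
    image = np.asarray(image, dtype=np.float64)
    overlay = image.copy()
    if not detections:
        return overlay
    mask = detection_mask(image.shape, detections, pixel_size_um,
                          display_diameter_um)
    if value is None:
        value = float(image.max()) if image.max() > 0 else 1.0
    overlay[mask] = value
    return overlay


def smooth_channel(image: np.ndarray, kernel_px: int = 7,
                   sigma_px: "float | None" = None) -> np.ndarray:
    """Convolve with a normalized k x k Gaussian kernel (default 7 x 7).

    The kernel support is exactly ``kernel_px`` pixels; sigma defaults to
    ``kernel_px / 6`` so the support spans about +/-3 sigma.  Normalization
    preserves the mean intensity up to boundary effects (nearest-edge
    padding).
    """
    if kernel_px < 3 or kernel_px % 2 == 0:
        raise ConfigurationError("kernel_px must be an odd integer >= 3")
    if sigma_px is None:
        sigma_px = kernel_px / 6.0
    half = kernel_px // 2
    x = np.arange(-half, half + 1, dtype=np.float64)
    g = np.exp(-(x**2) / (2.0 * sigma_px**2))
    kernel = np.outer(g, g)
    kernel /= kernel.sum()
    return ndi.convolve(np.asarray(image, dtype=np.float64), kernel,
                        mode="nearest")
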
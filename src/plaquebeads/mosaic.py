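"""Tile layout, composite stitching and overlap-aware bead de-duplication.

Adjacent z-stacks in a tiled acquisition share a fixed overlap fraction
(10% here), so a bead sitting in an overlap strip is imaged — and detected —
in more than one tile.  This module places tiles on a global pixel grid from
the stage model (no cross-correlation registration), maps detections into
global coordinates and merges duplicates, keeping the brighter member of
each cross-tile pair.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, TYPE_CHECKING

import numpy as np

from .config import BEAD_CHANNEL, CHANNELS, ConfigurationError, DetectionParams
from .detect import Detection, best_focus_plane, detect_spots, sum_projection

if TYPE_CHECKING:  # pragma: no cover
    from .synthetic import GroundTruth

__all__ = [
    "TileLayout",
    "TileSet",
    "Composite",
    "layout_tiles",
    "stitch",
    "to_global",
    "deduplicate",
    "detect_tileset",
    "assign_best_focus",
    "count_sample",
]


@dataclass(frozen=True)
class TileLayout:
    """Global pixel offsets of a row-major tile grid.

    Adjacent offsets differ by ``round((1 - overlap_fraction) * extent)``
    along each axis, matching a stage that advances by the field of view
    minus the programmed overlap.
    """

    grid_rows: int
    grid_cols: int
    tile_shape_px: Tuple[int, int]  # (height, width)
    overlap_fraction: float
    offsets: Mapping[Tuple[int, int], Tuple[int, int]]  # (row, col) -> (x, y)

    @property
    def composite_shape_px(self) -> Tuple[int, int]:
        h, w = self.tile_shape_px
        last_x, last_y = self.offsets[(self.grid_rows - 1, self.grid_cols - 1)]
        return (last_y + h, last_x + w)


@dataclass
class TileSet:
    """Per-tile z-stacks for each channel, plus the acquisition geometry.

    ``tiles[(row, col)][channel]`` is a (z, y, x) array.  When the tiles
    come from the simulator, ``truth`` carries the planted bead centres in
    scene-global micron coordinates.
    """

    tiles: Dict[Tuple[int, int], Dict[str, np.ndarray]]
    layout: TileLayout
    pixel_size_um: float
    z_step_um: float
    channels: Tuple[str, ...] = CHANNELS
    sample: str = "sample"
    truth: "Optional[GroundTruth]" = None


@dataclass
class Composite:
    """A stitched 2D image plus, for every pixel, the flat index
    (row * grid_cols + col) of the tile that supplied its value."""

    image: np.ndarray
    provenance: np.ndarray


def layout_tiles(
    grid_rows: int,
    grid_cols: int,
    tile_shape_px: Tuple[int, int],
    overlap_fraction: float,
) -> TileLayout:
    """Row-major tile offsets for a regular grid with fractional overlap."""
    h, w = tile_shape_px
    if grid_rows < 1 or grid_cols < 1:
        raise ConfigurationError("grid dimensions must be >= 1")
    if h <= 0 or w <= 0:
        raise ConfigurationError("tile shape must be positive")
    if not 0 <= overlap_fraction < 1:
        raise ConfigurationError("overlap_fraction must lie in [0, 1)")
    step_x = round((1.0 - overlap_fraction) * w)
    step_y = round((1.0 - overlap_fraction) * h)
    offsets = {
        (r, c): (c * step_x, r * step_y)
        for r in range(grid_rows)
        for c in range(grid_cols)
    }
    return TileLayout(grid_rows, grid_cols, (h, w), overlap_fraction, offsets)


def stitch(images: Mapping[Tuple[int, int], np.ndarray],
           layout: TileLayout) -> Composite:
    """Stitch single-channel 2D tile images into a composite.

    Overlap strips resolve by the per-pixel maximum so that a bead is never
    dimmed by averaging against another tile's background; on exact ties the
    earlier tile in row-major order wins.
    """
    if len(images) != layout.grid_rows * layout.grid_cols:
        raise ValueError("tile count does not match the layout grid")
    h, w = layout.tile_shape_px
    out_h, out_w = layout.composite_shape_px
    canvas = np.zeros((out_h, out_w), dtype=np.float64)
    prov = np.full((out_h, out_w), -1, dtype=np.int32)
    for r in range(layout.grid_rows):
        for c in range(layout.grid_cols):
            tile = np.asarray(images[(r, c)], dtype=np.float64)
            if tile.shape != (h, w):
                raise ValueError(
                    f"tile {(r, c)} has shape {tile.shape}, expected {(h, w)}")
            ox, oy = layout.offsets[(r, c)]
            region = (slice(oy, oy + h), slice(ox, ox + w))
            take = (prov[region] == -1) | (tile > canvas[region])
            canvas[region][take] = tile[take]
            prov[region][take] = r * layout.grid_cols + c
    return Composite(image=canvas, provenance=prov)


def to_global(
    detections: Sequence[Detection],
    layout: TileLayout,
    pixel_size_um: float,
) -> List[Detection]:
    """Fill in global micron coordinates from tile offsets.

    Pixel index ``i`` samples the centre of the half-open interval
    ``[i*s, (i+1)*s)``, so the micron coordinate is ``(i + offset + 0.5) * s``.
    """
    out: List[Detection] = []
    for det in detections:
        if det.tile_index not in layout.offsets:
            raise ValueError(f"tile index {det.tile_index} outside the grid")
        ox, oy = layout.offsets[det.tile_index]
        out.append(replace(
            det,
            x_um=(det.x_px + ox + 0.5) * pixel_size_um,
            y_um=(det.y_px + oy + 0.5) * pixel_size_um,
        ))
    return out


def deduplicate(
    global_detections: Sequence[Detection],
    match_radius_um: float,
) -> List[Detection]:
    """Merge cross-tile duplicates within ``match_radius_um``.

    Detections are visited brightest-first (deterministic tie-break on
    position), and a detection is dropped when an already-kept detection
    from a *different* tile lies within the match radius — one physical bead
    cannot produce two centres farther apart than its own diameter, and
    same-tile neighbours are genuinely distinct objects.  The result is
    independent of the input order and idempotent.
    """
    if match_radius_um <= 0:
        raise ValueError("match_radius_um must be > 0")
    for det in global_detections:
        if det.x_um is None or det.y_um is None:
            raise ValueError("detections must carry global coordinates")
    order = sorted(
        global_detections,
        key=lambda d: (-d.peak_intensity, d.y_um, d.x_um, d.tile_index),
    )
    kept: List[Detection] = []
    r2 = match_radius_um**2
    for det in order:
        dup = any(
            k.tile_index != det.tile_index
            and (k.x_um - det.x_um) ** 2 + (k.y_um - det.y_um) ** 2 <= r2
            for k in kept
        )
        if not dup:
            kept.append(det)
    kept.sort(key=lambda d: (d.y_um, d.x_um))
    return kept


def detect_tileset(
    tileset: TileSet,
    params: DetectionParams,
    channel: str = BEAD_CHANNEL,
    match_radius_um: Optional[float] = None,
) -> List[Detection]:
    """Project, detect, map to global coordinates and de-duplicate.

    The full per-sample counting chain: each tile's bead-channel stack is
    sum-projected, spots are detected per tile, mapped into the mosaic and
    merged across overlap strips.  The default match radius is the maximum
    bead diameter.
    """
    radius = params.max_diameter_um if match_radius_um is None else match_radius_um
    detections: List[Detection] = []
    for (r, c) in sorted(tileset.tiles):
        stack = tileset.tiles[(r, c)][channel]
        proj = sum_projection(stack)
        detections.extend(
            detect_spots(proj, params, tileset.pixel_size_um, tile_index=(r, c)))
    detections = to_global(detections, tileset.layout, tileset.pixel_size_um)
    return deduplicate(detections, radius)


def assign_best_focus(
    tileset: TileSet,
    detections: Sequence[Detection],
    focus_threshold: float,
    channel: str = BEAD_CHANNEL,
) -> List[Detection]:
    """Attach the best-focus z-plane to each detection; detections whose
    axial profile never reaches ``focus_threshold`` are dropped, mirroring
    the stricter cutoff used for axial-distortion correction."""
    out: List[Detection] = []
    for det in detections:
        stack = tileset.tiles[det.tile_index][channel]
        z = best_focus_plane(stack, det, focus_threshold, tileset.pixel_size_um)
        if z is not None:
            out.append(replace(det, z_best=z))
    return out


def count_sample(
    tileset: TileSet,
    params: DetectionParams,
    channel: str = BEAD_CHANNEL,
    match_radius_um: Optional[float] = None,
) -> int:
    """Number of unique beads in one tiled sample (project → detect →
    global map → de-duplicate → count)."""
    return len(detect_tileset(tileset, params, channel, match_radius_um))
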
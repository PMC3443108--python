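"""Standard-format I/O: multi-page TIFF tile stacks, CSV detection and
count tables, JSON/YAML configuration and reports.

One tile/channel pair is stored as one multi-page TIFF (one page per
z-plane), named ``{sample}_{row}_{col}_{channel}.tif``; the acquisition
geometry travels alongside in ``{sample}_layout.json`` and the planted
truth, when present, in ``{sample}_truth.csv``.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import tifffile
import yaml

from .config import (
    BackgroundModel,
    BeadSpec,
    DetectionParams,
    GateParams,
    NoiseModel,
    SceneConfig,
)
from .detect import Detection
from .mosaic import TileLayout, TileSet, layout_tiles
from .stats import group_summary
from .synthetic import GroundTruth

__all__ = [
    "RunConfig",
    "tile_filename",
    "write_tileset",
    "read_tileset",
    "write_detections",
    "read_detections",
    "write_counts",
    "read_counts",
    "write_report",
]


@dataclasses.dataclass
class RunConfig:
    """Bundle of pipeline settings loadable from one YAML file."""

    scene: SceneConfig = dataclasses.field(default_factory=SceneConfig)
    bead: BeadSpec = dataclasses.field(default_factory=BeadSpec)
    detection: DetectionParams = dataclasses.field(default_factory=DetectionParams)
    gates: GateParams = dataclasses.field(default_factory=GateParams)
    grid: Tuple[int, int] = (2, 2)
    overlap_fraction: float = 0.1
    match_radius_um: Optional[float] = None  # default: max bead diameter
    direction: str = "greater"  # alternative for the one-tailed t-test
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: "str | Path") -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = {}
        for key, sub in (("scene", SceneConfig), ("bead", BeadSpec),
                         ("detection", DetectionParams), ("gates", GateParams)):
            if key in raw:
                section = dict(raw[key])
                for k, v in section.items():
                    if isinstance(v, list):
                        section[k] = tuple(v)
                if key == "scene":
                    if "background" in section:
                        section["background"] = BackgroundModel(
                            **section["background"])
                    if "noise" in section:
                        section["noise"] = NoiseModel(**section["noise"])
                kwargs[key] = sub(**section)
        for key in ("grid", "overlap_fraction", "match_radius_um",
                    "direction", "seed"):
            if key in raw:
                val = raw[key]
                kwargs[key] = tuple(val) if key == "grid" else val
        return cls(**kwargs)


def tile_filename(sample: str, row: int, col: int, channel: str) -> str:
    return f"{sample}_{row}_{col}_{channel}.tif"


def write_tileset(tileset: TileSet, directory: "str | Path",
                  sample: Optional[str] = None) -> Path:
    """Write every tile/channel stack as a multi-page TIFF plus the layout
    JSON and, if present, the planted-truth CSV.  Returns the directory."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    sample = sample or tileset.sample
    for (r, c), channels in sorted(tileset.tiles.items()):
        for ch, stack in channels.items():
            tifffile.imwrite(directory / tile_filename(sample, r, c, ch),
                             np.asarray(stack, dtype=np.float32),
                             photometric="minisblack")
    layout = tileset.layout
    meta = {
        "sample": sample,
        "grid_rows": layout.grid_rows,
        "grid_cols": layout.grid_cols,
        "tile_shape_px": list(layout.tile_shape_px),
        "overlap_fraction": layout.overlap_fraction,
        "pixel_size_um": tileset.pixel_size_um,
        "z_step_um": tileset.z_step_um,
        "channels": list(tileset.channels),
    }
    (directory / f"{sample}_layout.json").write_text(
        json.dumps(meta, indent=2, sort_keys=True) + "\n")
    if tileset.truth is not None and len(tileset.truth):
        tileset.truth.to_frame().to_csv(
            directory / f"{sample}_truth.csv", index=False)
    return directory


def read_tileset(directory: "str | Path",
                 sample: Optional[str] = None) -> TileSet:
    """Read a tile set written by :func:`write_tileset`.

    A missing tile file raises a descriptive error naming the (row, col,
    channel); inconsistent stack shapes across tiles raise a format error.
    """
    directory = Path(directory)
    if sample is None:
        layouts = sorted(directory.glob("*_layout.json"))
        if not layouts:
            raise FileNotFoundError(f"no *_layout.json found in {directory}")
        sample = layouts[0].name[: -len("_layout.json")]
    meta = json.loads((directory / f"{sample}_layout.json").read_text())
    layout = layout_tiles(
        meta["grid_rows"], meta["grid_cols"],
        tuple(meta["tile_shape_px"]), meta["overlap_fraction"])
    tiles: Dict[Tuple[int, int], Dict[str, np.ndarray]] = {}
    shape = None
    for r in range(meta["grid_rows"]):
        for c in range(meta["grid_cols"]):
            tiles[(r, c)] = {}
            for ch in meta["channels"]:
                path = directory / tile_filename(sample, r, c, ch)
                if not path.exists():
                    raise FileNotFoundError(
                        f"missing tile stack for row={r}, col={c}, "
                        f"channel={ch!r}: {path.name}")
                stack = tifffile.imread(path)
                if stack.ndim == 2:  # single page
                    stack = stack[None, ...]
                if shape is None:
                    shape = stack.shape
                elif stack.shape != shape:
                    raise ValueError(
                        f"tile {path.name} has shape {stack.shape}, "
                        f"expected {shape}")
                tiles[(r, c)][ch] = np.asarray(stack, dtype=np.float64)
    truth = None
    truth_path = directory / f"{sample}_truth.csv"
    if truth_path.exists():
        df = pd.read_csv(truth_path)
        truth = GroundTruth(
            beads=df[["x_um", "y_um", "z_um"]].to_numpy(dtype=np.float64),
            clump_id=df["clump_id"].to_numpy(dtype=np.int64),
        )
    return TileSet(
        tiles=tiles,
        layout=layout,
        pixel_size_um=meta["pixel_size_um"],
        z_step_um=meta["z_step_um"],
        channels=tuple(meta["channels"]),
        sample=sample,
        truth=truth,
    )


_DETECTION_COLUMNS = ["sample", "row", "col", "x_px", "y_px", "x_um", "y_um",
                      "peak", "eq_diam_um", "z_best", "clump_flag"]


def write_detections(detections: Sequence[Detection], path: "str | Path",
                     sample: str = "sample") -> Path:
    rows = [
        {
            "sample": sample,
            "row": det.tile_index[0],
            "col": det.tile_index[1],
            "x_px": det.x_px,
            "y_px": det.y_px,
            "x_um": det.x_um,
            "y_um": det.y_um,
            "peak": det.peak_intensity,
            "eq_diam_um": det.equivalent_diameter_um,
            "z_best": det.z_best,
            "clump_flag": det.clump_flag,
        }
        for det in detections
    ]
    pd.DataFrame(rows, columns=_DETECTION_COLUMNS).to_csv(path, index=False)
    return Path(path)


def read_detections(path: "str | Path") -> List[Detection]:
    df = pd.read_csv(path)
    out = []
    for _, row in df.iterrows():
        out.append(Detection(
            tile_index=(int(row["row"]), int(row["col"])),
            x_px=float(row["x_px"]),
            y_px=float(row["y_px"]),
            peak_intensity=float(row["peak"]),
            equivalent_diameter_um=float(row["eq_diam_um"]),
            x_um=None if pd.isna(row["x_um"]) else float(row["x_um"]),
            y_um=None if pd.isna(row["y_um"]) else float(row["y_um"]),
            z_best=None if pd.isna(row["z_best"]) else int(row["z_best"]),
            clump_flag=bool(row["clump_flag"]),
        ))
    return out


def write_counts(counts: pd.DataFrame, path: "str | Path") -> Path:
    """Write a (group, animal, count) table."""
    counts.to_csv(path, index=False)
    return Path(path)


def read_counts(path: "str | Path") -> pd.DataFrame:
    return pd.read_csv(path)


def write_report(results: dict, path: "str | Path") -> Path:
    """Write a machine-readable JSON report plus a text summary.

    If ``results`` contains a ``"counts"`` mapping of group label to a list
    of per-animal counts, per-group n/mean/SEM are derived into a
    ``"groups"`` section.  Output ordering is stable, so re-running on the
    same inputs yields byte-identical files.
    """
    path = Path(path)
    report = dict(results)
    counts = report.get("counts", {})
    groups = {}
    for label in sorted(counts):
        values = counts[label]
        frame = pd.DataFrame({
            "group_label": label,
            "animal_id": [f"{label}_{i + 1}" for i in range(len(values))],
            "bead_count": values,
        })
        if len(values):
            row = group_summary(frame).loc[label]
            groups[label] = {"n": int(row["n"]), "mean": float(row["mean"]),
                             "sem": float(row["sem"])}
        else:
            groups[label] = {"n": 0, "mean": None, "sem": None}
    report["groups"] = groups
    path.write_text(json.dumps(report, indent=2, sort_keys=True,
                               default=_json_default) + "\n")
    lines = ["bead count report", "================="]
    for label in sorted(groups):
        g = groups[label]
        if g["n"]:
            lines.append(f"{label}: n={g['n']} mean={g['mean']:.3f} "
                         f"sem={g['sem']:.3f}")
        else:
            lines.append(f"{label}: no samples")
    for key in sorted(report):
        if key in ("counts", "groups"):
            continue
        lines.append(f"{key}: {report[key]}")
    path.with_suffix(".txt").write_text("\n".join(lines) + "\n")
    return path


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")
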
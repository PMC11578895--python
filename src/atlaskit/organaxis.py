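"""Hex-grid tissue annotation and continuous axis construction.

A manually annotated label raster (integer labels over pixels, 0 =
background) is migrated onto a high-resolution hexagonal spot grid (15 µm
spot diameter, 15 µm centre-to-centre spacing, no gaps) by taking the
median pixel label inside a small disc (spot radius / 4) at each spot
centre.  Per spot and per annotated structure, distance features are then
computed from the structure's annotated pixels: the mean Euclidean
distance to the ten nearest structure pixels for coarse (level 0)
structures, and the nearest-pixel distance for fine (level 1) structures.
Features migrate to Visium spots by nearest-grid-point proximity, and a
continuous axis between two structures is d_origin / (d_origin +
d_target), 0 on the origin and 1 on the target.

Raster convention: origin top-left, x to the right (columns), y down
(rows); the centre of pixel (row j, col i) sits at ((i + 0.5), (j + 0.5))
* pixel_size in µm.
"""
from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from PIL import Image
from scipy.spatial import cKDTree

from .netcore import IntegrityError

logger = logging.getLogger(__name__)

DEFAULT_SPOT_DIAMETER_UM = 15.0
DEFAULT_SPOT_SPACING_UM = 15.0
LEVEL0_N_POINTS = 10


@dataclass(frozen=True)
class StructureDef:
    name: str
    level: int

    def __post_init__(self) -> None:
        if self.level not in (0, 1):
            raise ValueError("structure level must be 0 or 1")


@dataclass
class LabelImage:
    """2-D integer label raster with physical pixel size and a legend."""

    pixels: np.ndarray
    pixel_size_um: float
    legend: dict[int, StructureDef]

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("label image must be 2-D")
        if not np.issubdtype(self.pixels.dtype, np.integer):
            raise ValueError("label image must be integer-valued")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel size must be > 0")
        present = set(np.unique(self.pixels)) - {0}
        uncovered = present - set(self.legend)
        if uncovered:
            raise ValueError(f"legend does not cover label value(s) {sorted(uncovered)}")

    def structure_label(self, name: str) -> int:
        for value, sdef in self.legend.items():
            if sdef.name == name:
                return value
        raise KeyError(f"no structure named {name!r} in legend")

    def structure_points_um(self, name: str) -> np.ndarray:
        """(x, y) µm centres of the pixels annotated with a structure."""
        value = self.structure_label(name)
        rows, cols = np.nonzero(self.pixels == value)
        if rows.size == 0:
            raise ValueError(f"structure {name!r} has no annotated pixel in the image")
        return np.column_stack(((cols + 0.5), (rows + 0.5))) * self.pixel_size_um


def read_label_image(
    image_path: str | Path, legend_path: str | Path, pixel_size_um: float
) -> LabelImage:
    """Load a single-channel PNG/TIFF and its JSON legend
    ({"<value>": {"name": ..., "level": 0|1}})."""
    arr = np.asarray(Image.open(image_path)).astype(np.int64)
    if arr.ndim == 3:
        arr = arr[..., 0]
    raw = json.loads(Path(legend_path).read_text())
    legend = {int(v): StructureDef(d["name"], int(d["level"])) for v, d in raw.items()}
    return LabelImage(arr, pixel_size_um, legend)


def write_label_image(img: LabelImage, image_path: str | Path, legend_path: str | Path) -> None:
    if img.pixels.max() > 255 or img.pixels.min() < 0:
        raise ValueError("PNG export supports labels in 0..255")
    Image.fromarray(img.pixels.astype(np.uint8), mode="L").save(image_path)
    doc = {str(v): {"name": s.name, "level": s.level} for v, s in img.legend.items()}
    Path(legend_path).write_text(json.dumps(doc, indent=1))


# ---------------------------------------------------------------------------
# hex grid


@dataclass
class HexGrid:
    """Hexagonal spot lattice in µm; rows run along x, alternate rows are
    offset by spacing/2 and rows are spacing*sqrt(3)/2 apart, so every
    nearest-neighbour centre distance equals the spacing exactly."""

    centers: np.ndarray
    diameter_um: float = DEFAULT_SPOT_DIAMETER_UM
    spacing_um: float = DEFAULT_SPOT_SPACING_UM

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=float)
        if self.centers.ndim != 2 or self.centers.shape[1] != 2:
            raise ValueError("centers must be an (n, 2) array of x, y in µm")

    def __len__(self) -> int:
        return len(self.centers)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.centers, columns=["x_um", "y_um"]).rename_axis("spot")


def build_hex_grid(
    bounds: tuple[float, float, float, float],
    diameter: float = DEFAULT_SPOT_DIAMETER_UM,
    spacing: float = DEFAULT_SPOT_SPACING_UM,
) -> HexGrid:
    """Fill (xmin, ymin, xmax, ymax) with a hex lattice of spot centres."""
    xmin, ymin, xmax, ymax = map(float, bounds)
    if not (xmax > xmin and ymax > ymin):
        raise ValueError(f"degenerate bounds {bounds}")
    if diameter <= 0 or spacing <= 0:
        raise ValueError("diameter and spacing must be > 0")
    pitch = spacing * math.sqrt(3.0) / 2.0
    centers = []
    row = 0
    y = ymin
    while y <= ymax + 1e-9:
        x = xmin + (spacing / 2.0 if row % 2 else 0.0)
        while x <= xmax + 1e-9:
            centers.append((x, y))
            x += spacing
        row += 1
        y = ymin + row * pitch
    if not centers:
        raise ValueError(f"bounds {bounds} admit no grid point")
    return HexGrid(np.asarray(centers), diameter, spacing)


# ---------------------------------------------------------------------------
# label migration


def _lower_median(values: np.ndarray) -> int:
    """Median of sorted integers; even count takes the lower middle, so the
    result is always an actually-occurring label."""
    v = np.sort(values)
    return int(v[(len(v) - 1) // 2])


def migrate_labels(img: LabelImage, grid: HexGrid) -> np.ndarray:
    """Per spot, the median label of the pixels within radius/4 of the
    centre (background 0 included); spots outside the image are 0, and a
    disc too small to catch any pixel centre falls back to the nearest
    pixel with a warning."""
    ps = img.pixel_size_um
    radius = (grid.diameter_um / 2.0) / 4.0
    h, w = img.pixels.shape
    # candidate pixel offsets around the spot's containing pixel
    reach = int(math.ceil(radius / ps)) + 1
    offs = np.arange(-reach, reach + 1)
    oj, oi = np.meshgrid(offs, offs, indexing="ij")
    oj, oi = oj.ravel(), oi.ravel()

    labels = np.zeros(len(grid), dtype=np.int64)
    warned_empty = False
    for s, (x, y) in enumerate(grid.centers):
        ci = int(math.floor(x / ps))
        cj = int(math.floor(y / ps))
        if not (0 <= ci < w and 0 <= cj < h):
            labels[s] = 0
            continue
        jj = cj + oj
        ii = ci + oi
        inb = (jj >= 0) & (jj < h) & (ii >= 0) & (ii < w)
        jj, ii = jj[inb], ii[inb]
        px = (ii + 0.5) * ps
        py = (jj + 0.5) * ps
        within = (px - x) ** 2 + (py - y) ** 2 <= radius**2 + 1e-12
        if within.any():
            labels[s] = _lower_median(img.pixels[jj[within], ii[within]])
        else:
            if not warned_empty:
                logger.warning(
                    "sampling disc (radius %.3g µm) smaller than a pixel; "
                    "falling back to nearest pixel",
                    radius,
                )
                warned_empty = True
            d2 = (px - x) ** 2 + (py - y) ** 2
            j = int(np.argmin(d2))
            labels[s] = int(img.pixels[jj[j], ii[j]])
    return labels


# ---------------------------------------------------------------------------
# distance features


def structure_distances(
    grid: HexGrid,
    img: LabelImage,
    level: int,
    rule: str | None = None,
) -> pd.DataFrame:
    """Per-spot distances to every structure of a given annotation level.

    level 0 structures use the mean of the ten nearest annotated-pixel
    distances (all pixels when fewer than ten); level 1 structures use
    the single nearest distance.  ``rule`` ("mean10" or "nearest")
    overrides the level's default.  Distances are in µm; a spot sitting on
    a structure pixel has nearest distance 0.
    """
    if rule is None:
        rule = "mean10" if level == 0 else "nearest"
    if rule not in ("mean10", "nearest"):
        raise ValueError("rule must be 'mean10' or 'nearest'")
    structures = [s.name for s in img.legend.values() if s.level == level]
    if not structures:
        raise ValueError(f"no structures at level {level} in legend")
    out = {}
    for name in structures:
        pts = img.structure_points_um(name)  # raises if absent
        tree = cKDTree(pts)
        if rule == "nearest":
            d, _ = tree.query(grid.centers, k=1)
            out[name] = np.asarray(d, dtype=float)
        else:
            k = min(LEVEL0_N_POINTS, len(pts))
            d, _ = tree.query(grid.centers, k=k)
            d = np.atleast_2d(np.asarray(d, dtype=float))
            if d.shape[0] != len(grid):
                d = d.T
            out[name] = d.mean(axis=1)
    return pd.DataFrame(out).rename_axis("spot")


@dataclass
class SpotAnnotation:
    """Everything computed on the high-resolution grid for one scene."""

    grid: HexGrid
    labels: np.ndarray
    dist_level0: pd.DataFrame | None = None
    dist_level1: pd.DataFrame | None = None
    axis: np.ndarray | None = None

    def label_names(self, img: LabelImage) -> list[str]:
        names = {0: "background"}
        names.update({v: s.name for v, s in img.legend.items()})
        return [names[int(l)] for l in self.labels]

    def to_frame(self) -> pd.DataFrame:
        df = self.grid.to_frame()
        df["label"] = self.labels
        for block, prefix in ((self.dist_level0, "d0"), (self.dist_level1, "d1")):
            if block is not None:
                for col in block.columns:
                    df[f"{prefix}_{col}"] = block[col].to_numpy()
        if self.axis is not None:
            df["axis"] = self.axis
        return df


def annotate_grid(img: LabelImage, grid: HexGrid | None = None) -> SpotAnnotation:
    """Convenience: build/accept a grid over the image, migrate labels and
    compute all available distance features."""
    if grid is None:
        h, w = img.pixels.shape
        grid = build_hex_grid((0.0, 0.0, w * img.pixel_size_um, h * img.pixel_size_um))
    labels = migrate_labels(img, grid)
    levels_present = {s.level for s in img.legend.values()}
    d0 = structure_distances(grid, img, 0) if 0 in levels_present else None
    d1 = structure_distances(grid, img, 1) if 1 in levels_present else None
    return SpotAnnotation(grid, labels, d0, d1)


# ---------------------------------------------------------------------------
# axis + Visium mapping


def compute_axis(
    spotann: SpotAnnotation, origin_structure: str, target_structure: str
) -> np.ndarray:
    """Continuous axis between two structures: d_o / (d_o + d_t) in [0, 1].

    Uses the level-1 nearest-point distances (falling back to level-0
    features when a structure only exists there).  A spot on the origin
    gets 0, on the target 1; a spot on both (degenerate overlap of the
    sampled pixels) gets 0.5 with a warning.
    """

    def col(name: str) -> np.ndarray:
        for block in (spotann.dist_level1, spotann.dist_level0):
            if block is not None and name in block.columns:
                return block[name].to_numpy(dtype=float)
        raise IntegrityError(f"no distances computed for structure {name!r}")

    d_o = col(origin_structure)
    d_t = col(target_structure)
    both_zero = (d_o == 0) & (d_t == 0)
    if both_zero.any():
        logger.warning("%d spot(s) at distance 0 from both structures; axis 0.5", int(both_zero.sum()))
    denom = d_o + d_t
    axis = np.where(both_zero, 0.5, d_o / np.where(denom > 0, denom, 1.0))
    spotann.axis = axis
    return axis


def map_to_visium(
    spotann: SpotAnnotation,
    visium_coords: pd.DataFrame,
    max_dist: float = DEFAULT_SPOT_SPACING_UM,
) -> pd.DataFrame:
    """Transfer grid annotations to Visium spots by nearest grid point.

    ``visium_coords`` needs columns barcode, x_um, y_um in the same µm
    frame as the grid.  Spots farther than ``max_dist`` from every grid
    point stay unannotated (NaN/empty label).
    """
    if len(spotann.grid) == 0:
        raise ValueError("empty annotation grid")
    for colname in ("barcode", "x_um", "y_um"):
        if colname not in visium_coords.columns:
            raise ValueError(f"visium coordinates require column {colname!r}")
    tree = cKDTree(spotann.grid.centers)
    pts = visium_coords[["x_um", "y_um"]].to_numpy(dtype=float)
    d, idx = tree.query(pts, k=1)
    ok = d <= max_dist

    grid_df = spotann.to_frame().reset_index(drop=True)
    out = pd.DataFrame({"barcode": visium_coords["barcode"].to_numpy()})
    out["grid_distance_um"] = d
    out["annotated"] = ok
    for colname in grid_df.columns:
        vals = grid_df[colname].to_numpy()[idx]
        if colname == "label":
            col_out = np.where(ok, vals, 0)
        else:
            col_out = np.where(ok, vals, np.nan)
        out[colname] = col_out
    return out.set_index("barcode")
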
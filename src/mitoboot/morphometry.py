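"""Per-object shape metrics for segmented mitochondria and per-tile aggregation.

The unit of analysis is a 100 um^2 image tile containing integer-labelled
mitochondrial objects (0 = background).  For each object we compute area,
maximum Feret (caliper) diameter, the axes of the moment-equivalent ellipse,
the aspect ratio (short/long, so 1 = perfectly round), and the Euclidean
distance to the nearest neighbouring object within the same tile.

Conventions
-----------
* Pixel indices are 0-based; the centre of pixel ``(i, j)`` sits at
  ``((j + 0.5) * pixel_size, (i + 0.5) * pixel_size)`` in (x, y) microns,
  with x along columns and y along rows.
* The moment-equivalent ellipse is derived from the second central moments
  of the pixel coordinates with the standard "pixel as unit square"
  correction (+1/12 px^2 on each diagonal term), so a solid axis-aligned
  w x h rectangle has aspect ratio exactly min(w, h) / max(w, h).
* The Feret diameter is the maximum pairwise distance between pixel
  *centres*, computed on the convex hull of the object (not extended to
  pixel corners).
* Nearest-neighbour distances are computed between object centroids within
  a tile only; neighbours in adjacent tiles are ignored.
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError, cKDTree
from scipy.spatial.distance import pdist
from skimage.measure import regionprops

__all__ = [
    "MitoObject",
    "TileRecord",
    "SizeFilter",
    "compute_object_metrics",
    "filter_objects",
    "nearest_neighbor_distances",
    "aggregate_tile",
    "normalize_to_control",
    "objects_to_frame",
    "frame_to_objects",
]


@dataclass
class MitoObject:
    """A single segmented mitochondrion with geometry metrics (all in um)."""

    object_id: object
    tile_id: object
    centroid_x: float
    centroid_y: float
    area: float
    feret_diameter: float
    short_axis: float
    long_axis: float
    aspect_ratio: float
    nn_distance: float | None = None

    def __post_init__(self) -> None:
        if self.area <= 0:
            raise ValueError(f"object {self.object_id}: area must be > 0")
        if not (0 < self.short_axis <= self.long_axis):
            raise ValueError(
                f"object {self.object_id}: need 0 < short_axis <= long_axis"
            )
        if not (0 < self.aspect_ratio <= 1 + 1e-12):
            raise ValueError(f"object {self.object_id}: aspect_ratio not in (0, 1]")
        if self.feret_diameter < 0:
            raise ValueError(f"object {self.object_id}: feret_diameter < 0")
        if self.nn_distance is not None and self.nn_distance < 0:
            raise ValueError(f"object {self.object_id}: nn_distance < 0")


@dataclass
class TileRecord:
    """Per-tile aggregate: nesting keys plus count and total object area."""

    tile_id: object
    section_id: object
    animal_id: object
    genotype: str
    layer: str
    mito_count: int
    total_mito_area: float
    tile_area: float = 100.0

    def __post_init__(self) -> None:
        if self.mito_count < 0:
            raise ValueError("mito_count must be non-negative")
        if self.total_mito_area < 0:
            raise ValueError("total_mito_area must be non-negative")
        if self.total_mito_area > self.tile_area + 1e-9:
            raise ValueError(
                f"tile {self.tile_id}: total mitochondrial area "
                f"{self.total_mito_area:.3f} exceeds tile area {self.tile_area}"
            )


@dataclass(frozen=True)
class SizeFilter:
    """Inclusive area filter in um^2; defaults retain objects in [0.01, 2.1]."""

    min_area: float = 0.01
    max_area: float = 2.1

    def __post_init__(self) -> None:
        if not (0 < self.min_area < self.max_area):
            raise ValueError("require 0 < min_area < max_area")


def _moment_axes(coords: np.ndarray) -> tuple[float, float]:
    """Full lengths (long, short) of the moment-equivalent ellipse in pixels.

    Uses the covariance of pixel centres plus the 1/12 px^2 per-pixel
    correction, then the usual 4*sqrt(eigenvalue) conversion.
    """
    if len(coords) == 1:
        cov = np.zeros((2, 2))
    else:
        cov = np.cov(coords.T.astype(float), ddof=0)
    cov = cov + np.eye(2) / 12.0
    evals = np.linalg.eigvalsh(cov)
    evals = np.clip(evals, 0.0, None)
    short, long = 4.0 * np.sqrt(evals)
    return float(long), float(short)


def _feret_px(coords: np.ndarray) -> float:
    """Max pairwise distance between pixel centres (pixels); 0 for 1 pixel."""
    if len(coords) < 2:
        return 0.0
    pts = coords.astype(float)
    if len(pts) > 3:
        try:
            hull = ConvexHull(pts)
            pts = pts[hull.vertices]
        except QhullError:
            # degenerate (collinear) object: fall back to all points
            pass
    return float(pdist(pts).max())


def compute_object_metrics(
    label_mask: np.ndarray, pixel_size: float, tile_id: object = "tile"
) -> list[MitoObject]:
    """Compute geometry metrics for every labelled object in a mask.

    Parameters
    ----------
    label_mask
        2D array of non-negative integers; 0 is background, each positive
        label is one object (labels need not be consecutive).
    pixel_size
        Side length of one pixel in microns.
    tile_id
        Identifier copied onto every returned object.

    Returns
    -------
    list of MitoObject, one per distinct non-zero label, sorted by label.
    """
    mask = np.asarray(label_mask)
    if mask.ndim != 2:
        raise ValueError("label_mask must be 2D")
    if not np.issubdtype(mask.dtype, np.integer):
        raise TypeError("label_mask must be an integer raster (0 = background)")
    if mask.size and mask.min() < 0:
        raise ValueError("label_mask must be non-negative")
    if pixel_size <= 0:
        raise ValueError("pixel_size must be > 0")

    objects: list[MitoObject] = []
    for region in regionprops(mask):
        coords = region.coords  # (n, 2) array of (row, col)
        long_px, short_px = _moment_axes(coords)
        centroid_row, centroid_col = coords.mean(axis=0)
        objects.append(
            MitoObject(
                object_id=int(region.label),
                tile_id=tile_id,
                centroid_x=(centroid_col + 0.5) * pixel_size,
                centroid_y=(centroid_row + 0.5) * pixel_size,
                area=len(coords) * pixel_size**2,
                feret_diameter=_feret_px(coords) * pixel_size,
                short_axis=short_px * pixel_size,
                long_axis=long_px * pixel_size,
                aspect_ratio=short_px / long_px,
            )
        )
    return objects


def filter_objects(
    objects: Iterable[MitoObject], size_filter: SizeFilter = SizeFilter()
) -> list[MitoObject]:
    """Retain objects with min_area <= area <= max_area (boundaries kept)."""
    return [o for o in objects if size_filter.min_area <= o.area <= size_filter.max_area]


def nearest_neighbor_distances(objects: Sequence[MitoObject]) -> list[MitoObject]:
    """Set ``nn_distance`` on each object: min centroid distance within its tile.

    Objects alone in their tile get ``nn_distance = None`` and a warning;
    they are excluded from nearest-neighbour statistics downstream.
    """
    by_tile: dict[object, list[MitoObject]] = defaultdict(list)
    for obj in objects:
        by_tile[obj.tile_id].append(obj)
    for tile_id, group in by_tile.items():
        if len(group) == 1:
            warnings.warn(
                f"tile {tile_id!r} has a single object; nn_distance left unset",
                stacklevel=2,
            )
            group[0].nn_distance = None
            continue
        pts = np.array([[o.centroid_x, o.centroid_y] for o in group])
        tree = cKDTree(pts)
        dists, _ = tree.query(pts, k=2)
        for obj, d in zip(group, dists[:, 1]):
            obj.nn_distance = float(d)
    return list(objects)


def aggregate_tile(
    objects: Sequence[MitoObject],
    tile_id: object,
    *,
    section_id: object,
    animal_id: object,
    genotype: str,
    layer: str,
    tile_area: float = 100.0,
) -> TileRecord:
    """Sum count and total area over a tile's (already filtered) objects."""
    for obj in objects:
        if obj.tile_id != tile_id:
            raise ValueError(
                f"object {obj.object_id} belongs to tile {obj.tile_id!r}, "
                f"not {tile_id!r}"
            )
    return TileRecord(
        tile_id=tile_id,
        section_id=section_id,
        animal_id=animal_id,
        genotype=genotype,
        layer=layer,
        mito_count=len(objects),
        total_mito_area=float(sum(o.area for o in objects)),
        tile_area=tile_area,
    )


def normalize_to_control(values, control_values) -> np.ndarray:
    """Divide ``values`` by the pooled mean of the control series."""
    control = np.asarray(control_values, dtype=float)
    if control.size == 0:
        raise ValueError("control series is empty")
    mean = control.mean()
    if not np.isfinite(mean) or mean <= 0:
        raise ValueError(f"control mean must be positive, got {mean}")
    return np.asarray(values, dtype=float) / mean


_OBJECT_COLUMNS = [
    "object_id",
    "tile_id",
    "centroid_x_um",
    "centroid_y_um",
    "area_um2",
    "short_axis_um",
    "long_axis_um",
    "feret_um",
    "aspect_ratio",
    "nn_dist_um",
]


def objects_to_frame(objects: Iterable[MitoObject]) -> pd.DataFrame:
    """Flatten MitoObjects into the canonical per-object table."""
    rows = [
        {
            "object_id": o.object_id,
            "tile_id": o.tile_id,
            "centroid_x_um": o.centroid_x,
            "centroid_y_um": o.centroid_y,
            "area_um2": o.area,
            "short_axis_um": o.short_axis,
            "long_axis_um": o.long_axis,
            "feret_um": o.feret_diameter,
            "aspect_ratio": o.aspect_ratio,
            "nn_dist_um": o.nn_distance,
        }
        for o in objects
    ]
    return pd.DataFrame(rows, columns=_OBJECT_COLUMNS)


def frame_to_objects(frame: pd.DataFrame) -> list[MitoObject]:
    """Rebuild MitoObjects from a per-object table (inverse of objects_to_frame).

    ``feret_um``, ``aspect_ratio`` and ``nn_dist_um`` are optional; the
    aspect ratio is recomputed from the axes when absent.
    """
    objects = []
    for row in frame.itertuples(index=False):
        short = float(row.short_axis_um)
        long = float(row.long_axis_um)
        aspect = float(getattr(row, "aspect_ratio", short / long))
        nn = getattr(row, "nn_dist_um", None)
        nn = None if nn is None or (isinstance(nn, float) and np.isnan(nn)) else float(nn)
        objects.append(
            MitoObject(
                object_id=row.object_id,
                tile_id=row.tile_id,
                centroid_x=float(row.centroid_x_um),
                centroid_y=float(row.centroid_y_um),
                area=float(row.area_um2),
                feret_diameter=float(getattr(row, "feret_um", long)),
                short_axis=short,
                long_axis=long,
                aspect_ratio=aspect,
                nn_distance=nn,
            )
        )
    return objects
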
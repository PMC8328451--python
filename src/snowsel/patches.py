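"""Snow-free patch delineation, exclusion masking and patch statistics.

A coarse cell is declared snow-free when its snow-free fraction meets a
threshold scenario (80/50/30% by default); contiguous snow-free cells form
patches (8-connectivity by default, so diagonally touching ridge crests join).
Patch statistics follow the field's descriptors: size distribution and
edge-to-edge nearest-neighbor distances, plus a Euclidean
distance-to-snow-free surface used as the DIST predictor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree
from shapely.geometry import shape as shapely_shape
from shapely.geometry.base import BaseGeometry
from skimage import measure

from .grid import Grid

DEFAULT_THRESHOLDS = (0.8, 0.5, 0.3)


@dataclass
class PatchSet:
    """Labeled snow-free patches on a coarse grid.

    ``labels`` holds an integer per cell (0 = background, patches numbered
    contiguously 1..n); ``table`` has one row per patch with pixel count,
    area (m^2), centroid (map units) and nearest-neighbor edge-to-edge
    distance (m; NaN when fewer than two patches exist).
    """

    labels: Grid
    table: pd.DataFrame = field(default_factory=pd.DataFrame)
    connectivity: int = 8
    excluded_area_pct: float = 0.0

    @property
    def n_patches(self) -> int:
        return len(self.table)

    @property
    def total_area(self) -> float:
        return float(self.table["area_m2"].sum()) if self.n_patches else 0.0


def threshold_mask(frac: Grid, t: float) -> Grid:
    """Binary snow-free mask: 1 where the snow-free fraction is >= t.

    The threshold is inclusive ("50% or more" keeps a cell at exactly 0.5).
    Nodata cells map to 0 (not snow-free).
    """
    if not 0.0 < t <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    v = frac.values
    out = np.where(np.isfinite(v) & (v >= t), 1.0, 0.0)
    return frac.like(out)


def _nn_edge_distances(labels: np.ndarray, cell: float) -> np.ndarray:
    """Nearest-neighbor edge-to-edge distance per patch (labels 1..n).

    Distance between two axis-aligned square cells' boundaries is
    ``hypot(max(|dx|-cell, 0), max(|dy|-cell, 0))`` for center offsets
    (dx, dy); the patch-to-patch distance is the minimum over cell pairs.
    Adjacent (even diagonally touching) cells of distinct patches are 0 m
    apart.
    """
    n = labels.max()
    rows, cols = np.nonzero(labels)
    lab = labels[rows, cols]
    pts = np.column_stack([cols, rows]).astype(float) * cell
    tree = cKDTree(pts)
    out = np.full(n, np.inf)
    for p in range(1, n + 1):
        own = lab == p
        own_pts = pts[own]
        other_pts = pts[~own]
        other_tree = cKDTree(other_pts) if len(other_pts) else None
        if other_tree is None:
            continue
        # center-to-center NN gives candidates; edge distance needs the
        # component-wise slack, so check a neighborhood of candidates
        d_c2c, idx = other_tree.query(own_pts, k=min(32, len(other_pts)))
        d_c2c = np.atleast_2d(d_c2c)
        idx = np.atleast_2d(idx)
        cand = other_pts[idx]  # (m, k, 2)
        dd = np.abs(cand - own_pts[:, None, :])
        edge = np.hypot(
            np.maximum(dd[..., 0] - cell, 0.0), np.maximum(dd[..., 1] - cell, 0.0)
        )
        out[p - 1] = edge.min()
    out[np.isinf(out)] = np.nan
    return out


def _build_table(labels: np.ndarray, grid: Grid) -> pd.DataFrame:
    cell = grid.cell
    props = measure.regionprops(labels)
    recs = []
    for pr in props:
        r, c = pr.centroid
        recs.append(
            {
                "patch_id": pr.label,
                "n_cells": pr.num_pixels,
                "area_m2": pr.num_pixels * cell**2,
                "centroid_x": grid.origin_x + (c + 0.5) * cell,
                "centroid_y": grid.origin_y - (r + 0.5) * cell,
            }
        )
    table = pd.DataFrame(
        recs, columns=["patch_id", "n_cells", "area_m2", "centroid_x", "centroid_y"]
    )
    if len(table) >= 2:
        table["nn_dist_m"] = _nn_edge_distances(labels, cell)
    else:
        table["nn_dist_m"] = np.nan
    return table


def label_patches(mask: Grid, connectivity: int = 8) -> PatchSet:
    """Connected-component patches from a binary snow-free mask."""
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    binary = np.nan_to_num(mask.values) > 0
    labels = measure.label(binary, connectivity=1 if connectivity == 4 else 2)
    return PatchSet(
        labels=mask.like(labels.astype(float)),
        table=_build_table(labels, mask),
        connectivity=connectivity,
    )


def apply_exclusions(ps: PatchSet, masks: list[BaseGeometry | dict]) -> PatchSet:
    """Remove patch cells intersecting any exclusion polygon and relabel.

    Polygons (shapely geometries or GeoJSON geometry dicts) are in map units.
    The returned PatchSet reports the excluded percentage of the original
    snow-free patch area.
    """
    geoms = []
    for m in masks:
        g = shapely_shape(m) if isinstance(m, dict) else m
        if not g.is_valid:
            raise ValueError("invalid exclusion polygon")
        geoms.append(g)
    grid = ps.labels
    lab = grid.values.astype(int)
    before = int((lab > 0).sum())
    if geoms and before:
        import shapely

        rows, cols = np.nonzero(lab)
        half = grid.cell / 2.0
        cx = grid.origin_x + (cols + 0.5) * grid.cell
        cy = grid.origin_y - (rows + 0.5) * grid.cell
        boxes = shapely.box(cx - half, cy - half, cx + half, cy + half)
        hit = np.zeros(len(boxes), dtype=bool)
        for g in geoms:
            hit |= shapely.intersects(g, boxes)
        lab = lab.copy()
        lab[rows[hit], cols[hit]] = 0
    binary = lab > 0
    relabeled = measure.label(binary, connectivity=1 if ps.connectivity == 4 else 2)
    after = int((relabeled > 0).sum())
    pct = 100.0 * (before - after) / before if before else 0.0
    return PatchSet(
        labels=grid.like(relabeled.astype(float)),
        table=_build_table(relabeled, grid),
        connectivity=ps.connectivity,
        excluded_area_pct=pct,
    )


def patch_stats(ps: PatchSet) -> dict:
    """Summary of patch sizes and between-patch distances.

    Reports the area distribution (median and quartiles), nearest-neighbor
    edge-to-edge distances, and the fraction of patches whose nearest
    neighbor is within 100 m.  With fewer than two patches the distance
    summary is flagged undefined.
    """
    t = ps.table
    out: dict = {"n_patches": ps.n_patches, "total_area_m2": ps.total_area}
    if ps.n_patches:
        a = t["area_m2"].to_numpy()
        out["area_median_m2"] = float(np.median(a))
        out["area_q25_m2"], out["area_q75_m2"] = (
            float(np.percentile(a, 25)),
            float(np.percentile(a, 75)),
        )
    if ps.n_patches >= 2:
        d = t["nn_dist_m"].to_numpy()
        out["nn_dist_median_m"] = float(np.median(d))
        out["nn_dist_frac_le_100m"] = float((d <= 100.0).mean())
        out["distances_defined"] = True
    else:
        out["distances_defined"] = False
    return out


def distance_to_snowfree(mask: Grid, min_patch_area: float = 0.0,
                         connectivity: int = 8) -> Grid:
    """Euclidean distance (m) to the nearest qualifying snow-free cell.

    Patches smaller than ``min_patch_area`` (m^2) are dropped before the
    transform, so e.g. a 1,800 m^2 floor keeps only median-sized-or-larger
    patches as targets.  Qualifying cells get 0; if none qualify the result
    is all nodata.
    """
    binary = np.nan_to_num(mask.values) > 0
    if min_patch_area > 0:
        lab = measure.label(binary, connectivity=1 if connectivity == 4 else 2)
        min_cells = int(np.ceil(min_patch_area / mask.cell**2))
        counts = np.bincount(lab.ravel())
        keep = counts >= min_cells
        keep[0] = False
        binary = keep[lab]
    if not binary.any():
        return mask.like(np.full(mask.shape, np.nan))
    dist = ndimage.distance_transform_edt(~binary, sampling=mask.cell)
    return mask.like(dist)
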
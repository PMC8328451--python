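"""File formats: ASCII grids, track CSVs, GeoJSON patches/masks, JSON reports.

Rasters travel as headered ESRI ASCII grids (ncols/nrows/xllcorner/yllcorner/
cellsize/NODATA_value, row-major from the north edge) — a plain-text format
every GIS reads.  Tracks are CSVs with columns ``animal_id, timestamp, x, y``
(ISO-8601 UTC timestamps).  Patch sets are exported as a polygonized GeoJSON
FeatureCollection plus a CSV attribute table.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import mapping, shape as shapely_shape

from .grid import Grid
from .patches import PatchSet
from .tracks import Track, tracks_from_frame, tracks_to_frame

TRACK_COLUMNS = ["animal_id", "timestamp", "x", "y"]


# -- grids --------------------------------------------------------------------


def write_ascii_grid(grid: Grid, path: str | Path) -> None:
    path = Path(path)
    xll = grid.origin_x
    yll = grid.origin_y - grid.nrows * grid.cell
    vals = np.where(np.isfinite(grid.values), grid.values, grid.nodata)
    header = (
        f"ncols {grid.ncols}\n"
        f"nrows {grid.nrows}\n"
        f"xllcorner {xll!r}\n"
        f"yllcorner {yll!r}\n"
        f"cellsize {grid.cell!r}\n"
        f"NODATA_value {grid.nodata!r}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, vals, fmt="%.10g")


def read_ascii_grid(path: str | Path) -> Grid:
    path = Path(path)
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        values = np.loadtxt(fh, ndmin=2)
    nodata = header.get("nodata_value", -9999.0)
    values = np.where(values == nodata, np.nan, values)
    nrows, ncols = values.shape
    if nrows != int(header["nrows"]) or ncols != int(header["ncols"]):
        raise ValueError(f"{path}: grid body does not match header dimensions")
    cell = header["cellsize"]
    return Grid(
        values,
        origin_x=header["xllcorner"],
        origin_y=header["yllcorner"] + nrows * cell,
        cell=cell,
        nodata=nodata,
    )


# -- tracks -------------------------------------------------------------------


def write_tracks_csv(tracks: list[Track], path: str | Path) -> None:
    df = tracks_to_frame(tracks)
    df["timestamp"] = pd.DatetimeIndex(df["timestamp"]).strftime("%Y-%m-%dT%H:%M:%SZ")
    df.to_csv(path, index=False)


def read_tracks_csv(path: str | Path) -> list[Track]:
    """Read and validate a positions CSV; malformed rows are reported by line.

    Requires the columns animal_id, timestamp, x, y; timestamps must parse as
    ISO-8601 (assumed UTC when unzoned) and be strictly increasing per animal.
    """
    df = pd.read_csv(path)
    missing = [c for c in TRACK_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    ts = pd.to_datetime(df["timestamp"], utc=True, format="ISO8601", errors="coerce")
    bad = df.index[ts.isna() | df["x"].isna() | df["y"].isna()]
    if len(bad):
        lines = [int(i) + 2 for i in bad[:10]]  # +2: header + 1-based
        raise ValueError(f"{path}: malformed row(s) at line(s) {lines}")
    df = df.assign(timestamp=ts)
    for aid, sub in df.groupby("animal_id"):
        t = sub["timestamp"].to_numpy()
        if len(t) > 1 and not (np.diff(t) > np.timedelta64(0, "s")).all():
            raise ValueError(f"{path}: timestamps not strictly increasing for {aid}")
    return tracks_from_frame(df)


# -- GeoJSON ------------------------------------------------------------------


def patchset_to_geojson(ps: PatchSet) -> dict:
    """Polygonize each patch (union of its cell squares) into GeoJSON features."""
    grid = ps.labels
    lab = grid.values.astype(int)
    half = grid.cell / 2.0
    features = []
    for _, row in ps.table.iterrows():
        pid = int(row["patch_id"])
        rr, cc = np.nonzero(lab == pid)
        cx = grid.origin_x + (cc + 0.5) * grid.cell
        cy = grid.origin_y - (rr + 0.5) * grid.cell
        geom = shapely.unary_union(
            shapely.box(cx - half, cy - half, cx + half, cy + half)
        )
        features.append(
            {
                "type": "Feature",
                "geometry": mapping(geom),
                "properties": {
                    "patch_id": pid,
                    "n_cells": int(row["n_cells"]),
                    "area_m2": float(row["area_m2"]),
                    "nn_dist_m": None
                    if pd.isna(row["nn_dist_m"])
                    else float(row["nn_dist_m"]),
                },
            }
        )
    return {"type": "FeatureCollection", "features": features}


def write_patches_geojson(ps: PatchSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(patchset_to_geojson(ps), fh)


def read_exclusion_polygons(path: str | Path) -> list:
    """Exclusion polygons from a GeoJSON file (FeatureCollection or geometry)."""
    with open(path) as fh:
        gj = json.load(fh)
    if gj.get("type") == "FeatureCollection":
        return [shapely_shape(f["geometry"]) for f in gj["features"]]
    if gj.get("type") == "Feature":
        return [shapely_shape(gj["geometry"])]
    return [shapely_shape(gj)]


# -- reports ------------------------------------------------------------------


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.DataFrame):
        return _jsonable(obj.to_dict(orient="records"))
    if isinstance(obj, pd.Series):
        return _jsonable(obj.to_dict())
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


def write_report(report: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(_jsonable(report), fh, indent=2, sort_keys=True)
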
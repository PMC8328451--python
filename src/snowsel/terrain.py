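"""Raster primitives for snow and terrain indices.

Implements the fine-grid snow-free classifier (depth threshold, default
35 cm), the Normalized-Difference Snow Index, multi-scene averaging, the
Topographic Position Index (TPI), fine-to-coarse snow-fraction aggregation,
and slope/hillshade.

Conventions
-----------
* Snow fractions are stored as the snow-FREE fraction of fine cells per
  coarse cell (a value of 1 means the whole coarse cell is snow-free).  The
  snow-covered complement is ``1 - x``.
* NaN is the in-memory nodata value and propagates through cellwise
  operations; windowed and aggregating operations drop NaN cells from their
  denominators.
* Windowed operations use truncated windows at raster edges (no padding with
  invented elevations).
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage

from .grid import Grid, aligned

SNOW_FREE_DEPTH_CM = 35.0
"""Snow-depth threshold (cm): a fine cell this shallow or less is snow-free."""


def classify_snow_free_fine(depth: Grid, threshold: float = SNOW_FREE_DEPTH_CM) -> Grid:
    """Binary snow-free layer from a fine-grid snow-depth raster (cm).

    A cell is snow-free (1) when its depth is *at most* ``threshold``; a depth
    of exactly 35 cm is snow-free.  Nodata propagates.
    """
    v = depth.values
    if np.nanmin(v) < 0:
        raise ValueError("snow depth must be non-negative")
    out = np.where(v <= threshold, 1.0, 0.0)
    out[~np.isfinite(v)] = np.nan
    return depth.like(out)


def ndsi(green: Grid, swir: Grid) -> Grid:
    """Normalized-Difference Snow Index: (green - swir) / (green + swir).

    Inputs are non-negative reflectances on one georeference.  Cells where
    both bands are zero (0/0) become nodata.
    """
    aligned(green, swir)
    g, s = green.values, swir.values
    if np.nanmin(g) < 0 or np.nanmin(s) < 0:
        raise ValueError("reflectances must be non-negative")
    denom = g + s
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(denom > 0, (g - s) / denom, np.nan)
    out[~np.isfinite(g) | ~np.isfinite(s)] = np.nan
    return green.like(out)


def mean_scene(scenes: list[Grid]) -> Grid:
    """Cellwise mean across scenes, skipping nodata; all-nodata -> nodata."""
    if len(scenes) == 0:
        raise ValueError("at least one scene is required")
    aligned(*scenes)
    stack = np.stack([s.values for s in scenes])
    with warnings.catch_warnings():
        # all-nodata cells legitimately produce an empty-slice mean (-> NaN)
        warnings.simplefilter("ignore", category=RuntimeWarning)
        out = np.nanmean(stack, axis=0)
    return scenes[0].like(out)


def tpi(dem: Grid, window: float = 30.0, include_center: bool = False) -> Grid:
    """Topographic Position Index: elevation minus neighborhood mean.

    ``window`` is the full width of the square neighborhood in map units.  By
    default the center cell is excluded from the neighborhood mean (positive
    TPI on ridges, negative in depressions).  Edge cells use the truncated
    window; nodata cells are dropped from the mean and stay nodata in the
    output.
    """
    half = int(round(window / (2.0 * dem.cell)))
    size = 2 * half + 1
    if size < 3:
        raise ValueError(
            f"window {window} m spans {size} cell(s) at {dem.cell} m; need >= 3"
        )
    v = dem.values
    valid = np.isfinite(v)
    # demean before filtering: TPI is shift-invariant and removing the large
    # elevation offset avoids catastrophic cancellation in the window sums
    shift = v[valid].mean() if valid.any() else 0.0
    v = v - shift
    filled = np.where(valid, v, 0.0)
    # truncated windows: zero padding contributes 0 to both sum and count
    wsum = ndimage.uniform_filter(filled, size=size, mode="constant", cval=0.0) * size**2
    wcnt = ndimage.uniform_filter(valid.astype(float), size=size, mode="constant", cval=0.0) * size**2
    wcnt = np.round(wcnt)
    if not include_center:
        wsum = wsum - filled
        wcnt = wcnt - valid
    with np.errstate(invalid="ignore", divide="ignore"):
        nmean = np.where(wcnt > 0, wsum / wcnt, np.nan)
    out = v - nmean
    out[~valid] = np.nan
    return dem.like(out)


def aggregate_fraction(fine_binary: Grid, factor: int) -> Grid:
    """Snow-free fraction per coarse cell from a fine binary snow-free layer.

    Each coarse cell covers a ``factor x factor`` block of fine cells; its
    value is the fraction of *valid* fine cells equal to 1.  Nodata fine cells
    are excluded from numerator and denominator; an all-nodata block is
    nodata.  Fine dimensions must divide evenly (no partial blocks).
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    nr, nc = fine_binary.shape
    if nr % factor or nc % factor:
        raise ValueError(
            f"fine grid {nr}x{nc} is not divisible by factor {factor}"
        )
    v = fine_binary.values
    valid = np.isfinite(v)
    ones = np.where(valid, v, 0.0).reshape(nr // factor, factor, nc // factor, factor)
    cnt = valid.reshape(nr // factor, factor, nc // factor, factor)
    num = ones.sum(axis=(1, 3))
    den = cnt.sum(axis=(1, 3))
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(den > 0, num / den, np.nan)
    return Grid(
        frac,
        origin_x=fine_binary.origin_x,
        origin_y=fine_binary.origin_y,
        cell=fine_binary.cell * factor,
        nodata=fine_binary.nodata,
    )


def block_mean(fine: Grid, factor: int) -> Grid:
    """Average a fine grid into coarse blocks (nodata-skipping).

    Used to bring fine-grid indices (e.g. 1 m TPI) onto the coarse analysis
    grid.  Dimensions must divide evenly by ``factor``.
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    nr, nc = fine.shape
    if nr % factor or nc % factor:
        raise ValueError(f"fine grid {nr}x{nc} is not divisible by factor {factor}")
    v = fine.values
    valid = np.isfinite(v)
    filled = np.where(valid, v, 0.0).reshape(nr // factor, factor, nc // factor, factor)
    cnt = valid.reshape(nr // factor, factor, nc // factor, factor).sum(axis=(1, 3))
    tot = filled.sum(axis=(1, 3))
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(cnt > 0, tot / cnt, np.nan)
    return Grid(
        mean,
        origin_x=fine.origin_x,
        origin_y=fine.origin_y,
        cell=fine.cell * factor,
        nodata=fine.nodata,
    )


def slope_hillshade(
    dem: Grid, sun_azimuth: float = 315.0, sun_altitude: float = 45.0
) -> tuple[Grid, Grid]:
    """Finite-difference slope (degrees) and hillshade in [0, 1].

    ``sun_azimuth`` is degrees clockwise from north, ``sun_altitude`` degrees
    above the horizon.
    """
    v = dem.values
    dz_drow, dz_dcol = np.gradient(v, dem.cell)
    # rows increase southwards, so dz/dy = -dz/drow
    dzdx, dzdy = dz_dcol, -dz_drow
    slope_rad = np.arctan(np.hypot(dzdx, dzdy))
    aspect = np.arctan2(-dzdx, dzdy)  # 0 = north, clockwise positive
    az = np.deg2rad(sun_azimuth)
    zen = np.deg2rad(90.0 - sun_altitude)
    hs = np.cos(zen) * np.cos(slope_rad) + np.sin(zen) * np.sin(slope_rad) * np.cos(az - aspect)
    hs = np.clip(hs, 0.0, 1.0)
    return dem.like(np.rad2deg(slope_rad)), dem.like(hs)
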
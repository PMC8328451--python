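"""Use-versus-availability selection statistics for snow-free patches.

GPS positions are overlaid on a binary snow-free mask and compared with the
proportional-availability ("random walk") null: if animals used the landscape
at random, the share of positions on snow-free cells would equal the areal
availability fraction.  Selection strength is summarized as the ratio of
observed to expected use and as the odds ratio of a 2x2 used/available x
on/off-patch contingency table, with Wald confidence limits on the log odds
ratio:

    OR = (used_on / used_off) / (avail_on / avail_off)
    SE(ln OR) = sqrt(1/a + 1/b + 1/c + 1/d)
    95% CI = exp(ln OR +/- 1.96 * SE)

Diel stratification splits each day into morning/day/evening/night windows
anchored one hour around local sunrise and sunset.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd
from scipy import stats

from .grid import Grid
from .tracks import Track

Z_95 = 1.959963984540054  # two-sided 95% normal quantile


class DielPeriod(str, Enum):
    DAY = "day"
    EVENING = "evening"
    NIGHT = "night"
    MORNING = "morning"


@dataclass
class ContingencyTable:
    """2x2 used/available x on/off-patch counts."""

    used_on: float
    used_off: float
    avail_on: float
    avail_off: float

    def __post_init__(self) -> None:
        if min(self.used_on, self.used_off, self.avail_on, self.avail_off) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def n_used(self) -> float:
        return self.used_on + self.used_off


@dataclass
class SelectionResult:
    availability_fraction: float
    n_used: float
    observed_on: float
    expected_on: float
    ratio: float          # observed / expected
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    excess_pct: float     # (ratio - 1) * 100


def overlay_positions(tracks: list[Track], mask: Grid) -> tuple[int, int, int]:
    """Count positions on (mask=1) and off (mask=0) snow-free cells.

    Positions outside the mask extent are excluded; the count of exclusions
    is returned as the third element.  Raises if nothing remains.
    """
    vals = np.concatenate([mask.sample(t.x, t.y) for t in tracks]) if tracks else np.array([])
    inside = np.isfinite(vals)
    n_outside = int((~inside).sum())
    if inside.sum() == 0:
        raise ValueError("all positions fall outside the mask extent")
    on = int((vals[inside] > 0).sum())
    off = int(inside.sum()) - on
    return on, off, n_outside


def availability_fraction(mask: Grid) -> float:
    """Areal fraction of snow-free (mask=1) cells among valid cells."""
    v = mask.values
    valid = np.isfinite(v)
    if not valid.any():
        raise ValueError("mask has no valid cells")
    return float((v[valid] > 0).mean())


def expected_under_proportional(n_used: float, avail_fraction: float) -> float:
    """Expected on-patch positions if use were proportional to availability."""
    if not 0.0 <= avail_fraction <= 1.0:
        raise ValueError("availability fraction must be in [0, 1]")
    return n_used * avail_fraction


def odds_ratio(
    t: ContingencyTable,
    availability: float | None = None,
    haldane: bool = False,
) -> SelectionResult:
    """Selection summary from a 2x2 table: OR, Wald 95% CI, two-sided p.

    Zero cells make the Wald statistics undefined; pass ``haldane=True`` to
    apply the Haldane-Anscombe +0.5 correction explicitly (never silent).
    ``availability`` defaults to the available-side on-fraction.
    """
    a, b, c, d = t.used_on, t.used_off, t.avail_on, t.avail_off
    if min(a, b, c, d) == 0:
        if not haldane:
            raise ValueError(
                "zero cell in contingency table; set haldane=True to apply "
                "the +0.5 continuity correction"
            )
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    orr = (a / b) / (c / d)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    log_or = math.log(orr)
    ci_low, ci_high = math.exp(log_or - Z_95 * se), math.exp(log_or + Z_95 * se)
    z = log_or / se
    p = 2.0 * stats.norm.sf(abs(z))
    if availability is None:
        availability = c / (c + d)
    expected = expected_under_proportional(t.n_used, availability)
    ratio = t.used_on / expected if expected > 0 else math.inf
    return SelectionResult(
        availability_fraction=float(availability),
        n_used=t.n_used,
        observed_on=t.used_on,
        expected_on=expected,
        ratio=ratio,
        odds_ratio=orr,
        ci_low=ci_low,
        ci_high=ci_high,
        p_value=float(p),
        excess_pct=(ratio - 1.0) * 100.0,
    )


def select_against_availability(
    tracks: list[Track], mask: Grid, haldane: bool = False
) -> SelectionResult:
    """Full proportional-availability analysis of tracks against a mask.

    The available side of the table is the count of snow-free vs snow-covered
    valid cells in the mask (the areal availability), the used side the
    overlaid positions.  ``haldane`` is forwarded to :func:`odds_ratio` for
    tables with a zero cell.
    """
    on, off, _ = overlay_positions(tracks, mask)
    v = mask.values
    valid = np.isfinite(v)
    avail_on = int((v[valid] > 0).sum())
    avail_off = int(valid.sum()) - avail_on
    table = ContingencyTable(on, off, avail_on, avail_off)
    return odds_ratio(
        table, availability=avail_on / (avail_on + avail_off), haldane=haldane
    )


# -- solar geometry and diel windows ----------------------------------------


class PolarDayNightError(ValueError):
    """The sun does not rise or does not set on this date at this latitude."""


def solar_times(date, lat: float, lon: float) -> tuple[pd.Timestamp, pd.Timestamp]:
    """Sunrise and sunset (UTC) by the standard NOAA solar-geometry formulas.

    Uses the conventional refraction-corrected zenith of 90.833 deg.  ``lon``
    is degrees east.  Raises :class:`PolarDayNightError` when the sun never
    rises or never sets on that date.
    """
    date = pd.Timestamp(date).normalize()
    doy = int(date.day_of_year)
    # fractional year (radians), at solar noonish
    gamma = 2.0 * math.pi / 365.0 * (doy - 1 + 0.5)
    # equation of time (minutes) and solar declination (radians)
    eqtime = 229.18 * (
        0.000075
        + 0.001868 * math.cos(gamma)
        - 0.032077 * math.sin(gamma)
        - 0.014615 * math.cos(2 * gamma)
        - 0.040849 * math.sin(2 * gamma)
    )
    decl = (
        0.006918
        - 0.399912 * math.cos(gamma)
        + 0.070257 * math.sin(gamma)
        - 0.006758 * math.cos(2 * gamma)
        + 0.000907 * math.sin(2 * gamma)
        - 0.002697 * math.cos(3 * gamma)
        + 0.00148 * math.sin(3 * gamma)
    )
    lat_r = math.radians(lat)
    zenith = math.radians(90.833)
    cos_ha = (math.cos(zenith) - math.sin(lat_r) * math.sin(decl)) / (
        math.cos(lat_r) * math.cos(decl)
    )
    if cos_ha > 1.0:
        raise PolarDayNightError("sun never rises on this date")
    if cos_ha < -1.0:
        raise PolarDayNightError("sun never sets on this date")
    ha = math.degrees(math.acos(cos_ha))
    sunrise_min = 720.0 - 4.0 * (lon + ha) - eqtime
    sunset_min = 720.0 - 4.0 * (lon - ha) - eqtime
    return (
        date + pd.Timedelta(minutes=sunrise_min),
        date + pd.Timedelta(minutes=sunset_min),
    )


def classify_diel(timestamp, sunrise, sunset) -> DielPeriod:
    """Diel window of a UTC timestamp given that date's sunrise/sunset.

    morning = [sunrise-1h, sunrise+1h), day = [sunrise+1h, sunset-1h),
    evening = [sunset-1h, sunset+1h), night = the remainder; all intervals
    half-open on the right, so a position exactly at sunset-1h is evening.
    """
    ts = pd.Timestamp(timestamp)
    sunrise, sunset = pd.Timestamp(sunrise), pd.Timestamp(sunset)
    if not sunrise < sunset:
        raise PolarDayNightError("sunrise must precede sunset")
    h = pd.Timedelta(hours=1)
    if sunrise - h <= ts < sunrise + h:
        return DielPeriod.MORNING
    if sunrise + h <= ts < sunset - h:
        return DielPeriod.DAY
    if sunset - h <= ts < sunset + h:
        return DielPeriod.EVENING
    return DielPeriod.NIGHT


def diel_labels(tracks: list[Track], lat: float, lon: float) -> pd.DataFrame:
    """Positions table with a diel-period label per fix.

    Dates without a sunrise or sunset (polar day/night) are flagged 'polar'
    and excluded from per-period statistics.
    """
    frames = []
    for t in tracks:
        df = t.to_frame()
        frames.append(df)
    df = pd.concat(frames, ignore_index=True)
    naive = pd.DatetimeIndex(df["timestamp"]).tz_convert(None)
    labels = []
    cache: dict = {}
    for ts in naive:
        day = ts.normalize()
        if day not in cache:
            try:
                cache[day] = solar_times(day, lat, lon)
            except PolarDayNightError:
                cache[day] = None
        sun = cache[day]
        labels.append(
            "polar" if sun is None else classify_diel(ts, sun[0], sun[1]).value
        )
    df["diel"] = labels
    return df


def diel_selection(
    tracks: list[Track], mask: Grid, avail_fraction: float,
    lat: float = 60.0, lon: float = 7.5,
) -> pd.DataFrame:
    """Observed vs expected use per diel period under proportional availability.

    Returns one row per period with observed/expected on-patch counts, the
    ratio and the percentage excess use; empty periods are flagged and
    skipped.  Positions on polar dates are excluded.
    """
    df = diel_labels(tracks, lat, lon)
    on = mask.sample(df["x"].to_numpy(), df["y"].to_numpy())
    df = df.assign(on_patch=on)
    df = df[np.isfinite(df["on_patch"]) & (df["diel"] != "polar")]
    rows = []
    for period in [p.value for p in DielPeriod]:
        sub = df[df["diel"] == period]
        n = len(sub)
        if n == 0:
            rows.append({"period": period, "n": 0, "defined": False})
            continue
        obs = float((sub["on_patch"] > 0).sum())
        exp = expected_under_proportional(n, avail_fraction)
        ratio = obs / exp if exp > 0 else np.inf
        rows.append(
            {
                "period": period,
                "n": n,
                "observed_on": obs,
                "expected_on": exp,
                "ratio": ratio,
                "excess_pct": (ratio - 1.0) * 100.0,
                "defined": True,
            }
        )
    return pd.DataFrame(rows)
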
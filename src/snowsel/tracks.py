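"""GPS track container: time-ordered positions for one animal."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class Track:
    """Positions of one animal at a nominal fix cadence (3 h by default).

    ``times`` are UTC timestamps, strictly increasing; ``x``/``y`` are
    projected planar coordinates in meters.
    """

    animal_id: str
    times: np.ndarray  # datetime64[ns], UTC
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype="datetime64[ns]")
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (len(self.times) == len(self.x) == len(self.y)):
            raise ValueError("times, x, y must have equal length")
        if len(self.times) > 1 and not (np.diff(self.times) > np.timedelta64(0, "s")).all():
            raise ValueError(f"timestamps not strictly increasing for {self.animal_id}")

    def __len__(self) -> int:
        return len(self.times)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "animal_id": self.animal_id,
                "timestamp": pd.DatetimeIndex(self.times, tz="UTC"),
                "x": self.x,
                "y": self.y,
            }
        )


def tracks_to_frame(tracks: list[Track]) -> pd.DataFrame:
    return pd.concat([t.to_frame() for t in tracks], ignore_index=True)


def tracks_from_frame(df: pd.DataFrame) -> list[Track]:
    """Split a tidy positions table into per-animal tracks.

    Expects columns animal_id, timestamp (UTC), x, y.  Rows are sorted by
    timestamp within animal; duplicate timestamps are rejected.
    """
    out = []
    for aid, sub in df.groupby("animal_id", sort=True):
        sub = sub.sort_values("timestamp")
        ts = pd.DatetimeIndex(sub["timestamp"])
        if ts.tz is not None:
            ts = ts.tz_convert("UTC").tz_localize(None)
        out.append(
            Track(str(aid), ts.values, sub["x"].to_numpy(), sub["y"].to_numpy())
        )
    return out
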
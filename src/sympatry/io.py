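"""CSV readers and writers for tracks, accelerometer records and scats.

Formats (all plain CSV):

* GPS: ``id,species,timestamp,x,y,error_sd[,activity]`` with ISO-8601
  timestamps and projected meters.
* Activity: ``id,species,interval_start,summed_accel`` -- one row per
  5-min accelerometer summary.
* Scats: long format ``id,date,diameter_mm,track_species,item,
  volume_fraction`` -- one row per prey item per scat; ``track_species``
  is ``wolf``/``coyote``/``none``.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .tracks import GpsTrack

GPS_COLUMNS = ["id", "species", "timestamp", "x", "y", "error_sd"]
ACTIVITY_COLUMNS = ["id", "species", "interval_start", "summed_accel"]
SCAT_COLUMNS = ["id", "date", "diameter_mm", "track_species", "item", "volume_fraction"]


def read_gps(path: str | Path) -> list[GpsTrack]:
    """Read a GPS CSV into one :class:`GpsTrack` per individual."""
    df = pd.read_csv(path, parse_dates=["timestamp"])
    missing = set(GPS_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"GPS CSV missing columns: {sorted(missing)}")
    tracks = []
    for (ind, species), grp in df.groupby(["id", "species"], sort=True):
        grp = grp.sort_values("timestamp")
        activity = grp["activity"].to_numpy() if "activity" in grp else None
        tracks.append(GpsTrack(
            individual=str(ind),
            species=str(species),
            timestamps=grp["timestamp"].to_numpy(),
            x=grp["x"].to_numpy(),
            y=grp["y"].to_numpy(),
            error_sd=grp["error_sd"].to_numpy(),
            activity=activity,
        ))
    return tracks


def write_gps(path: str | Path, tracks: list[GpsTrack]) -> None:
    frames = [t.to_frame() for t in tracks]
    df = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=GPS_COLUMNS + ["activity"])
    df.to_csv(path, index=False)


def read_activity(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, parse_dates=["interval_start"])
    missing = set(ACTIVITY_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"activity CSV missing columns: {sorted(missing)}")
    if (df["summed_accel"] < 0).any():
        raise ValueError("summed acceleration must be nonnegative")
    return df.sort_values(["id", "interval_start"]).reset_index(drop=True)


def write_activity(path: str | Path, df: pd.DataFrame) -> None:
    df.to_csv(path, index=False)


def read_scats(path: str | Path) -> pd.DataFrame:
    """Read a long-format scat CSV and check per-scat volume closure."""
    df = pd.read_csv(path, parse_dates=["date"])
    missing = set(SCAT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"scat CSV missing columns: {sorted(missing)}")
    if (df["diameter_mm"] <= 0).any():
        raise ValueError("scat diameters must be positive")
    sums = df.groupby("id")["volume_fraction"].sum()
    bad = sums[(sums - 1.0).abs() > 1e-6]
    if len(bad):
        raise ValueError(f"scat volume fractions do not sum to 1 for: {list(bad.index)[:5]}")
    return df


def write_scats(path: str | Path, df: pd.DataFrame) -> None:
    df.to_csv(path, index=False)
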
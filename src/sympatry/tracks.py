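"""GPS track and accelerometer series containers.

A :class:`GpsTrack` holds one animal's ordered relocations in projected
meters, each with a location-error SD (0 for GPS-quality fixes, larger
for VHF triangulations) and an activity state label. States live in
{"active", "inactive", "unknown"}; "unknown" fixes take part in neither
the active nor the inactive occurrence distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SPECIES = ("wolf", "coyote", "deer_adult", "deer_fawn")
STATES = ("active", "inactive", "unknown")


@dataclass
class GpsTrack:
    individual: str
    species: str
    timestamps: np.ndarray          # datetime64[s], strictly increasing
    x: np.ndarray                   # m, projected
    y: np.ndarray                   # m, projected
    error_sd: np.ndarray            # m, per-fix location error SD
    activity: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.species not in SPECIES:
            raise ValueError(f"unknown species {self.species!r}")
        self.timestamps = np.asarray(self.timestamps, dtype="datetime64[s]")
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.error_sd = np.asarray(self.error_sd, dtype=float)
        n = len(self.timestamps)
        for name in ("x", "y", "error_sd"):
            if len(getattr(self, name)) != n:
                raise ValueError("track arrays have unequal lengths")
        if self.activity is None:
            self.activity = np.full(n, "unknown", dtype="<U8")
        else:
            self.activity = np.asarray(self.activity, dtype="<U8")
            if len(self.activity) != n:
                raise ValueError("track arrays have unequal lengths")
            bad = set(np.unique(self.activity)) - set(STATES)
            if bad:
                raise ValueError(f"unknown activity states {sorted(bad)}")
        if n > 1 and not (np.diff(self.timestamps.astype("int64")) > 0).all():
            raise ValueError("timestamps must be strictly increasing")
        if not (np.isfinite(self.x).all() and np.isfinite(self.y).all()):
            raise ValueError("coordinates must be finite")
        if (self.error_sd < 0).any():
            raise ValueError("location error SD must be nonnegative")

    @property
    def n_fixes(self) -> int:
        return len(self.timestamps)

    def minutes(self) -> np.ndarray:
        """Time of each fix in minutes since the first fix."""
        t0 = self.timestamps[0].astype("int64")
        return (self.timestamps.astype("int64") - t0) / 60.0

    def dates(self) -> np.ndarray:
        return self.timestamps.astype("datetime64[D]")

    def subset(self, mask: np.ndarray) -> "GpsTrack":
        return GpsTrack(self.individual, self.species, self.timestamps[mask],
                        self.x[mask], self.y[mask], self.error_sd[mask],
                        self.activity[mask])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "id": self.individual,
            "species": self.species,
            "timestamp": self.timestamps,
            "x": self.x,
            "y": self.y,
            "error_sd": self.error_sd,
            "activity": self.activity,
        })
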
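"""Study configuration, the deer-season calendar, and inclusion filters.

The analysis calendar is split into three biological periods tied to
white-tailed deer fawn availability: the preparturition period (PPP,
May 1-26), the fawn limited-mobility period (LMP, May 27 - June 30) and
the fawn social-mobility period (SMP, July 1 - August 31). Period
assignment ignores the year; dates outside May 1 - Aug 31 belong to no
period.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from datetime import date as _date
from pathlib import Path
from typing import Iterable, Sequence

import yaml

PERIOD_LABELS = ("PPP", "LMP", "SMP")

#: Inclusive (month, day) bounds of each period, year-agnostic.
PERIOD_BOUNDS: dict[str, tuple[tuple[int, int], tuple[int, int]]] = {
    "PPP": ((5, 1), (5, 26)),
    "LMP": ((5, 27), (6, 30)),
    "SMP": ((7, 1), (8, 31)),
}

DEFAULT_COVARIATE_PRIORITY = (
    "deer_adult_occ",
    "deer_fawn_occ",
    "wolf_occ",
    "hare_density",
    "grouse_density",
    "dist_road",
    "dist_water",
    "dist_edge",
    "patch_size",
)


@dataclass
class StudyConfig:
    """Scalar settings of the whole pipeline, all overridable from YAML.

    Units: ``fix_interval`` and ``activity_interval`` in minutes,
    ``grid_cell`` in meters, ``vhf_max_lag`` in hours; the activity
    threshold is on the collar's unitless summed acceleration; motion
    variance is carried in m^2/min throughout.
    """

    activity_threshold: float = 30.7
    fix_interval: float = 15.0
    activity_interval: float = 5.0
    grid_cell: float = 30.0
    od_level: float = 0.99
    dbbmm_window: int = 23
    dbbmm_margin: int = 5
    vhf_max_lag: float = 48.0
    correlation_cutoff: float = 0.7
    cv_bins: int = 8
    alpha: float = 0.05
    min_locs_adult: int = 20
    min_locs_fawn: int = 5
    covariate_priority: tuple[str, ...] = DEFAULT_COVARIATE_PRIORITY
    rng_seed: int = 0

    def __post_init__(self) -> None:
        positive = (
            "activity_threshold", "fix_interval", "activity_interval",
            "grid_cell", "vhf_max_lag", "correlation_cutoff",
        )
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if not 0 < self.od_level < 1:
            raise ValueError("od_level must be in (0, 1)")
        if self.dbbmm_margin >= self.dbbmm_window:
            raise ValueError("dbbmm_margin must be smaller than dbbmm_window")
        if self.cv_bins < 2:
            raise ValueError("cv_bins must be at least 2")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.min_locs_adult <= 0 or self.min_locs_fawn <= 0:
            raise ValueError("minimum location counts must be positive")
        self.covariate_priority = tuple(self.covariate_priority)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["covariate_priority"] = list(self.covariate_priority)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


def assign_period(date: _date) -> str | None:
    """Assign a calendar date to PPP/LMP/SMP by month-day, ignoring the year.

    Returns ``None`` outside May 1 - Aug 31. Boundaries are inclusive on
    both ends.
    """
    if not isinstance(date, _date):
        raise TypeError("assign_period expects a datetime.date")
    md = (date.month, date.day)
    for label, (start, end) in PERIOD_BOUNDS.items():
        if start <= md <= end:
            return label
    return None


def filter_individuals(tracks: Iterable, config: StudyConfig) -> list:
    """Apply the location-count inclusion filters.

    Adult deer need at least ``min_locs_adult`` fixes and fawns at least
    ``min_locs_fawn`` (fawns suffered heavy early predation; requiring 20
    locations would bias the sample toward survivors). Wolves and coyotes
    are never count-filtered -- their inclusion was driven by collar data
    recovery, not fix counts.
    """
    kept = []
    for track in tracks:
        if track.species == "deer_adult" and track.n_fixes < config.min_locs_adult:
            continue
        if track.species == "deer_fawn" and track.n_fixes < config.min_locs_fawn:
            continue
        kept.append(track)
    return kept
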
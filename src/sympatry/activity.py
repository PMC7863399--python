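"""Accelerometer activity classification and circular activity overlap.

Collars summarize gravitational acceleration over 5-min intervals; an
interval is "active" when the summed reading is at or above a calibrated
threshold (30.7 by default). Daily activity patterns are estimated as
circular kernel densities of active-interval times-of-day using a von
Mises kernel whose concentration follows a rule-of-thumb plug-in, and
two species' patterns are compared with the coefficient of overlapping

    Delta = integral over the circle of min(f_a, f_b),

which is 0 for disjoint activity schedules and 1 for identical ones.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

DENSITY_GRID_SIZE = 512


@dataclass
class ActivityComparison:
    """Per-species time-active proportions and a one-tailed Welch t test."""

    proportions_a: np.ndarray
    proportions_b: np.ndarray
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    t: float
    df: float
    p: float
    alternative: str
    degenerate: bool = False


@dataclass
class OverlapResult:
    """Two circular densities on a shared time-of-day grid and their Delta."""

    grid_hours: np.ndarray      # [0, 24), regular
    density_a: np.ndarray       # per-hour density, integrates to 1
    density_b: np.ndarray
    delta: float
    estimator: str = "vonmises-kde-min-integral"


def classify_activity(records: pd.DataFrame, threshold: float = 30.7) -> pd.DataFrame:
    """Label each 5-min record active/inactive by the summed-accel threshold.

    The boundary itself is active: state = active iff summed_accel >= threshold.
    """
    accel = records["summed_accel"].to_numpy(dtype=float)
    if (accel < 0).any():
        raise ValueError("summed acceleration must be nonnegative")
    out = records.copy()
    out["state"] = np.where(accel >= threshold, "active", "inactive")
    return out


def assign_activity_to_fixes(track, series: pd.DataFrame,
                             fix_interval_minutes: float = 15.0,
                             activity_interval_minutes: float = 5.0):
    """Label each GPS fix with the state of the nearest activity interval.

    Each fix takes the state of the interval whose midpoint is nearest in
    time; ties go to the earlier interval. Fixes with no interval midpoint
    within one fix interval keep state "unknown".
    """
    from .tracks import GpsTrack

    sub = series[series["id"] == track.individual] if "id" in series.columns else series
    if sub.empty or "state" not in sub.columns:
        return GpsTrack(track.individual, track.species, track.timestamps,
                        track.x, track.y, track.error_sd,
                        np.full(track.n_fixes, "unknown", dtype="<U8"))
    starts = sub["interval_start"].to_numpy(dtype="datetime64[s]").astype("int64")
    order = np.argsort(starts, kind="stable")
    starts = starts[order]
    states = sub["state"].to_numpy(dtype="<U8")[order]
    mid = starts + activity_interval_minutes * 30.0  # half interval, in seconds

    fix_t = track.timestamps.astype("int64").astype(float)
    # nearest midpoint; on exact distance tie prefer the earlier interval
    idx = np.searchsorted(mid, fix_t)
    left = np.clip(idx - 1, 0, len(mid) - 1)
    right = np.clip(idx, 0, len(mid) - 1)
    d_left = np.abs(fix_t - mid[left])
    d_right = np.abs(fix_t - mid[right])
    nearest = np.where(d_left <= d_right, left, right)
    dist = np.minimum(d_left, d_right)
    labels = states[nearest].copy()
    labels[dist > fix_interval_minutes * 60.0] = "unknown"
    return GpsTrack(track.individual, track.species, track.timestamps,
                    track.x, track.y, track.error_sd, labels)


def proportion_active(series: pd.DataFrame) -> pd.DataFrame:
    """Per-individual proportion of intervals active, with species labels."""
    if "state" not in series.columns:
        raise ValueError("series must be classified first (no 'state' column)")
    grp = series.groupby(["species", "id"])["state"]
    prop = grp.apply(lambda s: float((s == "active").mean()))
    return prop.rename("proportion_active").reset_index()


def proportion_active_test(series: pd.DataFrame, species_a: str, species_b: str,
                           alternative: str = "less") -> ActivityComparison:
    """Welch t test on per-individual time-active proportions.

    ``alternative="less"`` tests whether ``species_a`` (the putative
    subordinate) is active a smaller proportion of the time than
    ``species_b``. Uses unequal variances with Welch-Satterthwaite df.
    """
    props = proportion_active(series)
    a = props.loc[props["species"] == species_a, "proportion_active"].to_numpy()
    b = props.loc[props["species"] == species_b, "proportion_active"].to_numpy()
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least two individuals per species")
    degenerate = a.std(ddof=1) == 0 and b.std(ddof=1) == 0
    if degenerate:
        t_stat, p_val, df = np.nan, np.nan, np.nan
    else:
        res = stats.ttest_ind(a, b, equal_var=False, alternative=alternative)
        t_stat, p_val, df = float(res.statistic), float(res.pvalue), float(res.df)
    return ActivityComparison(
        proportions_a=a, proportions_b=b,
        mean_a=float(a.mean()), sd_a=float(a.std(ddof=1)),
        mean_b=float(b.mean()), sd_b=float(b.std(ddof=1)),
        t=t_stat, df=df, p=p_val, alternative=alternative,
        degenerate=bool(degenerate),
    )


def _a1_inverse(r: float) -> float:
    """Invert the mean resultant length to a von Mises concentration.

    Standard piecewise approximation (Fisher 1993) of the inverse of
    A1(kappa) = I1(kappa) / I0(kappa).
    """
    if r < 0.53:
        return 2 * r + r ** 3 + 5 * r ** 5 / 6
    if r < 0.85:
        return -0.4 + 1.39 * r + 0.43 / (1 - r)
    return 1.0 / (r ** 3 - 4 * r ** 2 + 3 * r)


def kernel_concentration(times_hours: np.ndarray, adjust: float = 1.0) -> float:
    """Rule-of-thumb von Mises kernel concentration for circular KDE.

    Fits a von Mises concentration kappa-hat to the sample by maximum
    likelihood, then applies the AMISE-optimal plug-in

        nu = [3 n kappa^2 I2(2 kappa) / (4 sqrt(pi) I1(kappa)^2)]^(2/5),

    scaled by ``adjust`` (smaller values smooth more).
    """
    theta = np.asarray(times_hours, dtype=float) * (2 * np.pi / 24.0)
    n = len(theta)
    if n < 2:
        raise ValueError("need at least two event times")
    c, s = np.cos(theta).mean(), np.sin(theta).mean()
    rbar = float(np.hypot(c, s))
    kappa = _a1_inverse(min(rbar, 0.995))
    if kappa < 1e-6:
        kappa = 1e-6
    # exponentially scaled Bessel ratios keep this finite for large kappa
    i2 = special.ive(2, 2 * kappa)
    i1 = special.ive(1, kappa)
    nu = (3 * n * kappa ** 2 * i2 / (4 * np.sqrt(np.pi) * i1 ** 2)) ** 0.4
    return float(max(nu * adjust, 1e-6))


def circular_density(times_hours: np.ndarray, concentration: float | None = None,
                     adjust: float = 1.0,
                     grid_size: int = DENSITY_GRID_SIZE) -> tuple[np.ndarray, np.ndarray]:
    """Von Mises kernel density of times-of-day on the 24 h circle.

    Returns ``(grid_hours, density)`` where the density is per hour and
    integrates to 1 over [0, 24). ``concentration`` overrides the
    rule-of-thumb bandwidth.
    """
    times = np.asarray(times_hours, dtype=float)
    if len(times) < 2:
        raise ValueError("need at least two event times for a density")
    if concentration is None:
        concentration = kernel_concentration(times, adjust=adjust)
    theta = times * (2 * np.pi / 24.0)
    grid_hours = np.arange(grid_size) * (24.0 / grid_size)
    grid_theta = grid_hours * (2 * np.pi / 24.0)
    norm = 2 * np.pi * special.i0e(concentration)
    dens = np.zeros(grid_size)
    for start in range(0, len(theta), 4096):        # chunk to bound memory
        block = theta[start:start + 4096]
        # ive-consistent scaling: exp(kappa(cos d - 1)) / (2 pi i0e(kappa))
        dens += np.exp(concentration * (np.cos(grid_theta[:, None] - block[None, :]) - 1.0)).sum(axis=1)
    dens /= len(theta) * norm                       # per radian
    dens *= 2 * np.pi / 24.0                        # per hour
    return grid_hours, dens


def overlap_coefficient(grid_hours: np.ndarray, density_a: np.ndarray,
                        density_b: np.ndarray) -> OverlapResult:
    """Coefficient of overlapping Delta between two circular densities.

    Delta = integral of min(f_a, f_b) over the 24 h circle, by
    trapezoidal quadrature on the shared grid (closed by wraparound).
    """
    grid_hours = np.asarray(grid_hours, dtype=float)
    density_a = np.asarray(density_a, dtype=float)
    density_b = np.asarray(density_b, dtype=float)
    if grid_hours.shape != density_a.shape or grid_hours.shape != density_b.shape:
        raise ValueError("densities must share one evaluation grid")
    m = np.minimum(density_a, density_b)
    # close the circle: append the first point at t = 24 h
    xs = np.append(grid_hours, 24.0)
    ys = np.append(m, m[0])
    delta = float(np.trapezoid(ys, xs))
    return OverlapResult(grid_hours=grid_hours, density_a=density_a,
                         density_b=density_b, delta=delta)


def activity_overlap(times_a_hours: np.ndarray, times_b_hours: np.ndarray,
                     adjust: float = 1.0,
                     grid_size: int = DENSITY_GRID_SIZE) -> OverlapResult:
    """Delta between two samples of active-interval times-of-day."""
    grid, dens_a = circular_density(times_a_hours, adjust=adjust, grid_size=grid_size)
    _, dens_b = circular_density(times_b_hours, adjust=adjust, grid_size=grid_size)
    return overlap_coefficient(grid, dens_a, dens_b)


def times_of_day_hours(timestamps: np.ndarray) -> np.ndarray:
    """Clock time-of-day in hours for an array of datetime64 values."""
    t = np.asarray(timestamps, dtype="datetime64[s]").astype("int64")
    return (t % 86400) / 3600.0
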
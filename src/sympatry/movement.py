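"""Brownian bridge movement models and occurrence distributions.

The Brownian bridge movement model (BBMM) treats an animal's path
between consecutive fixes as a conditioned random walk with diffusion
rate sigma_m^2 (the Brownian motion variance, m^2/min here). The motion
variance is estimated by the leave-one-out likelihood: each interior fix
z_i is predicted from its neighbours,

    z_i ~ Normal(z_{i-1} + a (z_{i+1} - z_{i-1}), s I_2),
    a = (t_i - t_{i-1}) / (t_{i+1} - t_{i-1}),
    s = T a (1 - a) sigma_m^2
        + (1 - a)^2 delta_{i-1}^2 + a^2 delta_{i+1}^2 + delta_i^2,

where T = t_{i+1} - t_{i-1} and delta are the per-fix location-error
SDs. The delta_i^2 term carries the tested fix's own observation error;
without it the estimator absorbs location error into sigma_m^2, which
biases the estimate badly whenever the error is comparable to the
bridge SD (e.g., 15-min GPS fixes with 5 m error). The dynamic variant (dBBMM) slides a window along the path and
lets an information criterion decide whether a behavioural change point
splits the window into two diffusion regimes, yielding a piecewise
motion-variance profile.

The occurrence distribution (OD) integrates the bridge density over
every retained segment onto a regular grid and normalizes the result to
a probability surface; its 99% contour is taken as the outer boundary of
the area available to the animal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

from .grids import GridGeometry
from .tracks import GpsTrack

SIGMA2_BOUNDS = (1e-6, 1e3)   # m^2/min search range for the MLE
QUADRATURE_STEPS = 10         # time steps per segment when integrating bridges
TRUNCATION_SDS = 5.0          # evaluate each Gaussian only within this radius


@dataclass
class MotionVarianceProfile:
    """Per-segment motion variance along a track (length n_fixes - 1)."""

    sigma2: np.ndarray                       # m^2/min per inter-fix segment
    breakpoints: list[int] = field(default_factory=list)   # fix indices (diagnostic)
    window_estimates: list[tuple[int, int, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sigma2 = np.asarray(self.sigma2, dtype=float)
        if (self.sigma2 < 0).any():
            raise ValueError("motion variance must be nonnegative")


@dataclass
class OccurrenceDistribution:
    """Normalized per-cell occurrence heights with a contour mask."""

    geometry: GridGeometry
    height: np.ndarray            # sums to 1
    level_mask: np.ndarray        # bool, smallest cell set reaching od_level
    od_level: float
    individual: str = ""
    species: str = ""
    period: str = ""
    state: str = ""


# ---------------------------------------------------------------------------
# Motion variance MLE


def _loo_triples(times_min: np.ndarray, x: np.ndarray, y: np.ndarray,
                 err: np.ndarray, max_lag_minutes: float | None,
                 lo: int = 0, hi: int | None = None):
    """Leave-one-out triples (a, T, squared deviation, error term).

    Triples are centred on interior fixes in [lo+1, hi-1); a triple is
    skipped when its total span T exceeds ``max_lag_minutes``.
    """
    hi = len(times_min) if hi is None else hi
    i = np.arange(lo + 1, hi - 1)
    if len(i) == 0:
        return None
    t0, t1, t2 = times_min[i - 1], times_min[i], times_min[i + 1]
    T = t2 - t0
    keep = np.ones(len(i), dtype=bool)
    if max_lag_minutes is not None:
        keep = T <= max_lag_minutes
    if not keep.any():
        return None
    i, T = i[keep], T[keep]
    a = (t1[keep] - t0[keep]) / T
    mu_x = x[i - 1] + a * (x[i + 1] - x[i - 1])
    mu_y = y[i - 1] + a * (y[i + 1] - y[i - 1])
    dev2 = (x[i] - mu_x) ** 2 + (y[i] - mu_y) ** 2
    err2 = (1 - a) ** 2 * err[i - 1] ** 2 + a ** 2 * err[i + 1] ** 2 + err[i] ** 2
    return a, T, dev2, err2


def _neg_log_lik(sigma2: float, triples) -> float:
    a, T, dev2, err2 = triples
    s = T * a * (1 - a) * sigma2 + err2
    s = np.maximum(s, 1e-12)
    return float(np.sum(np.log(2 * np.pi * s) + dev2 / (2 * s)))


def _mle_sigma2(triples, bounds: tuple[float, float] = SIGMA2_BOUNDS,
                guard: bool = True) -> tuple[float, float]:
    """Maximize the leave-one-out likelihood over log(sigma_m^2).

    Returns (sigma2_hat, max log-likelihood). Optimizing on the log scale
    keeps the bounded Brent search well conditioned across the nine
    orders of magnitude the bounds span. ``guard`` adds a coarse scan to
    escape a local solution; the windowed dBBMM fits skip it for speed
    (their small-window likelihoods are unimodal in practice).
    """
    lo, hi = np.log(bounds[0]), np.log(bounds[1])
    res = minimize_scalar(lambda u: _neg_log_lik(np.exp(u), triples),
                          bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-8})
    if guard:
        grid = np.linspace(lo, hi, 40)
        vals = np.array([_neg_log_lik(np.exp(u), triples) for u in grid])
        if vals.min() < res.fun - 1e-9:
            k = int(vals.argmin())
            b = (grid[max(k - 1, 0)], grid[min(k + 1, len(grid) - 1)])
            res = minimize_scalar(lambda u: _neg_log_lik(np.exp(u), triples),
                                  bounds=b, method="bounded",
                                  options={"xatol": 1e-8})
    return float(np.exp(res.x)), -float(res.fun)


def fit_motion_variance(track: GpsTrack, max_lag_hours: float | None = None,
                        bounds: tuple[float, float] = SIGMA2_BOUNDS) -> float:
    """Single (static) motion variance for a whole track, m^2/min."""
    if track.n_fixes < 3:
        raise ValueError("need at least three fixes to estimate motion variance")
    max_lag_min = None if max_lag_hours is None else max_lag_hours * 60.0
    triples = _loo_triples(track.minutes(), track.x, track.y, track.error_sd,
                           max_lag_min)
    if triples is None:
        raise ValueError("every leave-one-out triple exceeds max_lag; "
                         "cannot estimate motion variance")
    sigma2, _ = _mle_sigma2(triples, bounds)
    return sigma2


def fit_dynamic_motion_variance(track: GpsTrack, window: int = 23,
                                margin: int = 5,
                                max_lag_hours: float | None = None,
                                bounds: tuple[float, float] = SIGMA2_BOUNDS,
                                ) -> MotionVarianceProfile:
    """Windowed change-point motion variance (dBBMM style).

    A window of ``window`` fixes slides one fix at a time. Within each
    window a no-break model competes against single-break models at
    every interior fix at least ``margin`` fixes from either edge; BIC
    on the window's leave-one-out likelihood picks the winner (no-break:
    one parameter; break: two variances plus the break position). Each
    inter-fix segment's final sigma_m^2 is the mean of the estimates
    from all windows covering it.
    """
    if window < 2 * margin + 3:
        raise ValueError("window must be at least 2*margin + 3 fixes")
    n = track.n_fixes
    if n < window:
        warnings.warn("track shorter than the dBBMM window; "
                      "falling back to a static fit", stacklevel=2)
        sigma2 = fit_motion_variance(track, max_lag_hours, bounds)
        return MotionVarianceProfile(np.full(n - 1, sigma2))

    times = track.minutes()
    x, y, err = track.x, track.y, track.error_sd
    max_lag_min = None if max_lag_hours is None else max_lag_hours * 60.0

    acc = np.zeros(n - 1)
    cnt = np.zeros(n - 1)
    breakpoints: list[int] = []
    window_estimates: list[tuple[int, int, float]] = []

    for k in range(n - window + 1):
        hi = k + window
        full = _loo_triples(times, x, y, err, max_lag_min, k, hi)
        if full is None:
            continue
        m = len(full[1])
        s2_full, ll_full = _mle_sigma2(full, bounds, guard=False)
        bic_best = -2 * ll_full + 1 * np.log(m)
        # break model: two variances plus the break position; the extra
        # 2 ln(c) term corrects for selecting the best of c candidate
        # positions, without which ~10% of windows on a constant-sigma
        # track sprout spurious breaks
        n_cand = max(window - 2 * margin, 1)
        break_penalty = 3 * np.log(m) + 2 * np.log(n_cand)
        best = None  # (break index, sigma2 left, sigma2 right)
        for p in range(k + margin, hi - margin):
            # the triple centred on the break fix goes to the left model so
            # both models sum the likelihood over the same m triples
            left = _loo_triples(times, x, y, err, max_lag_min, k, p + 2)
            right = _loo_triples(times, x, y, err, max_lag_min, p, hi)
            if left is None or right is None:
                continue
            s2_l, ll_l = _mle_sigma2(left, bounds, guard=False)
            s2_r, ll_r = _mle_sigma2(right, bounds, guard=False)
            bic = -2 * (ll_l + ll_r) + break_penalty
            if bic < bic_best:
                bic_best = bic
                best = (p, s2_l, s2_r)
        segs = np.arange(k, hi - 1)
        if best is None:
            acc[segs] += s2_full
            cnt[segs] += 1
            window_estimates.append((k, hi, s2_full))
        else:
            p, s2_l, s2_r = best
            left_segs = segs[segs < p]
            right_segs = segs[segs >= p]
            acc[left_segs] += s2_l
            acc[right_segs] += s2_r
            cnt[left_segs] += 1
            cnt[right_segs] += 1
            breakpoints.append(p)
            window_estimates.append((k, hi, np.nan))

    if (cnt == 0).any():
        # segments never covered (max_lag exclusions); fall back to static
        sigma2 = fit_motion_variance(track, max_lag_hours, bounds)
        acc[cnt == 0] = sigma2
        cnt[cnt == 0] = 1
    return MotionVarianceProfile(acc / cnt, breakpoints, window_estimates)


# ---------------------------------------------------------------------------
# Occurrence distributions


def _bridge_sd_max(dt: np.ndarray, sigma2: np.ndarray, err: np.ndarray) -> float:
    """Largest bridge SD over all segments (at mid-bridge) plus fix error."""
    if len(dt) == 0:
        return 0.0
    mid_var = dt * 0.25 * sigma2
    e2 = np.maximum(err[:-1], err[1:]) ** 2
    return float(np.sqrt((mid_var + e2).max()))


def default_grid(track: GpsTrack, sigma2: np.ndarray, cell: float = 30.0,
                 buffer_sds: float = 3.0) -> GridGeometry:
    """Grid covering the track's bounding box plus a bridge-SD buffer.

    The buffer is ``buffer_sds`` times the 99th percentile of the
    per-segment mid-bridge SD, and never less than one cell.
    """
    dt = np.diff(track.minutes())
    sig = np.broadcast_to(np.asarray(sigma2, dtype=float), dt.shape)
    mid_sd = np.sqrt(dt * 0.25 * sig + np.maximum(track.error_sd[:-1],
                                                  track.error_sd[1:]) ** 2)
    buf = max(buffer_sds * float(np.quantile(mid_sd, 0.99)), cell) if len(dt) else cell
    x_min = np.floor((track.x.min() - buf) / cell) * cell
    y_min = np.floor((track.y.min() - buf) / cell) * cell
    n_cols = int(np.ceil((track.x.max() + buf - x_min) / cell))
    n_rows = int(np.ceil((track.y.max() + buf - y_min) / cell))
    return GridGeometry(x_min, y_min, cell, max(n_rows, 1), max(n_cols, 1))


def _accumulate_bridge(height: np.ndarray, geom: GridGeometry,
                       x0: float, y0: float, x1: float, y1: float,
                       dt: float, sigma2: float, d0: float, d1: float,
                       weight: float, n_steps: int = QUADRATURE_STEPS) -> None:
    """Add one segment's time-integrated bridge density onto the grid."""
    xs = geom.x_centers()
    ys = geom.y_centers()
    a = (np.arange(n_steps) + 0.5) / n_steps
    for ak in a:
        mu_x = x0 + ak * (x1 - x0)
        mu_y = y0 + ak * (y1 - y0)
        var = dt * ak * (1 - ak) * sigma2 + ((1 - ak) * d0) ** 2 + (ak * d1) ** 2
        var = max(var, 1e-9)
        sd = np.sqrt(var)
        r = TRUNCATION_SDS * sd
        c0 = np.searchsorted(xs, mu_x - r)
        c1 = np.searchsorted(xs, mu_x + r)
        # y centers are descending: locate rows via the reversed array
        rr0 = geom.n_rows - np.searchsorted(ys[::-1], mu_y + r)
        rr1 = geom.n_rows - np.searchsorted(ys[::-1], mu_y - r)
        if c0 >= c1 or rr0 >= rr1:
            continue
        gx = np.exp(-0.5 * (xs[c0:c1] - mu_x) ** 2 / var)
        gy = np.exp(-0.5 * (ys[rr0:rr1] - mu_y) ** 2 / var)
        height[rr0:rr1, c0:c1] += (weight / n_steps / (2 * np.pi * var)) * np.outer(gy, gx)


def occurrence_distribution(track: GpsTrack,
                            profile: MotionVarianceProfile | float | np.ndarray,
                            geometry: GridGeometry | None = None,
                            state: str | None = None,
                            od_level: float = 0.99,
                            cell: float = 30.0,
                            max_lag_hours: float | None = None,
                            quadrature_steps: int = QUADRATURE_STEPS,
                            period: str = "") -> OccurrenceDistribution:
    """Time-integrated bridge density over a grid, normalized to 1.

    With ``state`` set, only segments whose *both* endpoint fixes carry
    that activity state contribute (mixed segments are dropped). Segments
    longer than ``max_lag_hours`` are skipped entirely. Each retained
    segment is weighted by its duration and integrated with a midpoint
    rule in ``quadrature_steps`` equal time steps.
    """
    if isinstance(profile, MotionVarianceProfile):
        sigma2 = profile.sigma2
    else:
        sigma2 = np.atleast_1d(np.asarray(profile, dtype=float))
        if sigma2.size == 1:
            sigma2 = np.full(max(track.n_fixes - 1, 0), float(sigma2[0]))
    if len(sigma2) != track.n_fixes - 1:
        raise ValueError("motion-variance profile is not aligned to the track")

    times = track.minutes()
    dt = np.diff(times)
    keep = np.ones(len(dt), dtype=bool)
    if state is not None:
        keep &= (track.activity[:-1] == state) & (track.activity[1:] == state)
    if max_lag_hours is not None:
        keep &= dt <= max_lag_hours * 60.0
    if not keep.any():
        raise ValueError(
            f"no usable segments for individual {track.individual!r}"
            + (f" in state {state!r}" if state else ""))

    if geometry is None:
        geometry = default_grid(track, sigma2, cell)

    height = np.zeros(geometry.shape)
    idx = np.flatnonzero(keep)
    for i in idx:
        _accumulate_bridge(height, geometry,
                           track.x[i], track.y[i], track.x[i + 1], track.y[i + 1],
                           float(dt[i]), float(sigma2[i]),
                           float(track.error_sd[i]), float(track.error_sd[i + 1]),
                           weight=float(dt[i]), n_steps=quadrature_steps)
    total = height.sum()
    if total <= 0:
        raise ValueError(f"empty occurrence surface for {track.individual!r}; "
                         "grid does not cover the track")
    height /= total
    mask = od_contour(height, od_level)
    return OccurrenceDistribution(geometry, height, mask, od_level,
                                  individual=track.individual,
                                  species=track.species,
                                  period=period, state=state or "all")


def od_contour(height: np.ndarray, level: float) -> np.ndarray:
    """Smallest set of cells whose summed height reaches ``level``.

    Cells are ranked by height; ties at the threshold height are all
    included, so the mask's total is always >= level.
    """
    flat = height.ravel()
    order = np.argsort(flat)[::-1]
    csum = np.cumsum(flat[order])
    k = int(np.searchsorted(csum, level * (1 - 1e-12)))
    k = min(k, len(flat) - 1)
    threshold = flat[order[k]]
    mask = flat >= threshold if threshold > 0 else flat > 0
    return mask.reshape(height.shape)


def fit_vhf_od(track: GpsTrack, max_lag_hours: float = 48.0,
               geometry: GridGeometry | None = None,
               od_level: float = 0.99, cell: float = 30.0,
               period: str = "") -> OccurrenceDistribution:
    """Static BBMM occurrence distribution for sparse VHF relocations.

    One motion variance for the whole track; leave-one-out triples and
    bridge segments spanning more than ``max_lag_hours`` are excluded so
    only related consecutive relocations shape the surface.
    """
    sigma2 = fit_motion_variance(track, max_lag_hours)
    return occurrence_distribution(track, sigma2, geometry=geometry,
                                   state=None, od_level=od_level, cell=cell,
                                   max_lag_hours=max_lag_hours, period=period)
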
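"""Resource utilization functions (RUFs) and their validation.

A RUF regresses the height of one animal's occurrence distribution (OD)
on landscape and prey covariates over the cells inside the OD's 99%
contour -- the area treated as available to that animal. Continuous
covariates are z-scored over the used cells so standardized slopes are
comparable across individuals; categorical land cover is dummy-coded
against a deciduous-forest reference.

Population-level inference averages the individual coefficients,

    beta_bar_i = (1/n) sum_j beta_ij,
    Var(beta_bar_i) = 1/(n-1) sum_j (beta_ij - beta_bar_i)^2,

treating individuals as random draws from the population so the
variance carries both intra- and inter-individual variation. Confidence
intervals and p-values use a t distribution with n - 1 df.

Model fit is scored by leave-one-individual-out cross-validation: the
withheld animal's OD is predicted from the others' population RUF, the
paired (predicted, observed) cells are sorted by prediction and split
into eight equal-count bins, and summed OD is regressed on summed
prediction across bins; a positive slope and high R^2 indicate a model
that ranks space use correctly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .grids import LAND_COVER_CLASSES, LandscapeStack
from .movement import OccurrenceDistribution

REFERENCE_CLASS = "deciduous"


@dataclass
class RufFit:
    """One individual's OD-on-covariates regression."""

    individual: str
    species: str
    period: str
    state: str
    coef_std: pd.Series       # standardized coefficients incl. "intercept"
    se_std: pd.Series
    coef_unstd: pd.Series     # on raw covariate scales, for prediction
    n_cells: int
    covariates: list[str] = field(default_factory=list)


@dataclass
class PopulationRuf:
    """Population mean/variance of individual RUF coefficients."""

    species: str
    period: str
    state: str
    n: int
    table: pd.DataFrame       # per covariate: mean, var, se, ci_lo, ci_hi, p
    coef_unstd_mean: pd.Series


@dataclass
class CvResult:
    folds: pd.DataFrame       # per withheld individual: slope, r2
    mean_slope: float
    mean_r2: float
    bins: int


def screen_covariates(stack: LandscapeStack,
                      candidates: list[str] | None = None,
                      cutoff: float = 0.7,
                      priority: tuple[str, ...] = (),
                      mask: np.ndarray | None = None) -> list[str]:
    """Drop one covariate of every highly correlated pair (|r| > cutoff).

    Pearson r is computed over in-mask cells. When two covariates
    conflict, the one later in ``priority`` (less ecologically relevant)
    is dropped; a conflict involving a covariate absent from the
    priority list is a configuration error. Categorical land cover never
    enters the screen. The retained names keep their input order.
    """
    names = list(candidates) if candidates is not None else stack.continuous_names()
    if len(names) < 2:
        return names
    flat_mask = (np.ones(stack.geometry.shape, dtype=bool) if mask is None
                 else np.asarray(mask, dtype=bool))
    data = np.column_stack([stack[n][flat_mask] for n in names])
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(data, rowvar=False)
    corr = np.nan_to_num(corr, nan=0.0)

    conflicts = [(names[i], names[j])
                 for i in range(len(names)) for j in range(i + 1, len(names))
                 if abs(corr[i, j]) > cutoff]
    involved = {n for pair in conflicts for n in pair}
    missing = involved - set(priority)
    if missing:
        raise ValueError(f"covariate priority order does not cover: {sorted(missing)}")

    rank = {n: k for k, n in enumerate(priority)}
    dropped: set[str] = set()
    for a, b in sorted(conflicts, key=lambda p: min(rank[p[0]], rank[p[1]])):
        if a in dropped or b in dropped:
            continue
        dropped.add(b if rank[a] < rank[b] else a)
    return [n for n in names if n not in dropped]


def _design(od: OccurrenceDistribution, stack: LandscapeStack,
            covariates: list[str]) -> tuple[np.ndarray, pd.DataFrame, pd.Series, pd.Series]:
    """Response and standardized design over the OD's in-mask cells."""
    if stack.geometry != od.geometry:
        raise ValueError("OD and landscape stack are on different grids")
    mask = od.level_mask
    y = od.height[mask]
    cols: dict[str, np.ndarray] = {}
    means, sds = {}, {}
    for name in covariates:
        vals = stack[name][mask].astype(float)
        mu, sd = float(vals.mean()), float(vals.std())
        if sd == 0:
            warnings.warn(f"covariate {name!r} is constant over used cells; dropped",
                          stacklevel=3)
            continue
        cols[name] = (vals - mu) / sd
        means[name], sds[name] = mu, sd
    if stack.land_cover is not None:
        lc = stack.land_cover[mask]
        for code, cls in enumerate(LAND_COVER_CLASSES):
            if cls == REFERENCE_CLASS:
                continue
            dummy = (lc == code).astype(float)
            if dummy.sum() in (0, len(dummy)):
                continue          # class absent (or the only class) here
            cols[f"lc_{cls}"] = dummy
            means[f"lc_{cls}"], sds[f"lc_{cls}"] = 0.0, 1.0
    X = pd.DataFrame(cols)
    return y, X, pd.Series(means), pd.Series(sds)


def fit_individual_ruf(od: OccurrenceDistribution, stack: LandscapeStack,
                       covariates: list[str]) -> RufFit:
    """OLS of OD height on standardized covariates over in-mask cells."""
    y, X, means, sds = _design(od, stack, covariates)
    if len(y) <= X.shape[1] + 1:
        raise ValueError(f"individual {od.individual!r}: fewer cells than parameters")
    # drop collinear dummies before fitting so SEs stay defined
    design = sm.add_constant(X, prepend=True, has_constant="add")
    rank = np.linalg.matrix_rank(design.to_numpy())
    while rank < design.shape[1]:
        dummy_cols = [c for c in design.columns if c.startswith("lc_")]
        if not dummy_cols:
            raise ValueError("rank-deficient design with no droppable dummies")
        drop = dummy_cols[-1]
        warnings.warn(f"dropping collinear land-cover dummy {drop!r}", stacklevel=2)
        design = design.drop(columns=drop)
        rank = np.linalg.matrix_rank(design.to_numpy())
    fit = sm.OLS(y, design).fit()
    coef_std = fit.params.rename({"const": "intercept"})
    se_std = fit.bse.rename({"const": "intercept"})
    # back-transform to raw covariate scales for landscape prediction
    coef_unstd = coef_std.copy()
    for name in coef_std.index:
        if name == "intercept":
            continue
        coef_unstd[name] = coef_std[name] / sds[name]
        coef_unstd["intercept"] -= coef_std[name] * means[name] / sds[name]
    kept = [c for c in design.columns if c != "const"]
    return RufFit(od.individual, od.species, od.period, od.state,
                  coef_std=coef_std, se_std=se_std, coef_unstd=coef_unstd,
                  n_cells=int(len(y)), covariates=kept)


def population_ruf(fits: list[RufFit], alpha: float = 0.05) -> PopulationRuf:
    """Average individual coefficients into a population RUF.

    Implements the random-individual estimator: the population
    coefficient is the plain mean across individuals and its variance is
    the between-individual sample variance (see module docstring).
    Covariates missing from an individual fit (e.g., a land-cover class
    absent from its range) contribute 0 for that individual.
    """
    if len(fits) < 2:
        raise ValueError("population RUF needs at least two individuals")
    names = sorted({n for f in fits for n in f.coef_std.index},
                   key=lambda n: (n != "intercept", n))
    betas = pd.DataFrame(
        [[f.coef_std.get(n, 0.0) for n in names] for f in fits],
        columns=names, index=[f.individual for f in fits])
    n = len(fits)
    mean = betas.mean(axis=0)
    var = betas.var(axis=0, ddof=1)
    se = np.sqrt(var / n)
    t_crit = stats.t.ppf(1 - alpha / 2, df=n - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_stat = mean / se
    p = 2 * stats.t.sf(np.abs(t_stat), df=n - 1)
    table = pd.DataFrame({
        "mean": mean, "var": var, "se": se,
        "ci_lo": mean - t_crit * se, "ci_hi": mean + t_crit * se,
        "t": t_stat, "p": p, "n": n,
    })
    unstd = pd.DataFrame(
        [[f.coef_unstd.get(nm, 0.0) for nm in names] for f in fits],
        columns=names).mean(axis=0)
    f0 = fits[0]
    return PopulationRuf(f0.species, f0.period, f0.state, n, table, unstd)


def predict_surface(popruf: PopulationRuf, stack: LandscapeStack) -> np.ndarray:
    """Relative predicted occurrence over the landscape, rescaled to [0, 1].

    Builds the linear predictor from the unstandardized population-mean
    coefficients; the min-max rescaled surface serves as a relative-use
    layer (e.g., the wolf surface supplied to coyote RUFs).
    """
    coefs = popruf.coef_unstd_mean
    pred = np.full(stack.geometry.shape, float(coefs.get("intercept", 0.0)))
    for name, beta in coefs.items():
        if name == "intercept":
            continue
        if name.startswith("lc_"):
            cls = name[3:]
            if stack.land_cover is None:
                raise ValueError("model uses land cover but stack has none")
            code = LAND_COVER_CLASSES.index(cls)
            pred += beta * (stack.land_cover == code)
        else:
            if name not in stack:
                raise ValueError(f"stack is missing model covariate {name!r}")
            pred += beta * stack[name]
    lo, hi = float(pred.min()), float(pred.max())
    if hi > lo:
        pred = (pred - lo) / (hi - lo)
    else:
        pred = np.zeros_like(pred)
    return pred


def binned_validation(observed: np.ndarray, predicted: np.ndarray,
                      bins: int = 8) -> tuple[float, float]:
    """Slope and R^2 of summed-OD on summed-prediction across rank bins.

    Pairs are sorted by prediction and split into ``bins`` groups of
    equal cell counts (remainder cells go to the last bin); per-bin sums
    are then related by simple linear regression.
    """
    sum_obs, sum_pred = bin_sums(observed, predicted, bins)
    slope, intercept, r, _, _ = stats.linregress(sum_pred, sum_obs)
    return float(slope), float(r ** 2)


def bin_sums(observed: np.ndarray, predicted: np.ndarray,
             bins: int = 8) -> tuple[np.ndarray, np.ndarray]:
    """Per-bin sums after sorting pairs by prediction.

    Bins hold equal cell counts (n // bins); remainder cells go to the
    last (highest-prediction) bin.
    """
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    n = len(observed)
    if n < bins:
        raise ValueError(f"need at least {bins} cells, got {n}")
    order = np.argsort(predicted, kind="stable")
    obs, pred = observed[order], predicted[order]
    size = n // bins
    edges = [k * size for k in range(bins)] + [n]
    sum_obs = np.array([obs[edges[k]:edges[k + 1]].sum() for k in range(bins)])
    sum_pred = np.array([pred[edges[k]:edges[k + 1]].sum() for k in range(bins)])
    return sum_obs, sum_pred


def loio_cv(fits: list[RufFit], ods: list[OccurrenceDistribution],
            stack: LandscapeStack, bins: int = 8,
            alpha: float = 0.05) -> CvResult:
    """Leave-one-individual-out cross-validation of a population RUF.

    ``fits`` and ``ods`` must be aligned (same individuals, same order).
    Each fold refits the population RUF without one individual, predicts
    the landscape, and scores the withheld OD by 8-bin regression over
    the cells inside that OD's contour mask.
    """
    if len(fits) != len(ods) or len(fits) < 3:
        raise ValueError("need aligned fits/ODs for at least three individuals")
    rows = []
    for k, (fit, od) in enumerate(zip(fits, ods)):
        train = fits[:k] + fits[k + 1:]
        pop = population_ruf(train, alpha=alpha)
        surface = predict_surface(pop, stack)
        mask = od.level_mask
        obs = od.height[mask]
        pred = surface[mask]
        if len(obs) < bins:
            warnings.warn(f"fold {fit.individual!r}: fewer than {bins} "
                          "overlapping cells; fold skipped", stacklevel=2)
            continue
        slope, r2 = binned_validation(obs, pred, bins)
        rows.append({"individual": fit.individual, "slope": slope, "r2": r2})
    if not rows:
        raise ValueError("every cross-validation fold was skipped")
    folds = pd.DataFrame(rows)
    return CvResult(folds, float(folds["slope"].mean()),
                    float(folds["r2"].mean()), bins)
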
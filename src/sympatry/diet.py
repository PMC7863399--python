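"""Scat-based diet analysis: species assignment, percent-volume
proportions, Levins-style dietary breadth and Pianka food-niche overlap.

Scats are assigned to wolf or coyote by associated tracks when present;
otherwise by diameter, with an exclusion band (strictly between 28.1 and
29.0 mm) where the two species' diameter distributions overlap too much
to call. Diet proportions p_i are means over scats of per-scat volume
fractions. Breadth B = 1 / sum(p_i^2) ranges from 1 (single item) to the
number of items (uniform diet). Overlap is Pianka's symmetric index

    alpha = sum(p_i q_i) / sqrt(sum(p_i^2) * sum(q_i^2)),

bounded in [0, 1] with 1 for identical diets and 0 for disjoint ones.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

PREY_ITEMS = ("deer_adult", "deer_fawn", "hare", "grouse", "rodent", "seeds", "other")

#: Diameter (mm) at or below which a track-unconfirmed scat is coyote,
#: and at or above which it is wolf; strictly between, it is excluded.
COYOTE_MAX_DIAMETER = 28.1
WOLF_MIN_DIAMETER = 29.0


@dataclass
class DietSummary:
    species: str
    period: str | None
    p: pd.Series            # proportion per prey item, sums to 1
    n_scats: int
    breadth: float | None = None
    overlap: float | None = None


def assign_scat_species(diameter_mm: float, track_species: str = "none") -> str:
    """Assign one scat to wolf/coyote, or exclude it.

    Track evidence dominates: a scat with confirmed tracks takes that
    species regardless of diameter. Otherwise diameter decides, with the
    28.1-29.0 mm band excluded as ambiguous.
    """
    if not np.isfinite(diameter_mm) or diameter_mm <= 0:
        raise ValueError("scat diameter must be positive")
    if track_species in ("wolf", "coyote"):
        return track_species
    if track_species not in ("none", "", None):
        raise ValueError(f"unknown track species {track_species!r}")
    if diameter_mm <= COYOTE_MAX_DIAMETER:
        return "coyote"
    if diameter_mm >= WOLF_MIN_DIAMETER:
        return "wolf"
    return "excluded"


def assign_scat_table(scats: pd.DataFrame) -> pd.DataFrame:
    """Add an ``assigned_species`` column to a long-format scat table."""
    per_scat = scats.drop_duplicates("id")[["id", "diameter_mm", "track_species"]]
    assigned = {
        row.id: assign_scat_species(row.diameter_mm, str(row.track_species))
        for row in per_scat.itertuples()
    }
    out = scats.copy()
    out["assigned_species"] = out["id"].map(assigned)
    return out


def diet_proportions(scats: pd.DataFrame, species: str,
                     period: str | None = None,
                     pooled: bool = False) -> DietSummary:
    """Mean per-scat volume fractions for one species (and period).

    ``pooled=False`` (default) averages each scat's fractions so every
    scat carries equal weight, matching how per-item percent means are
    reported; ``pooled=True`` sums volumes across scats before
    normalizing.
    """
    df = scats
    if "assigned_species" not in df.columns:
        df = assign_scat_table(df)
    df = df[df["assigned_species"] == species]
    if period is not None and "period" in df.columns:
        df = df[df["period"] == period]
    if df.empty:
        raise ValueError(f"no scats assigned to {species!r}"
                         + (f" in period {period!r}" if period else ""))
    wide = (df.pivot_table(index="id", columns="item", values="volume_fraction",
                           aggfunc="sum", fill_value=0.0)
            .reindex(columns=list(PREY_ITEMS), fill_value=0.0))
    if pooled:
        p = wide.sum(axis=0)
    else:
        p = wide.mean(axis=0)
    p = p / p.sum()
    return DietSummary(species=species, period=period, p=p, n_scats=len(wide))


def dietary_breadth(p: np.ndarray | pd.Series) -> float:
    """Levins-style breadth B = 1 / sum(p_i^2)."""
    p = np.asarray(p, dtype=float)
    if abs(p.sum() - 1.0) > 1e-6 or (p < 0).any():
        raise ValueError("p must be a proportion vector summing to 1")
    return float(1.0 / np.sum(p * p))


def food_niche_overlap(p: np.ndarray | pd.Series, q: np.ndarray | pd.Series) -> float:
    """Pianka's symmetric overlap alpha between two diet vectors."""
    if isinstance(p, pd.Series) and isinstance(q, pd.Series):
        if list(p.index) != list(q.index):
            raise ValueError("diet vectors are over different item sets")
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError("diet vectors are over different item sets")
    denom = np.sqrt(np.sum(p * p) * np.sum(q * q))
    if denom == 0:
        raise ValueError("degenerate (all-zero) diet vector")
    return float(np.sum(p * q) / denom)


def compare_item_volumes(scats: pd.DataFrame) -> pd.DataFrame:
    """One-way ANOVA per prey item on per-scat volume fractions, wolf vs coyote.

    Returns one row per prey item with species means (percent), SDs, the
    F statistic and p-value, and the coyote:wolf ratio of means.
    """
    df = scats
    if "assigned_species" not in df.columns:
        df = assign_scat_table(df)
    wide = (df[df["assigned_species"].isin(["wolf", "coyote"])]
            .pivot_table(index=["id", "assigned_species"], columns="item",
                         values="volume_fraction", aggfunc="sum", fill_value=0.0)
            .reindex(columns=list(PREY_ITEMS), fill_value=0.0)
            .reset_index("assigned_species"))
    rows = []
    for item in PREY_ITEMS:
        w = wide.loc[wide["assigned_species"] == "wolf", item].to_numpy()
        c = wide.loc[wide["assigned_species"] == "coyote", item].to_numpy()
        if len(w) < 2 or len(c) < 2:
            raise ValueError("need at least two scats per species for ANOVA")
        if np.ptp(np.concatenate([w, c])) == 0:
            f_stat, p_val = 0.0, 1.0
        else:
            f_stat, p_val = stats.f_oneway(c, w)
        rows.append({
            "item": item,
            "coyote_mean_pct": 100.0 * c.mean(),
            "coyote_sd_pct": 100.0 * c.std(ddof=1),
            "wolf_mean_pct": 100.0 * w.mean(),
            "wolf_sd_pct": 100.0 * w.std(ddof=1),
            "F": float(f_stat),
            "p": float(p_val),
            "coyote_wolf_ratio": float(c.mean() / w.mean()) if w.mean() > 0 else np.inf,
        })
    return pd.DataFrame(rows)
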
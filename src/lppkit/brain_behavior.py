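"""Individual-difference correlations between rating and LPP contrast scores.

For each of three instruction contrasts (Enhance-Suppress, View-Suppress,
View-Enhance) crossed with three valence scopes (pooled, pleasant,
unpleasant), the per-subject behavioural contrast (difference of mean
intensity ratings) is correlated with the matching LPP contrast, reporting
Pearson r, its two-sided p-value, and a default-Bayes correlation BF01.
Complete-case analysis per cell; cells with fewer than 4 complete subjects
are omitted with a log entry.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .bayes import jzs_correlation_bf01
from .config import DEFAULT_PRIOR_SCALE
from .io import validate_means

logger = logging.getLogger(__name__)

BB_CONTRASTS = {
    "enhance_minus_suppress": ("enhance", "suppress"),
    "view_minus_suppress": ("view", "suppress"),
    "view_minus_enhance": ("view", "enhance"),
}
SCOPES = ("pooled", "pleasant", "unpleasant")


@dataclass(frozen=True)
class BrainBehaviorResult:
    contrast: str
    valence_scope: str
    r: float
    p: float
    bf01: float
    n: int


def _subject_instruction_table(df: pd.DataFrame, value_col: str, scope: str) -> pd.DataFrame:
    sub = df[df["valence"].isin(["pleasant", "unpleasant"])] if scope == "pooled" else df[df["valence"] == scope]
    return (
        sub.groupby(["subject_id", "instruction"], observed=True)[value_col].mean().unstack()
    )


def rating_cell_means(trials: pd.DataFrame) -> pd.DataFrame:
    """Subject x valence x instruction mean intensity rating from a trial table."""
    rated = trials[trials["rating"].notna()].copy()
    rated["rating"] = rated["rating"].astype(float)
    return (
        rated.groupby(["subject_id", "valence", "instruction"], observed=True)["rating"]
        .mean()
        .rename("rating_mean")
        .reset_index()
    )


def brain_behavior_correlations(
    ratings: pd.DataFrame,
    means: pd.DataFrame,
    prior_scale: float = DEFAULT_PRIOR_SCALE,
) -> list[BrainBehaviorResult]:
    """The 3 x 3 grid of rating-LPP difference-score correlations.

    ``ratings`` is either a trial table (with a ``rating`` column) or an
    already-aggregated table with a ``rating_mean`` column; ``means`` is the
    subject x condition LPP table.
    """
    if "rating_mean" not in ratings.columns:
        ratings = rating_cell_means(ratings)
    means = validate_means(means)
    out: list[BrainBehaviorResult] = []
    for scope in SCOPES:
        r_tab = _subject_instruction_table(ratings, "rating_mean", scope)
        l_tab = _subject_instruction_table(means, "lpp_uv", scope)
        for name, (a, b) in BB_CONTRASTS.items():
            if not {a, b} <= set(r_tab.columns) or not {a, b} <= set(l_tab.columns):
                logger.warning("brain-behavior cell %s/%s lacks instruction cells; omitted", name, scope)
                continue
            beh = (r_tab[a] - r_tab[b]).dropna()
            neu = (l_tab[a] - l_tab[b]).dropna()
            common = beh.index.intersection(neu.index)
            if len(common) < 4:
                logger.warning(
                    "brain-behavior cell %s/%s has %d complete cases (<4); omitted",
                    name, scope, len(common),
                )
                continue
            x = beh.loc[common].to_numpy(dtype=float)
            y = neu.loc[common].to_numpy(dtype=float)
            r, p = stats.pearsonr(x, y)
            bf = jzs_correlation_bf01(float(np.clip(r, -0.999999, 0.999999)), len(common), prior_scale)
            out.append(
                BrainBehaviorResult(
                    contrast=name,
                    valence_scope=scope,
                    r=float(r),
                    p=float(p),
                    bf01=bf.bf01,
                    n=len(common),
                )
            )
    return out


def grid_frame(results: list[BrainBehaviorResult]) -> pd.DataFrame:
    """Long-format frame of the correlation grid for TSV export."""
    return pd.DataFrame([r.__dict__ for r in results])
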
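"""Robustness resampling: sequential Bayes factors and bootstrap effect sizes.

Both operate on the per-subject contrast scores (the analysis unit of the
whole pipeline), never on trials.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .bayes import jzs_ttest_bf01
from .config import DEFAULT_PRIOR_SCALE
from .freq_stats import one_sample_t
from .model import ContrastScores

logger = logging.getLogger(__name__)

#: dz assigned to a zero-variance bootstrap resample (rare-event guard).
DEGENERATE_DZ = 1e6


@dataclass
class SequentialBFTrace:
    """Median BF01 and 5th-95th percentile band across subject orderings."""

    n_grid: np.ndarray
    median: dict[str, np.ndarray]
    band_lo: dict[str, np.ndarray]
    band_hi: dict[str, np.ndarray]
    n_orderings: int


@dataclass
class BootstrapDistribution:
    name: str
    dz: np.ndarray
    ci95: tuple[float, float]
    prop_above_zero: float
    n_degenerate: int


def _bf01_of_prefix(values: np.ndarray, n_grid: np.ndarray, prior_scale: float) -> np.ndarray:
    """BF01 of the one-sample t over the first n values, for each n in the grid."""
    c1 = np.cumsum(values)
    c2 = np.cumsum(values**2)
    out = np.empty(len(n_grid))
    for i, n in enumerate(n_grid):
        mean = c1[n - 1] / n
        var = (c2[n - 1] - n * mean**2) / (n - 1)
        if var <= 0:
            out[i] = np.nan
            continue
        t = mean / np.sqrt(var / n)
        out[i] = jzs_ttest_bf01(t, int(n), prior_scale).bf01
    return out


def sequential_bf(
    scores: ContrastScores,
    n_start: int = 20,
    n_orderings: int = 500,
    seed: int = 0,
    step: int = 1,
    prior_scale: float = DEFAULT_PRIOR_SCALE,
) -> SequentialBFTrace:
    """Sequential Bayes-factor traces over random subject orderings.

    For each random permutation of subjects, BF01 is recomputed on the first
    ``n`` subjects for every ``n`` in ``n_start..N`` (grid step
    configurable); the central trace is the median across orderings and the
    band the 5th-95th percentiles.  With a single ordering the identity
    permutation is used, making the full-grid endpoint exactly the
    full-sample BF01.
    """
    if n_start < 4:
        raise ValueError("n_start must be >= 4 (Bayes factor unstable below)")
    n_total = scores.n
    if n_start > n_total:
        raise ValueError(f"n_start={n_start} exceeds the {n_total} available subjects")
    if n_orderings < 1:
        raise ValueError("n_orderings must be >= 1")
    n_grid = np.arange(n_start, n_total + 1, step)
    if n_grid[-1] != n_total:
        n_grid = np.append(n_grid, n_total)

    master = np.random.SeedSequence(seed)
    rngs = [np.random.default_rng(s) for s in master.spawn(n_orderings)]

    traces = {name: np.empty((n_orderings, len(n_grid))) for name in ("reappraisal", "load")}
    for name in traces:
        vals = scores.values(name)
        for oi in range(n_orderings):
            order = np.arange(n_total) if n_orderings == 1 else rngs[oi].permutation(n_total)
            traces[name][oi] = _bf01_of_prefix(vals[order], n_grid, prior_scale)

    med = {k: np.nanmedian(v, axis=0) for k, v in traces.items()}
    lo = {k: np.nanpercentile(v, 5, axis=0) for k, v in traces.items()}
    hi = {k: np.nanpercentile(v, 95, axis=0) for k, v in traces.items()}
    return SequentialBFTrace(n_grid=n_grid, median=med, band_lo=lo, band_hi=hi, n_orderings=n_orderings)


def bootstrap_dz(
    values: np.ndarray, n_boot: int = 10_000, seed: int = 0, name: str = "contrast"
) -> BootstrapDistribution:
    """Bootstrap the within-subject effect size dz by resampling subjects.

    Subjects are resampled with replacement ``n_boot`` times; each resample's
    dz = mean/sd is recorded; the 95% CI is the 2.5th/97.5th percentile of
    the resampled values.  A zero-variance resample is assigned
    ``sign(mean) * 1e6`` and counted (rare-event guard).
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    if n < 2:
        raise ValueError("need at least 2 subjects")
    if n_boot < 1000:
        raise ValueError("n_boot must be >= 1000 for stable percentile CIs")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    draws = values[idx]
    means = draws.mean(axis=1)
    sds = draws.std(axis=1, ddof=1)
    degenerate = sds == 0
    dz = np.empty(n_boot)
    dz[~degenerate] = means[~degenerate] / sds[~degenerate]
    dz[degenerate] = np.sign(means[degenerate]) * DEGENERATE_DZ
    n_deg = int(degenerate.sum())
    if n_deg:
        logger.warning("bootstrap_dz: %d degenerate (zero-variance) resamples", n_deg)
    ci = (float(np.percentile(dz, 2.5)), float(np.percentile(dz, 97.5)))
    return BootstrapDistribution(
        name=name,
        dz=dz,
        ci95=ci,
        prop_above_zero=float((dz > 0).mean()),
        n_degenerate=n_deg,
    )
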
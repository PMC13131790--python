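"""Frequentist inference implemented from the sums-of-squares formulas.

Fully within-subject repeated-measures ANOVA (one or two factors) with
Greenhouse-Geisser sphericity correction and generalized eta-squared, plus
classical paired/one-sample t-tests with the within-subject effect size
dz = t / sqrt(n) and its normal-approximation 95% CI.

The ANOVA uses the orthonormal-contrast formulation: for an effect with
orthonormal contrast matrix M over the design cells, the per-subject effect
scores Z = Y M give SS_effect = n ||mean(Z)||^2 and the matching error term
SS_err = sum_s ||Z_s - mean(Z)||^2; Box's epsilon-hat is computed from the
covariance of Z.  Generalized eta-squared treats all (within-subject) factors
as manipulated: SS_effect / (SS_effect + SS_subjects + sum of all error SS).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: int
    p: float
    mean_diff: float
    dz: float
    dz_ci95: tuple[float, float]
    n: int


@dataclass(frozen=True)
class AnovaResult:
    effect: str
    F: float
    df_num: int
    df_den: int
    epsilon_gg: float
    p_gg: float
    eta_g_sq: float
    p_uncorrected: float


def one_sample_t(d: np.ndarray) -> TTestResult:
    """One-sample t-test of ``mean(d) = 0`` with dz and its 95% CI.

    dz = mean(d)/sd(d) = t/sqrt(n); CI by the normal approximation
    dz +/- 1.96 * sqrt(1/n + dz^2/(2n)).
    """
    d = np.asarray(d, dtype=float)
    n = d.size
    if n < 2:
        raise ValueError("need at least 2 observations")
    sd = d.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance of differences: t undefined")
    m = d.mean()
    t = m / (sd / math.sqrt(n))
    dz = t / math.sqrt(n)
    se_dz = math.sqrt(1.0 / n + dz * dz / (2.0 * n))
    ci = (dz - 1.96 * se_dz, dz + 1.96 * se_dz)
    p = 2.0 * stats.t.sf(abs(t), n - 1)
    return TTestResult(t=float(t), df=n - 1, p=float(p), mean_diff=float(m), dz=float(dz), dz_ci95=ci, n=n)


def paired_t(x: np.ndarray, y: np.ndarray) -> TTestResult:
    """Classical paired t-test of condition A vs condition B."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    return one_sample_t(x - y)


# ---------------------------------------------------------------------------
# Repeated-measures ANOVA
# ---------------------------------------------------------------------------

def _orthonormal_contrasts(k: int) -> np.ndarray:
    """A k x (k-1) orthonormal basis of the subspace orthogonal to the unit vector."""
    q, _ = np.linalg.qr(np.column_stack([np.ones(k), np.eye(k)[:, : k - 1]]))
    return q[:, 1:]


def _effect_matrices(level_counts: list[int]) -> dict[str, np.ndarray]:
    """Orthonormal cell-space contrast matrix for each main effect/interaction.

    Cells are ordered lexicographically over factor levels.  Effect names are
    factor indices joined by ':' and are relabelled by the caller.
    """
    parts = []
    for k in level_counts:
        parts.append((np.ones((k, 1)) / math.sqrt(k), _orthonormal_contrasts(k)))
    effects: dict[str, np.ndarray] = {}
    n_fac = len(level_counts)
    for mask in itertools.product([0, 1], repeat=n_fac):
        if not any(mask):
            continue
        m = np.ones((1, 1))
        for fi in range(n_fac):
            m = np.kron(m, parts[fi][mask[fi]])
        name = ":".join(str(fi) for fi in range(n_fac) if mask[fi])
        effects[name] = m
    return effects


def rm_anova(
    data: pd.DataFrame,
    dv: str,
    within: list[str],
    subject: str = "subject_id",
) -> list[AnovaResult]:
    """Fully within-subject repeated-measures ANOVA (1 or 2 factors).

    Requires a complete balanced design: every subject must have exactly one
    value in every factor-level cell.  Returns one :class:`AnovaResult` per
    main effect and interaction with Greenhouse-Geisser-corrected p-values
    (epsilon fixed at 1 when the effect has a single numerator df) and
    generalized eta-squared.
    """
    if not 1 <= len(within) <= 2:
        raise ValueError("rm_anova supports one or two within-subject factors")
    levels = [sorted(data[f].unique()) for f in within]
    if any(len(lv) < 2 for lv in levels):
        raise ValueError("every factor needs at least 2 levels")
    wide = data.pivot_table(index=subject, columns=within, values=dv, aggfunc="mean", observed=True)
    expected = list(itertools.product(*levels)) if len(within) > 1 else list(levels[0])
    missing = wide.isna()
    if missing.to_numpy().any() or wide.shape[1] != len(expected):
        bad = [
            (str(s), str(c))
            for s in wide.index
            for c in wide.columns[missing.loc[s].to_numpy()]
        ]
        raise ValueError(f"incomplete design; missing subject/cell pairs: {bad[:10]}")
    wide = wide.reindex(columns=expected if len(within) > 1 else levels[0])
    y = wide.to_numpy(dtype=float)
    n = y.shape[0]
    if n < 2:
        raise ValueError("need at least 2 subjects")

    grand = y.mean()
    subj_means = y.mean(axis=1)
    n_cells = y.shape[1]
    ss_subjects = n_cells * float(((subj_means - grand) ** 2).sum())

    effects = _effect_matrices([len(lv) for lv in levels])
    comp = {}
    for name, m in effects.items():
        z = y @ m
        zbar = z.mean(axis=0)
        ss_eff = n * float(zbar @ zbar)
        resid = z - zbar
        ss_err = float((resid**2).sum())
        d = m.shape[1]
        if d == 1:
            eps = 1.0
        else:
            t_mat = np.cov(z, rowvar=False)
            tr = np.trace(t_mat)
            denom = d * float((t_mat**2).sum())
            eps = 1.0 / d if denom == 0 else float(tr * tr / denom)
            eps = min(1.0, max(1.0 / d, eps))
        comp[name] = (ss_eff, ss_err, d, eps)

    total_error = sum(c[1] for c in comp.values())
    results = []
    for name, (ss_eff, ss_err, d, eps) in comp.items():
        df_num = d
        df_den = d * (n - 1)
        if ss_err == 0:
            f_val = 0.0 if ss_eff == 0 else math.inf
        else:
            f_val = (ss_eff / df_num) / (ss_err / df_den)
        p_unc = float(stats.f.sf(f_val, df_num, df_den)) if math.isfinite(f_val) else 0.0
        p_gg = float(stats.f.sf(f_val, eps * df_num, eps * df_den)) if math.isfinite(f_val) else 0.0
        denom_g = ss_eff + ss_subjects + total_error
        eta_g = 0.0 if denom_g == 0 else ss_eff / denom_g
        label = " x ".join(within[int(i)] for i in name.split(":"))
        results.append(
            AnovaResult(
                effect=label,
                F=float(f_val),
                df_num=df_num,
                df_den=df_den,
                epsilon_gg=eps,
                p_gg=p_gg,
                eta_g_sq=float(eta_g),
                p_uncorrected=p_unc,
            )
        )
    return results
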
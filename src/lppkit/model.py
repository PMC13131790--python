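"""Orthogonal-contrast model comparison: reappraisal vs cognitive load vs null.

The scientific core of the package.  Per subject, two orthogonal planned
contrasts are computed from the instruction condition means of the LPP:

* reappraisal score = Enhance - Suppress (weights (0, 1, -1)),
* cognitive-load score = 2*View - Enhance - Suppress (weights (2, -1, -1)),

each tested against zero with a one-sample t-test and a JZS Bayes factor
(BF01).  The two weight vectors are orthogonal, so under exchangeable
condition noise the scores are uncorrelated and carry independent evidence:
a directional-regulation world puts signal on the first contrast, a
dual-task world puts signal on the second, and a null world on neither.

The decision rule formalises the verbal argument as an interpretive layer
(thresholds taken from the conventional 3 / (1/3) evidence categories,
configurable):

* ``cognitive_load`` -- load BF01 < 1/3 with positive mean load AND
  reappraisal BF01 > 1;
* ``reappraisal``    -- reappraisal BF01 < 1/3 with positive mean;
* ``null``           -- both BF01 > 3;
* ``indeterminate``  -- otherwise.

The statsmodels-style entry point is :class:`InstructionEffectModel`, whose
``fit()`` returns an :class:`AdjudicationResults` carrying both contrast
tests, the decision, and robustness methods (sequential Bayes factors and
bootstrap effect sizes).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bayes import BayesFactorResult, evidence_label, jzs_ttest_bf01
from .config import DEFAULT_PRIOR_SCALE, AnalysisConfig
from .freq_stats import TTestResult, one_sample_t
from .io import validate_means

logger = logging.getLogger(__name__)

CONTRAST_WEIGHTS = {
    "reappraisal": {"view": 0.0, "enhance": 1.0, "suppress": -1.0},
    "load": {"view": 2.0, "enhance": -1.0, "suppress": -1.0},
}


@dataclass
class ContrastScores:
    """Per-subject reappraisal and cognitive-load contrast scores (uV)."""

    scores: pd.DataFrame  # columns: subject_id, reappraisal, load
    valence_scope: str

    def __post_init__(self) -> None:
        need = {"subject_id", "reappraisal", "load"}
        if not need <= set(self.scores.columns):
            raise ValueError(f"scores frame must have columns {sorted(need)}")

    @property
    def n(self) -> int:
        return len(self.scores)

    def values(self, contrast: str) -> np.ndarray:
        return self.scores[contrast].to_numpy(dtype=float)


@dataclass
class ContrastInference:
    ttest: TTestResult
    bayes: BayesFactorResult
    evidence: str


@dataclass
class AdjudicationReport:
    reappraisal: ContrastInference
    load: ContrastInference
    decision: str
    rationale: str
    valence_scope: str
    n: int


def compute_contrasts(means: pd.DataFrame, scope: str = "pooled") -> ContrastScores:
    """Per-subject contrast scores from a subject x condition mean table.

    ``scope="pooled"`` averages the pleasant and unpleasant means within each
    instruction before applying the weights (linearity makes this equal to
    the mean of the two single-valence scores).  Subjects missing any
    required cell are excluded and logged.
    """
    means = validate_means(means)
    if scope == "pooled":
        sub = means[means["valence"].isin(["pleasant", "unpleasant"])]
        cell = (
            sub.groupby(["subject_id", "instruction"], observed=True)["lpp_uv"].mean().unstack()
        )
    elif scope in ("pleasant", "unpleasant"):
        sub = means[means["valence"] == scope]
        cell = sub.pivot(index="subject_id", columns="instruction", values="lpp_uv")
    else:
        raise ValueError(f"scope must be pooled/pleasant/unpleasant, got {scope!r}")

    needed = ["view", "enhance", "suppress"]
    missing_cols = [c for c in needed if c not in cell.columns]
    if missing_cols:
        raise ValueError(f"no subjects with instruction cells {missing_cols} in scope {scope!r}")
    complete = cell[needed].dropna()
    dropped = len(cell) - len(complete)
    if dropped:
        logger.warning("compute_contrasts: excluded %d subjects with missing cells", dropped)
    if complete.empty:
        raise ValueError("no subjects with complete view/enhance/suppress cells")

    frame = pd.DataFrame(
        {
            "subject_id": complete.index,
            "reappraisal": complete["enhance"].to_numpy() - complete["suppress"].to_numpy(),
            "load": 2.0 * complete["view"].to_numpy()
            - complete["enhance"].to_numpy()
            - complete["suppress"].to_numpy(),
        }
    ).reset_index(drop=True)
    return ContrastScores(scores=frame, valence_scope=scope)


def decide(
    bf_reappraisal: float,
    bf_load: float,
    mean_reappraisal: float,
    mean_load: float,
    alt_threshold: float = 1.0 / 3.0,
    null_threshold: float = 3.0,
) -> tuple[str, str]:
    """Pure decision function over the two BF01 values and contrast means."""
    if bf_load < alt_threshold and mean_load > 0 and bf_reappraisal > 1.0:
        return (
            "cognitive_load",
            f"load contrast favoured (BF01={bf_load:.3g} < {alt_threshold:.3g}, mean "
            f"{mean_load:+.2f} uV) while the reappraisal contrast does not "
            f"(BF01={bf_reappraisal:.3g} > 1)",
        )
    if bf_reappraisal < alt_threshold and mean_reappraisal > 0:
        return (
            "reappraisal",
            f"reappraisal contrast favoured (BF01={bf_reappraisal:.3g} < "
            f"{alt_threshold:.3g}, mean {mean_reappraisal:+.2f} uV)",
        )
    if bf_reappraisal > null_threshold and bf_load > null_threshold:
        return (
            "null",
            f"both contrasts favour the null (BF01 {bf_reappraisal:.3g} and "
            f"{bf_load:.3g} > {null_threshold:.3g})",
        )
    return (
        "indeterminate",
        f"evidence pattern (reappraisal BF01={bf_reappraisal:.3g}, load "
        f"BF01={bf_load:.3g}) matches no account decisively",
    )


def adjudicate(
    scores: ContrastScores,
    prior_scale: float = DEFAULT_PRIOR_SCALE,
    alt_threshold: float = 1.0 / 3.0,
    null_threshold: float = 3.0,
) -> AdjudicationReport:
    """Test both contrasts against zero and decide among the three accounts."""
    if scores.n < 2:
        raise ValueError("need at least 2 subjects")
    inf = {}
    for name in ("reappraisal", "load"):
        vals = scores.values(name)
        tt = one_sample_t(vals)
        bf = jzs_ttest_bf01(tt.t, tt.n, prior_scale)
        inf[name] = ContrastInference(ttest=tt, bayes=bf, evidence=evidence_label(bf).label)
    decision, rationale = decide(
        inf["reappraisal"].bayes.bf01,
        inf["load"].bayes.bf01,
        inf["reappraisal"].ttest.mean_diff,
        inf["load"].ttest.mean_diff,
        alt_threshold,
        null_threshold,
    )
    return AdjudicationReport(
        reappraisal=inf["reappraisal"],
        load=inf["load"],
        decision=decision,
        rationale=rationale,
        valence_scope=scores.valence_scope,
        n=scores.n,
    )


# ---------------------------------------------------------------------------
# Model / Results objects
# ---------------------------------------------------------------------------

class InstructionEffectModel:
    """Adjudicates instruction effects on the LPP from condition means.

    Parameters
    ----------
    means
        Long-format subject x valence x instruction LPP mean table
        (columns ``subject_id, valence, instruction, lpp_uv, n_trials``),
        typically the winsorized output of :func:`lppkit.lpp.lpp_amplitude`.
    scope
        Valence scope of the contrasts: ``"pooled"`` (default),
        ``"pleasant"`` or ``"unpleasant"``.
    prior_scale
        Cauchy prior scale of the contrast Bayes factors.

    Examples
    --------
    >>> model = InstructionEffectModel(means)           # doctest: +SKIP
    >>> res = model.fit()                               # doctest: +SKIP
    >>> res.decision                                    # doctest: +SKIP
    'cognitive_load'
    """

    def __init__(
        self,
        means: pd.DataFrame,
        scope: str = "pooled",
        prior_scale: float = DEFAULT_PRIOR_SCALE,
        alt_threshold: float = 1.0 / 3.0,
        null_threshold: float = 3.0,
    ):
        self.means = validate_means(means)
        self.scope = scope
        self.prior_scale = prior_scale
        self.alt_threshold = alt_threshold
        self.null_threshold = null_threshold
        self.scores = compute_contrasts(self.means, scope)

    @classmethod
    def from_epochs(cls, epochs, trials, config: AnalysisConfig | None = None, **kwargs):
        """Build the model straight from epoched data via the LPP pipeline."""
        from .lpp import average_reference, baseline_correct, lpp_amplitude, reject_artifacts, winsorize_table

        config = config or AnalysisConfig()
        eps = [epochs] if not isinstance(epochs, list) else epochs
        cleaned = []
        for ep in eps:
            ep = baseline_correct(ep, config.baseline_window)
            ep = average_reference(ep)
            ep, _ = reject_artifacts(ep, config.artifact_threshold_uv)
            cleaned.append(ep)
        means = lpp_amplitude(cleaned, trials, config.roi_channels, config.lpp_window)
        means = winsorize_table(means, config.winsor_limits, config.winsor_scope)
        kwargs.setdefault("prior_scale", config.prior_scale_t)
        return cls(means, **kwargs)

    def fit(self) -> "AdjudicationResults":
        report = adjudicate(self.scores, self.prior_scale, self.alt_threshold, self.null_threshold)
        return AdjudicationResults(model=self, report=report)


@dataclass
class AdjudicationResults:
    """Fitted adjudication: contrast estimates, Bayes factors, and the decision."""

    model: InstructionEffectModel
    report: AdjudicationReport

    @property
    def decision(self) -> str:
        return self.report.decision

    @property
    def reappraisal(self) -> ContrastInference:
        return self.report.reappraisal

    @property
    def load(self) -> ContrastInference:
        return self.report.load

    def sequential_bf(self, n_start: int = 20, n_orderings: int = 500, seed: int = 0, step: int = 1):
        from .robustness import sequential_bf

        return sequential_bf(
            self.model.scores, n_start=n_start, n_orderings=n_orderings, seed=seed,
            step=step, prior_scale=self.model.prior_scale,
        )

    def bootstrap_dz(self, contrast: str = "load", n_boot: int = 10_000, seed: int = 0):
        from .robustness import bootstrap_dz

        return bootstrap_dz(self.model.scores.values(contrast), n_boot=n_boot, seed=seed, name=contrast)

    def summary(self) -> str:
        r, l = self.report.reappraisal, self.report.load
        lines = [
            "Instruction-effect adjudication (LPP, {} scope, n = {})".format(
                self.report.valence_scope, self.report.n
            ),
            "=" * 66,
            f"{'contrast':<24}{'mean (uV)':>10}{'t':>8}{'dz':>8}{'BF01':>9}{'evidence':>14}",
            "-" * 66,
        ]
        for name, c in (("Reappraisal (E-S)", r), ("Cognitive load (2V-E-S)", l)):
            lines.append(
                f"{name:<24}{c.ttest.mean_diff:>10.3f}{c.ttest.t:>8.2f}"
                f"{c.ttest.dz:>8.3f}{c.bayes.bf01:>9.3g}{c.evidence:>14}"
            )
        lines += ["-" * 66, f"decision: {self.report.decision}", self.report.rationale]
        return "\n".join(lines)

    def plot_sequential(self, trace=None, ax=None, **kwargs):
        """Plot a sequential Bayes-factor trace (computes one if not given)."""
        import matplotlib.pyplot as plt

        trace = trace or self.sequential_bf(**kwargs)
        if ax is None:
            _, ax = plt.subplots()
        for name, color in (("reappraisal", "0.5"), ("load", "k")):
            ax.plot(trace.n_grid, trace.median[name], color=color, label=name)
            ax.fill_between(trace.n_grid, trace.band_lo[name], trace.band_hi[name], color=color, alpha=0.2)
        for y in (3.0, 1.0, 1.0 / 3.0):
            ax.axhline(y, ls=":", color="0.7")
        ax.set_yscale("log")
        ax.set_xlabel("subjects")
        ax.set_ylabel("BF01")
        ax.legend()
        return ax
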
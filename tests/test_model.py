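"""Contrast computation, the decision rule, and the Model/Results API."""

import numpy as np
import pandas as pd
import pytest

from lppkit.config import GeneratorConfig
from lppkit.model import (
    ContrastScores,
    InstructionEffectModel,
    adjudicate,
    compute_contrasts,
    decide,
)
from lppkit.simulate import simulate_condition_means


def means_frame(rows):
    df = pd.DataFrame(rows)
    df["n_trials"] = 10
    return df


def single_subject_means(view, enhance, suppress, subject="S1", valence="pleasant"):
    return [
        {"subject_id": subject, "valence": valence, "instruction": ins, "lpp_uv": v}
        for ins, v in (("view", view), ("enhance", enhance), ("suppress", suppress))
    ]


class TestComputeContrasts:
    def test_arithmetic(self):
        df = means_frame(single_subject_means(1.0, 0.5, 0.5))
        sc = compute_contrasts(df, scope="pleasant")
        assert sc.values("load")[0] == pytest.approx(1.0)
        assert sc.values("reappraisal")[0] == pytest.approx(0.0)

    def test_equal_enhance_suppress_zero_reappraisal(self):
        rows = []
        for s in range(5):
            rows += single_subject_means(s + 1.0, s + 0.3, s + 0.3, subject=f"S{s}")
        sc = compute_contrasts(means_frame(rows), scope="pleasant")
        assert np.allclose(sc.values("reappraisal"), 0.0)

    def test_pooled_is_mean_of_valence_scopes(self):
        rng = np.random.default_rng(0)
        rows = []
        for s in range(6):
            for val in ("pleasant", "unpleasant"):
                rows += single_subject_means(*rng.normal(size=3), subject=f"S{s}", valence=val)
        df = means_frame(rows)
        pooled = compute_contrasts(df, "pooled").scores.set_index("subject_id")
        pl = compute_contrasts(df, "pleasant").scores.set_index("subject_id")
        un = compute_contrasts(df, "unpleasant").scores.set_index("subject_id")
        for c in ("reappraisal", "load"):
            np.testing.assert_allclose(pooled[c], (pl[c] + un[c]) / 2, atol=1e-12)

    def test_incomplete_subject_excluded(self):
        rows = single_subject_means(1.0, 0.5, 0.2, subject="A")
        rows += single_subject_means(2.0, 1.0, 0.4, subject="B")[:2]  # missing suppress
        sc = compute_contrasts(means_frame(rows), scope="pleasant")
        assert list(sc.scores["subject_id"]) == ["A"]

    def test_no_complete_subjects_raises(self):
        rows = single_subject_means(1.0, 0.5, 0.2, subject="A")[:2]
        with pytest.raises(ValueError):
            compute_contrasts(means_frame(rows), scope="pleasant")

    def test_orthogonal_contrasts_uncorrelated_under_null(self):
        rng = np.random.default_rng(42)
        rows = []
        for s in range(4000):
            v, e, su = rng.normal(size=3)
            rows += single_subject_means(v, e, su, subject=f"S{s:05d}")
        sc = compute_contrasts(means_frame(rows), scope="pleasant")
        corr = np.corrcoef(sc.values("reappraisal"), sc.values("load"))[0, 1]
        assert abs(corr) < 0.1


class TestDecisionRule:
    @pytest.mark.parametrize(
        "bf_reap,bf_load,m_reap,m_load,expected",
        [
            (9.3, 0.04, -0.01, 0.89, "cognitive_load"),
            (0.1, 5.0, 0.8, 0.0, "reappraisal"),
            (8.0, 7.0, 0.0, 0.0, "null"),
            (0.5, 0.5, 0.1, 0.1, "indeterminate"),
            # load alternative with NEGATIVE mean must not count as load
            (9.0, 0.04, 0.0, -0.9, "indeterminate"),
            # load evidence but reappraisal also leaning alternative
            (0.9, 0.04, 0.0, 0.9, "indeterminate"),
            # reappraisal alternative with negative mean (suppress > enhance)
            (0.1, 5.0, -0.8, 0.0, "indeterminate"),
        ],
    )
    def test_decide(self, bf_reap, bf_load, m_reap, m_load, expected):
        decision, rationale = decide(bf_reap, bf_load, m_reap, m_load)
        assert decision == expected
        assert rationale

    def test_adjudicate_planted_load_effect(self, make_exact_vector):
        # mirrors the reported pattern: load mean ~0.9 uV, reappraisal ~0
        rng = np.random.default_rng(5)
        frame = pd.DataFrame(
            {
                "subject_id": [f"S{i}" for i in range(107)],
                "reappraisal": make_exact_vector(107, 0.0, 2.0, rng),
                "load": make_exact_vector(107, 0.9, 2.7, rng),
            }
        )
        report = adjudicate(ContrastScores(frame, "pooled"))
        assert report.decision == "cognitive_load"
        assert report.load.bayes.bf01 < 1 / 3
        assert report.reappraisal.bayes.bf01 > 3

    def test_adjudicate_null_for_tiny_noise(self, make_exact_vector):
        rng = np.random.default_rng(6)
        frame = pd.DataFrame(
            {
                "subject_id": [f"S{i}" for i in range(107)],
                "reappraisal": make_exact_vector(107, 0.0, 1.0, rng),
                "load": make_exact_vector(107, 0.0, 1.0, rng),
            }
        )
        report = adjudicate(ContrastScores(frame, "pooled"))
        assert report.decision == "null"

    def test_zero_variance_contrast_raises(self):
        frame = pd.DataFrame(
            {"subject_id": ["A", "B"], "reappraisal": [1.0, 1.0], "load": [0.5, 0.7]}
        )
        with pytest.raises(ValueError):
            adjudicate(ContrastScores(frame, "pooled"))


class TestModelAPI:
    def test_fit_summary_and_attributes(self):
        means = simulate_condition_means(GeneratorConfig(regime="load"), seed=9)
        model = InstructionEffectModel(means)
        res = model.fit()
        assert res.decision in {"cognitive_load", "reappraisal", "null", "indeterminate"}
        text = res.summary()
        assert "Reappraisal" in text and "Cognitive load" in text
        assert res.decision in text
        assert res.load.ttest.n == 107

    def test_results_robustness_methods(self):
        means = simulate_condition_means(GeneratorConfig(n_subjects=30), seed=10)
        res = InstructionEffectModel(means).fit()
        trace = res.sequential_bf(n_start=20, n_orderings=3, seed=0, step=5)
        assert trace.n_grid[-1] == 30
        boot = res.bootstrap_dz("load", n_boot=1000, seed=0)
        assert boot.ci95[0] <= np.median(boot.dz) <= boot.ci95[1]

    def test_from_epochs_end_to_end(self, tiny_study, small_ana):
        epochs, trials = tiny_study
        model = InstructionEffectModel.from_epochs(epochs, trials, small_ana)
        res = model.fit()
        assert res.report.n == 8
        assert res.decision in {"cognitive_load", "reappraisal", "null", "indeterminate"}
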
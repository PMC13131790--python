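"""RM-ANOVA and paired-t against longhand oracles and an independent library."""

import math

import numpy as np
import pandas as pd
import pytest

from lppkit.freq_stats import one_sample_t, paired_t, rm_anova

# A fixed 6-subject x 3-condition table used for the longhand oracle.
WORKED_TABLE = np.array(
    [
        [4.1, 2.9, 3.1],
        [6.0, 4.8, 5.4],
        [3.2, 3.0, 2.5],
        [5.5, 4.1, 4.9],
        [4.8, 3.6, 3.3],
        [5.1, 4.4, 4.0],
    ]
)


def longhand_oneway(y: np.ndarray) -> dict:
    """Sum-of-squares decomposition written out with explicit loops."""
    n, k = y.shape
    grand = y.sum() / (n * k)
    cond_means = [sum(y[s][j] for s in range(n)) / n for j in range(k)]
    subj_means = [sum(y[s][j] for j in range(k)) / k for s in range(n)]
    ss_cond = n * sum((m - grand) ** 2 for m in cond_means)
    ss_subj = k * sum((m - grand) ** 2 for m in subj_means)
    ss_err = sum(
        (y[s][j] - cond_means[j] - subj_means[s] + grand) ** 2
        for s in range(n)
        for j in range(k)
    )
    df1, df2 = k - 1, (k - 1) * (n - 1)
    f = (ss_cond / df1) / (ss_err / df2)
    eta_g = ss_cond / (ss_cond + ss_subj + ss_err)
    # Box's epsilon-hat from the k x k sample covariance of condition scores
    cov = np.zeros((k, k))
    for i in range(k):
        for j in range(k):
            cov[i, j] = sum(
                (y[s][i] - cond_means[i]) * (y[s][j] - cond_means[j]) for s in range(n)
            ) / (n - 1)
    mean_all = cov.mean()
    mean_diag = np.trace(cov) / k
    row_means = cov.mean(axis=1)
    num = (k * (mean_diag - mean_all)) ** 2
    den = (k - 1) * (
        (cov**2).sum() - 2 * k * (row_means**2).sum() + k * k * mean_all**2
    )
    eps = num / den
    return {"F": f, "eta_g": eta_g, "eps": eps, "df": (df1, df2)}


class TestRmAnovaOneWay:
    def test_matches_longhand_oracle_on_worked_table(self):
        oracle = longhand_oneway(WORKED_TABLE)
        df = pd.DataFrame(
            [
                {"subject_id": f"S{s}", "instruction": f"c{j}", "y": WORKED_TABLE[s, j]}
                for s in range(6)
                for j in range(3)
            ]
        )
        (res,) = rm_anova(df, "y", ["instruction"])
        assert res.F == pytest.approx(oracle["F"], rel=1e-10)
        assert res.eta_g_sq == pytest.approx(oracle["eta_g"], rel=1e-10)
        assert res.epsilon_gg == pytest.approx(oracle["eps"], rel=1e-10)
        assert (res.df_num, res.df_den) == oracle["df"]

    def test_matches_pingouin_on_worked_table(self):
        pg = pytest.importorskip("pingouin")
        df = pd.DataFrame(
            [
                {"subject_id": f"S{s}", "instruction": f"c{j}", "y": WORKED_TABLE[s, j]}
                for s in range(6)
                for j in range(3)
            ]
        )
        (res,) = rm_anova(df, "y", ["instruction"])
        ref = pg.rm_anova(data=df, dv="y", within="instruction", subject="subject_id", effsize="ng2")
        assert res.F == pytest.approx(float(ref["F"].iloc[0]), rel=1e-8)
        assert res.epsilon_gg == pytest.approx(float(ref["eps"].iloc[0]), rel=1e-8)
        assert res.eta_g_sq == pytest.approx(float(ref["ng2"].iloc[0]), rel=1e-8)

    def test_constant_conditions_give_zero_f(self):
        df = pd.DataFrame(
            [
                {"subject_id": f"S{s}", "instruction": f"c{j}", "y": 1.0 + s}
                for s in range(5)
                for j in range(3)
            ]
        )
        (res,) = rm_anova(df, "y", ["instruction"])
        assert res.F == 0.0
        assert res.eta_g_sq == 0.0

    def test_compound_symmetry_gives_epsilon_near_one(self):
        rng = np.random.default_rng(4)
        n, k = 300, 3
        y = rng.normal(size=(n, 1)) + rng.normal(size=(n, k))  # exchangeable
        df = pd.DataFrame(
            [
                {"subject_id": f"S{s}", "instruction": f"c{j}", "y": y[s, j]}
                for s in range(n)
                for j in range(k)
            ]
        )
        (res,) = rm_anova(df, "y", ["instruction"])
        assert res.epsilon_gg > 0.95

    def test_epsilon_bounds_and_subject_shift_invariance(self):
        rng = np.random.default_rng(9)
        y = rng.normal(size=(10, 4))
        def to_df(mat):
            return pd.DataFrame(
                [
                    {"subject_id": f"S{s}", "instruction": f"c{j}", "y": mat[s, j]}
                    for s in range(mat.shape[0])
                    for j in range(mat.shape[1])
                ]
            )
        (res,) = rm_anova(to_df(y), "y", ["instruction"])
        assert 1 / 3 <= res.epsilon_gg <= 1
        shifted = y + rng.normal(size=(10, 1))  # per-subject constants
        (res2,) = rm_anova(to_df(shifted), "y", ["instruction"])
        assert res2.epsilon_gg == pytest.approx(res.epsilon_gg, rel=1e-9)
        assert res2.F == pytest.approx(res.F, rel=1e-9)
        scaled = y * 3.7  # global rescale leaves F untouched
        (res3,) = rm_anova(to_df(scaled), "y", ["instruction"])
        assert res3.F == pytest.approx(res.F, rel=1e-9)

    def test_missing_cell_raises(self):
        df = pd.DataFrame(
            [
                {"subject_id": f"S{s}", "instruction": f"c{j}", "y": float(s + j)}
                for s in range(4)
                for j in range(3)
            ]
        )
        df = df.drop(index=0)
        with pytest.raises(ValueError, match="incomplete"):
            rm_anova(df, "y", ["instruction"])


class TestRmAnovaTwoWay:
    def test_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(21)
        rows = []
        for s in range(14):
            base = rng.normal(0, 2)
            for vi, val in enumerate(["pleasant", "unpleasant"]):
                for ii, ins in enumerate(["view", "enhance", "suppress"]):
                    rows.append(
                        {
                            "subject_id": f"S{s}",
                            "valence": val,
                            "instruction": ins,
                            "y": base + 0.4 * vi + [0.0, -0.7, -0.6][ii] + rng.normal(0, 1),
                        }
                    )
        df = pd.DataFrame(rows)
        mine = {r.effect: r for r in rm_anova(df, "y", ["valence", "instruction"])}
        ref = pg.rm_anova(
            data=df, dv="y", within=["valence", "instruction"], subject="subject_id",
            detailed=True, effsize="ng2",
        )
        mapping = {
            "valence": "valence",
            "instruction": "instruction",
            "valence * instruction": "valence x instruction",
        }
        for src, eff in mapping.items():
            row = ref[ref["Source"] == src].iloc[0]
            assert mine[eff].F == pytest.approx(float(row["F"]), rel=1e-8)
            assert mine[eff].eta_g_sq == pytest.approx(float(row["ng2"]), rel=1e-8)
            assert mine[eff].epsilon_gg == pytest.approx(float(row["eps"]), rel=1e-8)
            assert mine[eff].p_gg == pytest.approx(float(row["p_GG_corr"]), rel=1e-6)

    def test_two_levels_reduce_to_paired_t(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(1, 1, 20), rng.normal(0, 1, 20)
        df = pd.DataFrame(
            [{"subject_id": f"S{i}", "c": "a", "y": x[i]} for i in range(20)]
            + [{"subject_id": f"S{i}", "c": "b", "y": y[i]} for i in range(20)]
        )
        (res,) = rm_anova(df, "y", ["c"])
        tt = paired_t(x, y)
        assert res.F == pytest.approx(tt.t**2, rel=1e-10)
        assert res.epsilon_gg == 1.0
        assert res.p_gg == pytest.approx(tt.p, rel=1e-9)


class TestPairedT:
    def test_dz_is_t_over_sqrt_n(self, make_exact_vector):
        d = make_exact_vector(107, 0.334, 1.0)
        res = one_sample_t(d)
        assert res.dz == pytest.approx(res.t / math.sqrt(107), rel=1e-12)

    def test_ci_normal_approximation(self, make_exact_vector):
        # dz = 0.41 at n = 107 must give the interval [0.21, 0.61] at 2 d.p.
        d = make_exact_vector(107, 0.41, 1.0)
        res = one_sample_t(d)
        assert res.dz == pytest.approx(0.41, abs=1e-12)
        lo, hi = res.dz_ci95
        assert (round(lo, 2), round(hi, 2)) == (0.21, 0.61)
        assert lo < res.dz < hi

    def test_zero_variance_raises(self):
        x = np.ones(10)
        with pytest.raises(ValueError, match="variance"):
            paired_t(x + 2.0, x)

    def test_mean_diff_sign(self):
        rng = np.random.default_rng(6)
        x = rng.normal(1.0, 0.5, 30)
        y = rng.normal(0.0, 0.5, 30)
        res = paired_t(x, y)
        assert res.mean_diff == pytest.approx((x - y).mean())
        assert res.t > 0
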
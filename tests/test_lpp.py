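"""LPP scoring, preprocessing stand-ins, and winsorization."""

import numpy as np
import pandas as pd
import pytest

from lppkit.io import EpochSet, ValidationError
from lppkit.lpp import (
    average_reference,
    baseline_correct,
    lpp_amplitude,
    reject_artifacts,
    trial_window_means,
    winsorize_table,
    winsorize_values,
)


def make_epochs(data, sfreq=250.0, t0=-0.1, subject="S1"):
    data = np.asarray(data, dtype=float)
    return EpochSet(subject, data, sfreq, t0, np.arange(1, data.shape[1] + 1))


def flat_epochs(value=3.0, n_trials=2, n_chan=4, n_samples=275, **kw):
    return make_epochs(np.full((n_trials, n_chan, n_samples), value), **kw)


class TestBaselineCorrect:
    def test_constant_trace_becomes_zero(self):
        out = baseline_correct(flat_epochs(3.0), (-0.1, 0.0))
        assert np.allclose(out.data, 0.0)

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        ep = make_epochs(rng.normal(size=(3, 4, 275)))
        once = baseline_correct(ep, (-0.1, 0.0))
        twice = baseline_correct(once, (-0.1, 0.0))
        assert np.allclose(once.data, twice.data, atol=1e-12)

    def test_step_trace_arithmetic(self):
        # 2 uV pre-onset, 7 uV post-onset; [-0.1, 0) baseline leaves 5 uV
        ep = flat_epochs(2.0)
        t = ep.times
        data = ep.data.copy()
        data[:, :, t >= 0] = 7.0
        ep = make_epochs(data)
        out = baseline_correct(ep, (-0.1, 0.0))
        assert np.allclose(out.data[:, :, t >= 0], 5.0)
        assert np.allclose(out.data[:, :, t < 0], 0.0)

    def test_window_validation(self):
        ep = flat_epochs()
        with pytest.raises(ValueError):
            baseline_correct(ep, (-0.5, 0.0))  # before epoch start
        with pytest.raises(ValueError):
            baseline_correct(ep, (-0.05, 0.2))  # extends past onset


class TestAverageReference:
    def test_zero_mean_input_unchanged(self):
        data = np.zeros((1, 2, 275))
        data[0, 0], data[0, 1] = 1.0, -1.0
        out = average_reference(make_epochs(data))
        assert np.allclose(out.data, data)

    def test_identical_channels_become_zero(self):
        out = average_reference(flat_epochs(5.0))
        assert np.allclose(out.data, 0.0)

    def test_idempotent_and_channel_mean_zero(self):
        rng = np.random.default_rng(1)
        ep = make_epochs(rng.normal(size=(2, 6, 275)))
        once = average_reference(ep)
        assert np.allclose(once.data.mean(axis=1), 0.0, atol=1e-12)
        twice = average_reference(once)
        assert np.allclose(once.data, twice.data, atol=1e-12)

    def test_single_channel_rejected(self):
        with pytest.raises(ValueError):
            average_reference(flat_epochs(n_chan=1))

    def test_commutes_with_baseline_correction(self):
        rng = np.random.default_rng(2)
        ep = make_epochs(rng.normal(size=(3, 5, 275)))
        ab = average_reference(baseline_correct(ep, (-0.1, 0.0)))
        ba = baseline_correct(average_reference(ep), (-0.1, 0.0))
        assert np.allclose(ab.data, ba.data, atol=1e-10)


class TestRejectArtifacts:
    def test_clean_data_identity(self):
        ep = flat_epochs(5.0)
        out, log = reject_artifacts(ep, 100.0)
        assert out.n_trials == ep.n_trials
        assert log.empty

    def test_spike_trial_removed_and_logged(self):
        ep = flat_epochs(5.0, n_trials=4)
        data = ep.data.copy()
        data[2, 1, 50] = 500.0
        ep = make_epochs(data)
        out, log = reject_artifacts(ep, 100.0)
        assert out.n_trials == 3
        assert list(out.trial_indices) == [0, 1, 3]
        assert log.iloc[0]["trial_index"] == 2
        assert log.iloc[0]["channel"] == 2  # 1-based label
        assert log.iloc[0]["peak_uv"] == 500.0

    def test_known_injected_spikes_exactly_removed(self):
        rng = np.random.default_rng(3)
        data = rng.normal(0, 5, size=(10, 4, 275))
        bad = [1, 4, 7]
        for ti in bad:
            data[ti, rng.integers(4), rng.integers(275)] = 300.0
        out, log = reject_artifacts(make_epochs(data), 100.0)
        assert sorted(log["trial_index"]) == bad
        assert out.n_trials == 7


class TestLppAmplitude:
    def _trials(self, subject="S1", n=2):
        return pd.DataFrame(
            {
                "subject_id": subject,
                "trial_index": range(n),
                "valence": "pleasant",
                "instruction": "view",
                "presentation": "second",
                "arousal": "none",
                "rating": 4,
            }
        )

    def test_constant_window_value(self):
        ep = flat_epochs(5.0)
        means = lpp_amplitude(ep, self._trials(), roi=(1, 2, 3, 4), window=(0.4, 0.8))
        assert means["lpp_uv"].iloc[0] == pytest.approx(5.0)
        assert means["n_trials"].iloc[0] == 2

    def test_cell_mean_of_two_trials(self):
        ep = flat_epochs(0.0)
        data = ep.data.copy()
        data[0] = 2.0
        data[1] = 4.0
        means = lpp_amplitude(make_epochs(data), self._trials(), (1, 2), (0.4, 0.8))
        assert means["lpp_uv"].iloc[0] == pytest.approx(3.0)

    def test_half_open_window_sample_count(self):
        # 250 Hz epoch from -0.1 s: [0.4, 0.8) covers exactly 100 samples
        ep = flat_epochs()
        assert ep.sample_mask((0.4, 0.8)).sum() == 100

    def test_channel_permutation_invariance(self):
        rng = np.random.default_rng(5)
        data = rng.normal(size=(3, 6, 275))
        ep = make_epochs(data)
        perm = rng.permutation(6)
        ep_perm = EpochSet("S1", data[:, perm], 250.0, -0.1, ep.channel_ids[perm])
        roi = (2, 5)
        a = lpp_amplitude(ep, self._trials(n=3), roi, (0.4, 0.8))
        b = lpp_amplitude(ep_perm, self._trials(n=3), roi, (0.4, 0.8))
        assert a["lpp_uv"].iloc[0] == pytest.approx(b["lpp_uv"].iloc[0], rel=1e-12)

    def test_missing_roi_channel_named(self):
        ep = flat_epochs(n_chan=4)
        with pytest.raises(ValidationError, match="99"):
            lpp_amplitude(ep, self._trials(), (1, 99), (0.4, 0.8))


class TestWinsorize:
    def test_1_to_100_against_brute_force_percentiles(self):
        values = np.arange(1.0, 101.0)
        lo = np.percentile(values, 1)  # linear interpolation rule
        hi = np.percentile(values, 99)
        clipped, n = winsorize_values(values, (1, 99))
        assert clipped.min() == pytest.approx(lo)
        assert clipped.max() == pytest.approx(hi)
        assert n == 2
        inner = (values > lo) & (values < hi)
        np.testing.assert_array_equal(clipped[inner], values[inner])

    def test_full_limits_identity(self):
        rng = np.random.default_rng(6)
        v = rng.normal(size=50)
        clipped, n = winsorize_values(v, (0, 100))
        np.testing.assert_array_equal(clipped, v)
        assert n == 0

    def test_monotone_rank_preserving(self):
        rng = np.random.default_rng(7)
        v = rng.normal(size=80)
        clipped, _ = winsorize_values(v, (5, 95))
        assert np.all(np.diff(clipped[np.argsort(v)]) >= 0)
        lo, hi = np.percentile(v, [5, 95])
        assert clipped.min() >= lo - 1e-12 and clipped.max() <= hi + 1e-12

    def test_table_scoped_per_condition(self):
        rng = np.random.default_rng(8)
        rows = []
        for cond, offset in (("view", 0.0), ("enhance", 50.0)):
            for s in range(40):
                rows.append(
                    {
                        "subject_id": f"S{s}",
                        "valence": "pleasant",
                        "instruction": cond,
                        "lpp_uv": offset + rng.normal(),
                        "n_trials": 10,
                    }
                )
        df = pd.DataFrame(rows)
        out = winsorize_table(df, (5, 95), scope="condition")
        # the big condition offset must survive per-condition winsorization
        for cond, offset in (("view", 0.0), ("enhance", 50.0)):
            sub = out[out["instruction"] == cond]["lpp_uv"]
            orig = df[df["instruction"] == cond]["lpp_uv"]
            lo, hi = np.percentile(orig, [5, 95])
            assert sub.min() == pytest.approx(lo)
            assert sub.max() == pytest.approx(hi)
            assert abs(sub.mean() - offset) < 1.0

    def test_degenerate_condition_is_identity(self):
        df = pd.DataFrame(
            {
                "subject_id": [f"S{i}" for i in range(4)],
                "valence": "pleasant",
                "instruction": "view",
                "lpp_uv": [2.0] * 4,
                "n_trials": 5,
            }
        )
        out = winsorize_table(df, (1, 99))
        np.testing.assert_array_equal(out["lpp_uv"], df["lpp_uv"])
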
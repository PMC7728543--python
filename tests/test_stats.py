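import numpy as np
import pandas as pd
import pytest

from tremorkit import (
    ParticipantProfile,
    before_after_tests,
    kendall_tau_b,
    kendall_tip_updrs,
    pairwise_group_tests,
    percent_change,
    rank_sum_test,
)
from .oracles import kendall_oracle, mannwhitney_u, ranksum_exact_p


class TestKendallTauB:
    def test_perfect_concordance(self):
        x = [0, 1, 2, 3, 4]
        y = [1.0, 2.0, 5.0, 7.0, 9.0]
        tau, z, p = kendall_tau_b(x, y)
        assert tau == pytest.approx(1.0)
        assert z > 0 and p < 0.05

    def test_perfect_discordance(self):
        x = [0, 1, 2, 3, 4]
        y = [9.0, 7.0, 5.0, 2.0, 1.0]
        tau, _, _ = kendall_tau_b(x, y)
        assert tau == pytest.approx(-1.0)

    def test_hand_tied_example_matches_pair_count_oracle(self):
        x = [0, 0, 1, 1, 2, 2, 3, 3]
        y = [0.2, 0.5, 0.4, 1.1, 0.9, 2.0, 1.8, 2.5]
        tau, _, _ = kendall_tau_b(x, y)
        assert tau == pytest.approx(kendall_oracle(x, y), abs=1e-12)

    def test_matches_oracle_on_random_tied_data(self, rng):
        for _ in range(200):
            n = int(rng.integers(3, 40))
            x = rng.integers(0, 4, size=n).astype(float)
            y = np.round(rng.normal(size=n), 1)
            if np.unique(x).size < 2 or np.unique(y).size < 2:
                continue
            tau, _, _ = kendall_tau_b(x, y)
            assert tau == pytest.approx(kendall_oracle(x, y), abs=1e-10)

    def test_constant_variable_flagged(self):
        with pytest.raises(ValueError, match="constant"):
            kendall_tau_b([1, 1, 1], [1.0, 2.0, 3.0])

    def test_z_matches_untied_closed_form(self):
        # without ties var(S) = n(n-1)(2n+5)/18
        rng = np.random.default_rng(3)
        x = rng.permutation(20).astype(float)
        y = rng.normal(size=20)
        tau, z, _ = kendall_tau_b(x, y)
        n = 20
        s = tau * n * (n - 1) / 2
        assert z == pytest.approx(s / np.sqrt(n * (n - 1) * (2 * n + 5) / 18))


class TestRankSum:
    def test_identical_samples_p_near_one(self):
        a = np.arange(30.0)
        w, p = rank_sum_test(a, a.copy())
        assert p > 0.9

    def test_separated_samples_exact_enumeration(self):
        # {1,2,3} vs {4,5,6}: the most extreme of C(6,3)=20 orderings
        w, p = rank_sum_test([1, 2, 3], [4, 5, 6])
        assert w == 0.0
        assert p == pytest.approx(2 / 20)
        assert p == pytest.approx(ranksum_exact_p([1, 2, 3], [4, 5, 6]))

    def test_statistic_matches_pair_count_oracle(self, rng):
        for _ in range(100):
            n, m = int(rng.integers(2, 25)), int(rng.integers(2, 25))
            a = np.round(rng.normal(size=n), 1)
            b = np.round(rng.normal(size=m), 1)
            w, _ = rank_sum_test(a, b)
            assert w == pytest.approx(mannwhitney_u(a, b))

    def test_exact_p_matches_enumeration_for_small_untied_samples(self, rng):
        for _ in range(20):
            n, m = int(rng.integers(2, 7)), int(rng.integers(2, 7))
            pool = rng.permutation(100)[: n + m].astype(float)
            a, b = pool[:n], pool[n:]
            _, p = rank_sum_test(a, b)
            assert p == pytest.approx(ranksum_exact_p(a, b), abs=1e-9)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            rank_sum_test([], [1.0])

    def test_power_for_twofold_tip_shift(self):
        """A 2x shift with n=100/group is detected in >=95% of simulations."""
        ss = np.random.SeedSequence(17)
        hits = 0
        n_sim = 200
        for child in ss.spawn(n_sim):
            r = np.random.default_rng(child)
            a = r.lognormal(mean=0.0, sigma=1.0, size=100)
            b = 2.0 * r.lognormal(mean=0.0, sigma=1.0, size=100)
            _, p = rank_sum_test(a, b)
            hits += p < 0.05
        assert hits / n_sim >= 0.95


def _profiles():
    return [
        ParticipantProfile("A", 5, 0, "no_tremor"),
        ParticipantProfile("B", 10, 1, "tremor"),
        ParticipantProfile("C", 15, 2, "hand_tremor"),
        ParticipantProfile("D", 20, 3, "plays_with_hand_tremor"),
    ]


def _features_df(rng, n_per=30):
    """Per-session features with group-dependent TIP scale."""
    scale = {"A": 0.1, "B": 1.0, "C": 1.0, "D": 5.0}
    rows = []
    for pid, s in scale.items():
        for i in range(n_per):
            tip = s * rng.lognormal(0, 0.5)
            rows.append(
                dict(
                    participant_id=pid,
                    session_id=f"{pid}-{i}",
                    tip=tip,
                    pv=tip * 0.4,
                    sf50=0.4,
                    f0=5.0,
                    f50=5.0,
                    f50_f0_abs=0.0,
                    auc_dyskinesia=0.1 * s,
                    auc_rest=s,
                    auc_postural=0.1 * s,
                    auc_kinetic=0.05 * s,
                )
            )
    return pd.DataFrame(rows)


class TestKendallTipUpdrs:
    def test_session_unit_uses_all_sessions(self, rng):
        df = _features_df(rng)
        res = kendall_tip_updrs(df, _profiles(), unit="session")
        assert res.n == len(df)
        assert res.statistic > 0.3
        assert res.p_value < 0.001

    def test_participant_unit_collapses_to_medians(self, rng):
        df = _features_df(rng)
        res = kendall_tip_updrs(df, _profiles(), unit="participant")
        assert res.n == 4
        # B and C share a TIP distribution, so their medians may invert:
        # at most one of the six participant pairs can be discordant
        assert res.statistic >= 2.0 / 3.0 - 1e-12


class TestPairwiseGroupTests:
    def test_six_pairs_per_feature(self, rng):
        res = pairwise_group_tests(_features_df(rng), _profiles(),
                                   feature_cols=("tip", "pv"))
        assert len(res) == 12  # 6 pairs x 2 features
        comparisons = {t.comparison for t in res}
        assert len(comparisons) == 6

    def test_identical_groups_not_significant(self, rng):
        res = pairwise_group_tests(_features_df(rng), _profiles(),
                                   feature_cols=("tip",))
        by_pair = {t.comparison: t.p_value for t in res}
        assert by_pair["tremor_vs_hand_tremor"] > 0.01  # same distribution
        assert by_pair["no_tremor_vs_plays_with_hand_tremor"] < 1e-6

    def test_small_group_skipped_with_warning(self, rng):
        df = _features_df(rng)
        df = df[~((df["participant_id"] == "A") & (df.index > 0))]
        df = pd.concat([df[df["participant_id"] == "A"].head(1),
                        df[df["participant_id"] != "A"]])
        with pytest.warns(UserWarning, match="skipping"):
            res = pairwise_group_tests(df, _profiles(), feature_cols=("tip",))
        assert all("no_tremor" not in t.comparison for t in res)

    def test_bh_adjustment_is_monotone_and_larger(self, rng):
        df = _features_df(rng)
        raw = pairwise_group_tests(df, _profiles(), feature_cols=("tip",))
        adj = pairwise_group_tests(df, _profiles(), feature_cols=("tip",),
                                   adjust="bh")
        for r, a in zip(raw, adj):
            assert a.p_value >= r.p_value - 1e-12


def _labels_df(features, split=0.5, rng=None):
    labels = []
    for pid, sub in features.groupby("participant_id"):
        n = len(sub)
        for i, sid in enumerate(sub["session_id"]):
            labels.append(dict(session_id=sid,
                               label="before" if i < n * split else "after"))
    return pd.DataFrame(labels)


class TestBeforeAfter:
    def test_no_effect_gives_uniformish_p(self, rng):
        df = _features_df(rng)
        labels = _labels_df(df)
        res = before_after_tests(df, labels, feature_cols=("tip",))
        assert len(res) == 4
        assert all(0.0 <= t.p_value <= 1.0 for t in res)

    def test_insufficient_sessions_skipped(self, rng):
        df = _features_df(rng, n_per=3)
        labels = _labels_df(df, split=0.4)  # 1 before, 2 after
        res = before_after_tests(df, labels, feature_cols=("tip",),
                                 min_sessions=2)
        assert res == []

    def test_strong_shift_detected(self, rng):
        df = _features_df(rng)
        labels = _labels_df(df)
        after = set(labels.loc[labels["label"] == "after", "session_id"])
        df.loc[df["session_id"].isin(after), "tip"] *= 0.1
        res = before_after_tests(df, labels, feature_cols=("tip",))
        assert all(t.p_value < 0.01 for t in res)


class TestPercentChange:
    def test_equal_means_give_zero(self):
        df = pd.DataFrame(
            dict(participant_id=["A"] * 4, session_id=list("wxyz"),
                 tip=[1.0, 2.0, 1.0, 2.0])
        )
        labels = pd.DataFrame(
            dict(session_id=list("wxyz"),
                 label=["before", "before", "after", "after"])
        )
        out = percent_change(df, labels, feature_cols=("tip",))
        assert out.loc["A", "tip"] == pytest.approx(0.0)

    @pytest.mark.parametrize("after_vals,expected", [
        ([1.0, 1.0], -50.0),
        ([3.0, 3.0], +50.0),
    ])
    def test_direct_arithmetic(self, after_vals, expected):
        df = pd.DataFrame(
            dict(participant_id=["A"] * 4, session_id=list("wxyz"),
                 tip=[2.0, 2.0] + after_vals)
        )
        labels = pd.DataFrame(
            dict(session_id=list("wxyz"),
                 label=["before", "before", "after", "after"])
        )
        out = percent_change(df, labels, feature_cols=("tip",))
        assert out.loc["A", "tip"] == pytest.approx(expected)

    def test_zero_before_mean_flagged_as_nan(self):
        df = pd.DataFrame(
            dict(participant_id=["A"] * 4, session_id=list("wxyz"),
                 tip=[0.0, 0.0, 1.0, 1.0])
        )
        labels = pd.DataFrame(
            dict(session_id=list("wxyz"),
                 label=["before", "before", "after", "after"])
        )
        out = percent_change(df, labels, feature_cols=("tip",))
        assert np.isnan(out.loc["A", "tip"])
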
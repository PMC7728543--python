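"""Nonparametric statistics on per-session spectral features.

Three analyses mirror the study design:

* a tie-corrected Kendall rank correlation (tau-b) between each session's
  tremor intensity parameter (TIP) and the participant's self-assessed
  UPDRS II tremor item (0–4), with a normal-approximation z and
  two-sided p;
* Wilcoxon rank-sum tests comparing the four tremor groups pairwise on
  every feature, pooling sessions across group members;
* per-participant Wilcoxon rank-sum tests of "before" vs "after"
  medication sessions, plus percent-change summaries of feature means.

No multiplicity correction is applied by default (each p value reported
as-is); Benjamini–Hochberg adjustment is available via ``adjust="bh"``.
Sessions are pooled within groups without modeling the repeated-measures
structure — a deliberate simplification preserved from the study design.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as _stats

__all__ = [
    "GROUPS",
    "FEATURES",
    "ParticipantProfile",
    "TestResult",
    "kendall_tau_b",
    "kendall_tip_updrs",
    "rank_sum_test",
    "pairwise_group_tests",
    "before_after_tests",
    "percent_change",
]

#: Tremor groups, ordered by expected severity of the measured hand signal.
GROUPS = ("no_tremor", "tremor", "hand_tremor", "plays_with_hand_tremor")

#: The ten per-session features entering the group comparisons.
FEATURES = (
    "auc_dyskinesia",
    "auc_rest",
    "auc_postural",
    "auc_kinetic",
    "pv",
    "f0",
    "f50",
    "sf50",
    "f50_f0_abs",
    "tip",
)


@dataclass(frozen=True)
class ParticipantProfile:
    """Clinical self-report metadata for one participant."""

    participant_id: str
    updrs2_total: int
    updrs_tremor_item: int
    group: str
    rigidity: bool = False
    bradykinesia: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.updrs2_total <= 52:
            raise ValueError("updrs2_total must be in 0..52")
        if not 0 <= self.updrs_tremor_item <= 4:
            raise ValueError("updrs_tremor_item must be in 0..4")
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}")
        if (self.updrs_tremor_item == 0) != (self.group == "no_tremor"):
            raise ValueError(
                "tremor item 0 and group 'no_tremor' must imply each other"
            )


@dataclass(frozen=True)
class TestResult:
    """Outcome of one hypothesis test."""

    comparison: str
    feature: str
    statistic: float  # tau for Kendall, W (rank-sum U of the first sample)
    p_value: float
    n: int
    z: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value must lie in [0, 1]")


# ---------------------------------------------------------------------------
# Kendall tau-b


def kendall_tau_b(x, y) -> tuple[float, float, float]:
    """Tie-corrected Kendall rank correlation with normal-approximation p.

    Returns ``(tau_b, z, p)``.  The z statistic divides the concordance
    score S = (#concordant − #discordant) by the square root of its
    tie-corrected null variance, matching the classical large-sample
    test for heavily tied data.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 2:
        raise ValueError("x and y must have equal length >= 2")
    n = x.size
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        raise ValueError("correlation undefined: a variable is constant")

    tau = float(_stats.kendalltau(x, y, variant="b").statistic)

    # recover S from tau_b and the tie structure
    t_cnt = np.unique(x, return_counts=True)[1].astype(float)
    u_cnt = np.unique(y, return_counts=True)[1].astype(float)
    n0 = n * (n - 1) / 2.0
    n1 = float(np.sum(t_cnt * (t_cnt - 1) / 2.0))
    n2 = float(np.sum(u_cnt * (u_cnt - 1) / 2.0))
    s = tau * math.sqrt((n0 - n1) * (n0 - n2))

    # tie-corrected variance of S under the null
    def _sum(c, f):
        return float(np.sum(f(c)))

    v0 = n * (n - 1) * (2 * n + 5)
    vt = _sum(t_cnt, lambda t: t * (t - 1) * (2 * t + 5))
    vu = _sum(u_cnt, lambda u: u * (u - 1) * (2 * u + 5))
    v1 = (
        _sum(t_cnt, lambda t: t * (t - 1)) * _sum(u_cnt, lambda u: u * (u - 1))
    ) / (2.0 * n * (n - 1))
    v2 = 0.0
    if n > 2:
        v2 = (
            _sum(t_cnt, lambda t: t * (t - 1) * (t - 2))
            * _sum(u_cnt, lambda u: u * (u - 1) * (u - 2))
        ) / (9.0 * n * (n - 1) * (n - 2))
    var_s = (v0 - vt - vu) / 18.0 + v1 + v2
    if var_s <= 0:
        raise ValueError("degenerate tie structure: zero null variance")
    z = s / math.sqrt(var_s)
    p = 2.0 * float(_stats.norm.sf(abs(z)))
    return tau, z, min(p, 1.0)


def kendall_tip_updrs(
    features: pd.DataFrame,
    profiles: list[ParticipantProfile],
    unit: str = "session",
) -> TestResult:
    """Correlate TIP with the UPDRS II tremor item across participants.

    ``unit="session"`` pairs every session's TIP with its participant's
    score (many tied scores; this is what gives the test its power).
    ``unit="participant"`` first collapses each participant to their
    median TIP, a conservative aggregation with n = number of
    participants.
    """
    score = {p.participant_id: p.updrs_tremor_item for p in profiles}
    df = features[["participant_id", "tip"]].dropna()
    df = df[df["participant_id"].isin(score)]
    if unit == "participant":
        df = df.groupby("participant_id", as_index=False)["tip"].median()
    elif unit != "session":
        raise ValueError("unit must be 'session' or 'participant'")
    x = df["participant_id"].map(score).to_numpy(dtype=float)
    y = df["tip"].to_numpy(dtype=float)
    tau, z, p = kendall_tau_b(x, y)
    return TestResult(
        comparison=f"tip_vs_updrs[{unit}]",
        feature="tip",
        statistic=tau,
        z=z,
        p_value=p,
        n=len(df),
    )


# ---------------------------------------------------------------------------
# Wilcoxon rank sum


def rank_sum_test(a, b) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann–Whitney) test.

    Returns ``(W, p)`` where W is the Mann–Whitney U statistic of the
    first sample (the ``W`` that R's ``wilcox.test`` reports).  The p
    value comes from exact enumeration when both samples have at most 10
    observations and no ties, and from the normal approximation with tie
    and continuity corrections otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (a.size <= 10 and b.size <= 10 and no_ties) else "asymptotic"
    res = _stats.mannwhitneyu(
        a, b, alternative="two-sided", method=method, use_continuity=True
    )
    return float(res.statistic), float(res.pvalue)


def _maybe_adjust(results: list[TestResult], adjust: str) -> list[TestResult]:
    if adjust == "none" or not results:
        return results
    if adjust != "bh":
        raise ValueError("adjust must be 'none' or 'bh'")
    adj = _stats.false_discovery_control(
        [r.p_value for r in results], method="bh"
    )
    return [
        TestResult(
            comparison=r.comparison,
            feature=r.feature,
            statistic=r.statistic,
            z=r.z,
            p_value=float(min(p, 1.0)),
            n=r.n,
        )
        for r, p in zip(results, adj)
    ]


def pairwise_group_tests(
    features: pd.DataFrame,
    profiles: list[ParticipantProfile],
    feature_cols: tuple[str, ...] = FEATURES,
    adjust: str = "none",
) -> list[TestResult]:
    """Rank-sum tests for every feature and every pair of tremor groups.

    Sessions are pooled across the members of each group; the four
    groups yield six pairwise comparisons per feature.  Pairs where
    either group contributes fewer than 2 sessions are skipped with a
    warning.
    """
    group_of = {p.participant_id: p.group for p in profiles}
    df = features.copy()
    df["group"] = df["participant_id"].map(group_of)
    df = df.dropna(subset=["group"])

    results: list[TestResult] = []
    for g1, g2 in combinations(GROUPS, 2):
        a_df = df[df["group"] == g1]
        b_df = df[df["group"] == g2]
        if len(a_df) < 2 or len(b_df) < 2:
            warnings.warn(
                f"skipping {g1} vs {g2}: fewer than 2 sessions in a group",
                stacklevel=2,
            )
            continue
        for feat in feature_cols:
            a = a_df[feat].dropna().to_numpy()
            b = b_df[feat].dropna().to_numpy()
            w, p = rank_sum_test(a, b)
            results.append(
                TestResult(
                    comparison=f"{g1}_vs_{g2}",
                    feature=feat,
                    statistic=w,
                    p_value=p,
                    n=a.size + b.size,
                )
            )
    return _maybe_adjust(results, adjust)


def before_after_tests(
    features: pd.DataFrame,
    labels: pd.DataFrame,
    feature_cols: tuple[str, ...] = FEATURES,
    min_sessions: int = 2,
    adjust: str = "none",
) -> list[TestResult]:
    """Per-participant rank-sum tests of before- vs after-medication sessions.

    Participants lacking ``min_sessions`` sessions in either condition
    are skipped for that feature.
    """
    df = features.merge(
        labels[["session_id", "label"]], on="session_id", how="inner"
    )
    df = df[df["label"].isin(["before", "after"])]
    results: list[TestResult] = []
    for pid, sub in df.groupby("participant_id", sort=True):
        for feat in feature_cols:
            bef = sub.loc[sub["label"] == "before", feat].dropna().to_numpy()
            aft = sub.loc[sub["label"] == "after", feat].dropna().to_numpy()
            if bef.size < min_sessions or aft.size < min_sessions:
                continue
            w, p = rank_sum_test(bef, aft)
            results.append(
                TestResult(
                    comparison=f"{pid}:before_vs_after",
                    feature=feat,
                    statistic=w,
                    p_value=p,
                    n=bef.size + aft.size,
                )
            )
    return _maybe_adjust(results, adjust)


def percent_change(
    features: pd.DataFrame,
    labels: pd.DataFrame,
    feature_cols: tuple[str, ...] = FEATURES,
) -> pd.DataFrame:
    """Percent change of feature means from "before" to "after" sessions.

    Computed per participant as ``100·(mean_after − mean_before)/
    mean_before``: negative values mean the feature dropped after
    medication.  Undefined entries (a missing condition, or a zero
    "before" mean) are NaN.
    """
    df = features.merge(
        labels[["session_id", "label"]], on="session_id", how="inner"
    )
    df = df[df["label"].isin(["before", "after"])]
    rows = {}
    for pid, sub in df.groupby("participant_id", sort=True):
        row = {}
        for feat in feature_cols:
            bef = sub.loc[sub["label"] == "before", feat].dropna()
            aft = sub.loc[sub["label"] == "after", feat].dropna()
            if bef.empty or aft.empty or bef.mean() == 0.0:
                row[feat] = math.nan
            else:
                row[feat] = 100.0 * (aft.mean() - bef.mean()) / bef.mean()
        rows[pid] = row
    out = pd.DataFrame.from_dict(rows, orient="index", columns=list(feature_cols))
    out.index.name = "participant_id"
    return out
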
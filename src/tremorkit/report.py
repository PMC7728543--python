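"""Pipeline orchestration, summaries, and exports.

``run_pipeline`` chains the stages — simulate (or load) sessions →
resample → Welch PSD → spectral features → medication labeling → group
and medication statistics — and writes every tabular result as CSV.
Sessions that fail a stage are excluded with a logged reason, never
fatally.  ``mean_psd_with_ci`` computes the per-frequency mean PSD with
a t-based confidence band across sessions, the summary shown per group
and per medication condition.
"""

from __future__ import annotations

import logging
import math
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as _stats

from . import io as _io
from .medlabel import MedicationLog, label_sessions
from .preprocess import AccelSeries, to_uniform_scalar
from .spectral import (
    ANALYSIS_BAND,
    DEFAULT_BANDS,
    BandScheme,
    Periodogram,
    ZeroPowerError,
    extract_features,
    welch_psd,
)
from .stats import (
    FEATURES,
    ParticipantProfile,
    TestResult,
    before_after_tests,
    kendall_tip_updrs,
    pairwise_group_tests,
    percent_change,
)
from .synth import MedEffectModel, TremorSimConfig, simulate_cohort

__all__ = [
    "MeanPsdSummary",
    "PipelineConfig",
    "PipelineResult",
    "mean_psd_with_ci",
    "category_percentages",
    "compute_session_features",
    "run_pipeline",
    "plot_mean_psd",
]

log = logging.getLogger("tremorkit")


@dataclass
class MeanPsdSummary:
    """Pointwise mean PSD with a confidence band across sessions."""

    label: str
    condition: str  # "all" | "before" | "after"
    freqs: np.ndarray
    mean: np.ndarray
    ci_lo: np.ndarray
    ci_hi: np.ndarray
    n_sessions: int
    degenerate: bool = False  # True when n = 1 (zero-width band)


def mean_psd_with_ci(
    periodograms: list[Periodogram],
    level: float = 0.95,
    label: str = "",
    condition: str = "all",
) -> MeanPsdSummary:
    """Pointwise mean and t-based CI of several PSDs on a common grid.

    With small n the lower bound can go negative — the band is a CI for
    the mean, not a power envelope.  A single periodogram yields a
    zero-width band flagged as degenerate.
    """
    if not periodograms:
        raise ValueError("need at least one periodogram")
    if not 0 < level < 1:
        raise ValueError("level must lie in (0, 1)")
    freqs = periodograms[0].freqs
    for p in periodograms[1:]:
        if p.freqs.size != freqs.size or not np.allclose(p.freqs, freqs):
            raise ValueError("periodograms must share a common frequency grid")
    stack = np.vstack([p.psd for p in periodograms])
    mean = stack.mean(axis=0)
    n = stack.shape[0]
    if n == 1:
        return MeanPsdSummary(
            label, condition, freqs, mean, mean.copy(), mean.copy(), 1, True
        )
    sd = stack.std(axis=0, ddof=1)
    half = _stats.t.ppf(0.5 + level / 2.0, n - 1) * sd / math.sqrt(n)
    return MeanPsdSummary(
        label, condition, freqs, mean, mean - half, mean + half, n, False
    )


def category_percentages(features: pd.DataFrame) -> pd.DataFrame:
    """Per-participant percentage of sessions in each F0 symptom band.

    Percentages are computed over all sessions with defined features;
    counts are retained alongside so the unrounded closure (percentages
    summing to 100) can always be recovered.
    """
    cats = [b[0] for b in DEFAULT_BANDS.bands]
    rows = {}
    for pid, sub in features.groupby("participant_id", sort=True):
        total = len(sub)
        row: dict[str, float] = {"n_total": total}
        for cat in cats:
            n = int((sub["category"] == cat).sum())
            row[f"n_{cat}"] = n
            row[f"pct_{cat}"] = 100.0 * n / total
        rows[pid] = row
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "participant_id"
    return out


# ---------------------------------------------------------------------------
# Pipeline


@dataclass
class PipelineConfig:
    """Everything the end-to-end pipeline needs.

    Either ``input_dir`` points at a directory written by
    :func:`tremorkit.io.save_cohort` (sessions + manifest + medication +
    profiles CSVs), or ``simulate=True`` generates a cohort in memory.
    """

    out_dir: Path = Path("tremorkit-out")
    simulate: bool = True
    seed: int = 0
    n_days: int = 7
    sessions_per_day: int = 4
    attenuation: float = 0.5
    input_dir: Path | None = None
    rate_hz: float = 50.0
    welch_segment_s: float = 2.56
    welch_overlap: float = 0.5
    welch_window: str = "hann"
    band_lo: float = ANALYSIS_BAND[0]
    band_hi: float = ANALYSIS_BAND[1]
    make_plots: bool = False

    @classmethod
    def from_toml(cls, path: Path) -> "PipelineConfig":
        import tomllib

        raw = tomllib.loads(Path(path).read_text())
        kw = {}
        for key in (
            "simulate seed n_days sessions_per_day attenuation rate_hz "
            "welch_segment_s welch_overlap welch_window band_lo band_hi "
            "make_plots"
        ).split():
            if key in raw:
                kw[key] = raw[key]
        if "out_dir" in raw:
            kw["out_dir"] = Path(raw["out_dir"])
        if "input_dir" in raw:
            kw["input_dir"] = Path(raw["input_dir"])
        return cls(**kw)


@dataclass
class PipelineResult:
    """In-memory bundle of everything the pipeline computed."""

    features: pd.DataFrame
    labels: pd.DataFrame
    categories: pd.DataFrame
    kendall: TestResult | None
    kendall_by_participant: TestResult | None
    pairwise: list[TestResult]
    before_after: list[TestResult]
    pct_change: pd.DataFrame
    exclusions: pd.DataFrame
    periodograms: dict[str, Periodogram]
    profiles: list[ParticipantProfile]
    out_dir: Path


def compute_session_features(
    sessions: list[AccelSeries],
    config: PipelineConfig | None = None,
) -> tuple[pd.DataFrame, dict[str, Periodogram], pd.DataFrame]:
    """Run preprocess + spectral stages over sessions, tracking exclusions.

    Returns (features table, periodograms by session id, exclusions
    table).  Every input session appears either in the features table or
    in the exclusions table with a reason.
    """
    config = config or PipelineConfig()
    rows, excl = [], []
    pgs: dict[str, Periodogram] = {}
    for sess in sessions:
        sid = sess.session_id or "<unnamed>"
        try:
            uni = to_uniform_scalar(sess, config.rate_hz)
            pg = welch_psd(
                uni,
                segment_s=config.welch_segment_s,
                overlap_frac=config.welch_overlap,
                window=config.welch_window,
            )
            feats = extract_features(pg, config.band_lo, config.band_hi)
        except (ValueError, ZeroPowerError) as err:
            log.warning("session %s excluded: %s", sid, err)
            excl.append(dict(session_id=sid, reason=str(err)))
            continue
        pgs[sid] = pg
        rows.append(
            dict(
                participant_id=sess.participant_id,
                session_id=sid,
                session_start=sess.session_start,
                **feats.as_dict(),
            )
        )
    features = pd.DataFrame(rows)
    exclusions = pd.DataFrame(excl, columns=["session_id", "reason"])
    return features, pgs, exclusions


def _write_results(result: PipelineResult) -> None:
    out = result.out_dir
    out.mkdir(parents=True, exist_ok=True)
    result.features.to_csv(out / "features.csv", index=False)
    result.labels.to_csv(out / "labels.csv", index=False)
    cats = result.categories.copy()
    for col in cats.columns:
        if col.startswith("pct_"):
            cats[col] = cats[col].round(0).astype(int)
    cats.to_csv(out / "categories.csv")
    result.pct_change.to_csv(out / "percent_change.csv")

    def _tests_df(tests: list[TestResult]) -> pd.DataFrame:
        return pd.DataFrame(
            dict(
                comparison=[t.comparison for t in tests],
                feature=[t.feature for t in tests],
                statistic=[t.statistic for t in tests],
                z=[t.z for t in tests],
                p_value=[t.p_value for t in tests],
                n=[t.n for t in tests],
            )
        )

    _tests_df(result.pairwise).to_csv(out / "stats_pairwise.csv", index=False)
    _tests_df(result.before_after).to_csv(
        out / "stats_before_after.csv", index=False
    )
    kend = [
        t
        for t in (result.kendall, result.kendall_by_participant)
        if t is not None
    ]
    _tests_df(kend).to_csv(out / "stats_kendall.csv", index=False)
    result.exclusions.to_csv(out / "exclusions.csv", index=False)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full analysis and write CSV artifacts to ``out_dir``."""
    if config.simulate:
        cohort = simulate_cohort(
            config.seed,
            n_days=config.n_days,
            sessions_per_day=config.sessions_per_day,
            med=MedEffectModel(attenuation=config.attenuation),
        )
        sessions, logs, profiles = cohort.sessions, cohort.logs, cohort.profiles
    else:
        if config.input_dir is None:
            raise ValueError("input_dir required when simulate=False")
        sessions = _io.load_sessions(config.input_dir)
        logs = _io.read_medication_csv(Path(config.input_dir) / "medication.csv")
        profiles = _io.read_profiles_csv(Path(config.input_dir) / "profiles.csv")

    features, pgs, exclusions = compute_session_features(sessions, config)
    log.info(
        "featured %d sessions, excluded %d", len(features), len(exclusions)
    )

    index = pd.DataFrame(
        dict(
            session_id=[s.session_id for s in sessions],
            participant_id=[s.participant_id for s in sessions],
            session_start=[s.session_start for s in sessions],
        )
    )
    index = index[index["session_id"].isin(features["session_id"])]
    labels = label_sessions(index, logs)

    kendall = kendall_by_pid = None
    try:
        kendall = kendall_tip_updrs(features, profiles, unit="session")
        kendall_by_pid = kendall_tip_updrs(features, profiles, unit="participant")
    except ValueError as err:
        log.warning("Kendall correlation skipped: %s", err)
    pairwise = pairwise_group_tests(features, profiles)
    ba = before_after_tests(features, labels)
    pct = percent_change(features, labels)
    cats = category_percentages(features)

    result = PipelineResult(
        features=features,
        labels=labels,
        categories=cats,
        kendall=kendall,
        kendall_by_participant=kendall_by_pid,
        pairwise=pairwise,
        before_after=ba,
        pct_change=pct,
        exclusions=exclusions,
        periodograms=pgs,
        profiles=profiles,
        out_dir=Path(config.out_dir),
    )
    _write_results(result)
    if config.make_plots:
        _plot_groups(result, profiles)
    return result


# ---------------------------------------------------------------------------
# Plotting (headless-safe, optional)


def plot_mean_psd(
    summary: MeanPsdSummary,
    path: Path,
    scheme: BandScheme = DEFAULT_BANDS,
) -> None:
    """Plot a mean PSD with its CI band and shaded symptom bands."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 3.2))
    shades = ["0.92", "0.85", "0.92", "0.85"]
    for (name, lo, hi), shade in zip(scheme.bands, shades):
        ax.axvspan(lo, hi, color=shade, zorder=0)
        ax.text(
            (lo + hi) / 2, 0.97, name, transform=ax.get_xaxis_transform(),
            ha="center", va="top", fontsize=7, color="0.4",
        )
    ax.fill_between(
        summary.freqs, summary.ci_lo, summary.ci_hi, alpha=0.35,
        label="95% CI", zorder=1,
    )
    ax.plot(summary.freqs, summary.mean, lw=1.2, zorder=2, label="mean PSD")
    ax.set_xlim(scheme.lo, scheme.hi)
    ax.set_xlabel("frequency (Hz)")
    ax.set_ylabel("PSD ((m/s²)²/Hz)")
    ax.set_title(f"{summary.label} [{summary.condition}] n={summary.n_sessions}")
    ax.legend(loc="upper right", fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _plot_groups(result: PipelineResult, profiles: list[ParticipantProfile]) -> None:
    group_of = {p.participant_id: p.group for p in profiles}
    by_group: dict[str, list[Periodogram]] = {}
    sid_to_pid = dict(
        zip(result.features["session_id"], result.features["participant_id"])
    )
    for sid, pg in result.periodograms.items():
        g = group_of.get(sid_to_pid.get(sid))
        if g:
            by_group.setdefault(g, []).append(pg)
    plot_dir = result.out_dir / "plots"
    plot_dir.mkdir(parents=True, exist_ok=True)
    for g, pgs in by_group.items():
        summary = mean_psd_with_ci(pgs, label=g)
        plot_mean_psd(summary, plot_dir / f"mean_psd_{g}.png")


def configure_logging(verbose: bool = False) -> None:
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.DEBUG if verbose else logging.INFO)
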
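"""Synthetic accelerometer sessions with known tremor ground truth.

The generator emulates the measurement setting: a phone resting
horizontally on the palm for 10 seconds, sampling a triaxial
accelerometer at a nominal 50 Hz.  The simulated signal is

    a(t) = g·n  +  m·A·sin(φ(t))·n  +  ε(t),

where ``n`` is the gravity axis (the tremor oscillation is applied along
the same axis — the dominant vertical bobbing of a palm-held phone),
``g = 9.81 m/s²``, ``A`` the tremor amplitude, ``m ∈ [0, 1]`` a
medication-dependent amplitude multiplier, ``ε`` white sensor/hand
noise, and the instantaneous frequency behind the phase ``φ`` wanders
slowly around the tremor frequency (real tremor is not a pure tone).

Sampling-time irregularity is modelled in two regimes observed on real
devices: per-interval Gaussian jitter (a phone that roughly holds its
rate) and dropout bursts (stretches where the effective rate collapses
to a fraction of nominal).

A medication intake attenuates the tremor amplitude through a
piecewise-linear effect profile: no effect before onset (~15 min, the
minimum time oral PD medication needs to act), maximal attenuation at
the peak, and a linear return to baseline by wear-off.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import datetime, time, timedelta, timezone

import numpy as np
import pandas as pd

from .medlabel import MedicationLog
from .preprocess import AccelSeries
from .stats import ParticipantProfile

__all__ = [
    "GRAVITY",
    "TremorSimConfig",
    "MedEffectModel",
    "Regimen",
    "CohortSim",
    "simulate_session",
    "simulate_participant",
    "simulate_cohort",
    "STUDY_COHORT",
]

GRAVITY = 9.81  # m/s²

_JITTER_MODELS = ("none", "gaussian", "dropout-burst")


@dataclass(frozen=True)
class TremorSimConfig:
    """Ground-truth parameters of a simulated game session.

    Parameters
    ----------
    tremor_freq_hz : float
        Centre frequency of the tremor oscillation, in (0, 25) Hz.
        Parkinsonian rest tremor sits at 3–6 Hz.
    tremor_amp : float
        Acceleration amplitude of the oscillation, m/s².
    freq_jitter_hz : float
        Scale of the slow random-walk wander of the instantaneous
        frequency; the wander is clipped to ±3× this value.
    noise_sd : float
        Standard deviation of additive white noise per axis, m/s².
    gravity_axis : tuple
        Unit 3-vector giving the phone's vertical; tremor is applied
        along this axis.
    session_duration_s, nominal_rate_hz : float
        10-second sessions at a nominal 50 Hz by default.
    jitter_model : str
        "none" (exact grid), "gaussian" (per-interval timing jitter), or
        "dropout-burst" (intermittent collapses of the sampling rate).
    timing_jitter_frac : float
        For the gaussian model: st.dev. of each inter-sample interval as
        a fraction of the nominal interval.
    seed : int
        Default RNG seed; fixed seed gives bit-identical sessions.
    """

    tremor_freq_hz: float = 5.0
    tremor_amp: float = 0.5
    freq_jitter_hz: float = 0.1
    noise_sd: float = 0.1
    gravity_axis: tuple[float, float, float] = (0.0, 0.0, 1.0)
    session_duration_s: float = 10.0
    nominal_rate_hz: float = 50.0
    jitter_model: str = "gaussian"
    timing_jitter_frac: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        scalars = (
            self.tremor_freq_hz,
            self.tremor_amp,
            self.freq_jitter_hz,
            self.noise_sd,
            self.session_duration_s,
            self.nominal_rate_hz,
            self.timing_jitter_frac,
        )
        if not all(math.isfinite(v) for v in scalars):
            raise ValueError("config values must be finite")
        if not 0 < self.tremor_freq_hz < 25:
            raise ValueError("tremor_freq_hz must lie in (0, 25)")
        if self.tremor_amp < 0 or self.freq_jitter_hz < 0 or self.noise_sd < 0:
            raise ValueError("amplitudes and noise scales must be >= 0")
        if self.session_duration_s <= 0 or self.nominal_rate_hz <= 0:
            raise ValueError("duration and rate must be positive")
        if self.jitter_model not in _JITTER_MODELS:
            raise ValueError(f"jitter_model must be one of {_JITTER_MODELS}")
        ax = np.asarray(self.gravity_axis, dtype=float)
        if ax.shape != (3,) or not np.all(np.isfinite(ax)):
            raise ValueError("gravity_axis must be a finite 3-vector")
        if not math.isclose(float(np.linalg.norm(ax)), 1.0, rel_tol=1e-6):
            raise ValueError("gravity_axis must be a unit vector")

    def replace(self, **kw) -> "TremorSimConfig":
        from dataclasses import replace as _replace

        return _replace(self, **kw)


@dataclass(frozen=True)
class MedEffectModel:
    """Piecewise-linear medication effect on tremor amplitude.

    The amplitude multiplier as a function of minutes since intake is 1
    before ``onset_min``, falls linearly to ``1 − attenuation`` at
    ``peak_min``, and returns linearly to 1 at ``wearoff_min``.
    Defaults (15 / 60 / 240 min) follow the typical onset and duration
    of oral levodopa.
    """

    onset_min: float = 15.0
    peak_min: float = 60.0
    wearoff_min: float = 240.0
    attenuation: float = 0.5

    def __post_init__(self) -> None:
        if not self.onset_min < self.peak_min < self.wearoff_min:
            raise ValueError("need onset_min < peak_min < wearoff_min")
        if not 0.0 <= self.attenuation <= 1.0:
            raise ValueError("attenuation must lie in [0, 1]")

    def amp_multiplier(self, minutes_since_intake: float | None) -> float:
        """Tremor amplitude multiplier, in [1 − attenuation, 1]."""
        d = minutes_since_intake
        if d is None or d < self.onset_min or d >= self.wearoff_min:
            return 1.0
        low = 1.0 - self.attenuation
        if d <= self.peak_min:
            frac = (d - self.onset_min) / (self.peak_min - self.onset_min)
            return 1.0 - frac * self.attenuation
        frac = (d - self.peak_min) / (self.wearoff_min - self.peak_min)
        return low + frac * self.attenuation


@dataclass(frozen=True)
class Regimen:
    """A participant's daily medication schedule."""

    intakes_per_day: int
    intake_times: tuple[time, ...]

    def __post_init__(self) -> None:
        if self.intakes_per_day < 1:
            raise ValueError("intakes_per_day must be >= 1")
        if len(self.intake_times) != self.intakes_per_day:
            raise ValueError("len(intake_times) must equal intakes_per_day")

    @classmethod
    def evenly_spaced(
        cls, intakes_per_day: int, first_hour: int = 8, last_hour: int = 20
    ) -> "Regimen":
        """Intakes spread evenly between ``first_hour`` and ``last_hour``."""
        if intakes_per_day == 1:
            hours = [first_hour]
        else:
            step = (last_hour - first_hour) / (intakes_per_day - 1)
            hours = [first_hour + i * step for i in range(intakes_per_day)]
        times = tuple(
            time(hour=int(h), minute=int(round((h % 1) * 60))) for h in hours
        )
        return cls(intakes_per_day=intakes_per_day, intake_times=times)


# ---------------------------------------------------------------------------
# Session-level simulation


def _sample_times_s(cfg: TremorSimConfig, rng: np.random.Generator) -> np.ndarray:
    """Sample instants in seconds: 0 ... ≈ session_duration_s."""
    dt = 1.0 / cfg.nominal_rate_hz
    n_int = int(round(cfg.session_duration_s * cfg.nominal_rate_hz))
    if cfg.jitter_model == "none":
        return np.arange(n_int + 1) * dt
    if cfg.jitter_model == "gaussian":
        iv = dt * (1.0 + cfg.timing_jitter_frac * rng.standard_normal(n_int))
        iv = np.clip(iv, 0.1 * dt, None)
        return np.concatenate(([0.0], np.cumsum(iv)))
    # dropout-burst: keep only every k-th sample inside 1-2 burst windows
    t = np.arange(n_int + 1) * dt
    keep = np.ones(t.size, dtype=bool)
    for _ in range(int(rng.integers(1, 3))):
        length = rng.uniform(0.5, 1.5)
        start = rng.uniform(0.0, max(cfg.session_duration_s - length, 0.0))
        in_burst = (t >= start) & (t < start + length)
        idx = np.flatnonzero(in_burst)
        drop = idx[np.arange(idx.size) % 5 != 0]
        keep[drop] = False
    keep[0] = keep[-1] = True
    return t[keep]


def _instantaneous_freq(
    cfg: TremorSimConfig, t: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Tremor frequency wandering as a clipped slow random walk."""
    if cfg.freq_jitter_hz == 0.0:
        return np.full(t.size, cfg.tremor_freq_hz)
    dt = np.diff(t, prepend=t[0])
    # increments scaled so the walk moves ~freq_jitter_hz over ~1 s
    steps = rng.normal(0.0, cfg.freq_jitter_hz, size=t.size) * np.sqrt(
        np.clip(dt, 0.0, None)
    )
    wander = np.clip(
        np.cumsum(steps), -3.0 * cfg.freq_jitter_hz, 3.0 * cfg.freq_jitter_hz
    )
    return cfg.tremor_freq_hz + wander


def simulate_session(
    cfg: TremorSimConfig,
    amp_multiplier: float = 1.0,
    *,
    rng: np.random.Generator | None = None,
) -> AccelSeries:
    """Generate one timestamped triaxial session.

    ``amp_multiplier`` scales the tremor amplitude (medication effect);
    gravity and noise are unaffected.  With ``rng=None`` a generator
    seeded from ``cfg.seed`` is used, so a fixed config yields
    bit-identical output.
    """
    if not 0.0 <= amp_multiplier <= 1.0:
        raise ValueError("amp_multiplier must lie in [0, 1]")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    t = _sample_times_s(cfg, rng)
    axis = np.asarray(cfg.gravity_axis, dtype=float)

    f_inst = _instantaneous_freq(cfg, t, rng)
    phase0 = rng.uniform(0.0, 2.0 * np.pi)
    phase = phase0 + 2.0 * np.pi * np.cumsum(f_inst * np.diff(t, prepend=t[0]))
    tremor = amp_multiplier * cfg.tremor_amp * np.sin(phase)

    sig = GRAVITY * axis[None, :] + tremor[:, None] * axis[None, :]
    if cfg.noise_sd > 0:
        sig = sig + rng.normal(0.0, cfg.noise_sd, size=(t.size, 3))
    return AccelSeries(
        t=t * 1000.0,
        x=sig[:, 0],
        y=sig[:, 1],
        z=sig[:, 2],
        nominal_rate_hz=cfg.nominal_rate_hz,
    )


# ---------------------------------------------------------------------------
# Participant- and cohort-level simulation

_UTC = timezone.utc
_DEFAULT_START = datetime(2024, 3, 1, tzinfo=_UTC)
_PLAY_WINDOW_H = (7.5, 22.5)  # sessions scattered over the waking day


def _minutes_since_latest_intake(
    start: datetime, intakes: list[datetime]
) -> float | None:
    prior = [it for it in intakes if it <= start]
    if not prior:
        return None
    return (start - max(prior)).total_seconds() / 60.0


def simulate_participant(
    profile: ParticipantProfile,
    regimen: Regimen,
    med: MedEffectModel,
    cfg: TremorSimConfig,
    n_days: int,
    sessions_per_day: int,
    seed: int,
    start_date: datetime = _DEFAULT_START,
) -> tuple[list[AccelSeries], list[MedicationLog], pd.DataFrame]:
    """Simulate a participant's sessions and medication log over ``n_days``.

    Session start times are scattered uniformly over each waking day
    (07:30–22:30), rejecting schedules with overlapping sessions.  Each
    session's tremor amplitude multiplier follows the medication-effect
    model evaluated at the time since the latest intake.

    Returns the sessions (with UTC start times), the intake log, and a
    ground-truth table (session_id, session_start, delta_min,
    amp_multiplier, tremor_freq_hz, tremor_amp).
    """
    if n_days < 1:
        raise ValueError("n_days must be >= 1")
    if sessions_per_day < 1:
        raise ValueError("sessions_per_day must be >= 1")
    if start_date.tzinfo is None:
        raise ValueError("start_date must be timezone-aware")

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    ss = np.random.SeedSequence(seed + 1)
    children = ss.spawn(n_days * sessions_per_day)

    logs: list[MedicationLog] = []
    intakes: list[datetime] = []
    for d in range(n_days):
        day = start_date + timedelta(days=d)
        for tt in regimen.intake_times:
            it = day.replace(hour=tt.hour, minute=tt.minute, second=0, microsecond=0)
            intakes.append(it)
            logs.append(
                MedicationLog(
                    participant_id=profile.participant_id,
                    intake_time=it,
                    intakes_per_day=regimen.intakes_per_day,
                )
            )

    lo_s = _PLAY_WINDOW_H[0] * 3600.0
    hi_s = _PLAY_WINDOW_H[1] * 3600.0
    min_gap = cfg.session_duration_s + 30.0

    sessions: list[AccelSeries] = []
    truth_rows = []
    k = 0
    for d in range(n_days):
        day = start_date + timedelta(days=d)
        for attempt in range(1000):
            offs = np.sort(rng.uniform(lo_s, hi_s, size=sessions_per_day))
            if sessions_per_day == 1 or np.all(np.diff(offs) >= min_gap):
                break
        else:
            raise ValueError("could not schedule non-overlapping sessions")
        for off in offs:
            start = day + timedelta(seconds=float(off))
            delta = _minutes_since_latest_intake(start, intakes)
            mult = med.amp_multiplier(delta)
            sid = f"{profile.participant_id}-d{d:03d}s{int(off)}"
            sess = simulate_session(
                cfg, mult, rng=np.random.default_rng(children[k])
            )
            k += 1
            sess.participant_id = profile.participant_id
            sess.session_id = sid
            sess.session_start = start
            sessions.append(sess)
            truth_rows.append(
                dict(
                    session_id=sid,
                    participant_id=profile.participant_id,
                    session_start=start,
                    delta_min=math.nan if delta is None else delta,
                    amp_multiplier=mult,
                    tremor_freq_hz=cfg.tremor_freq_hz,
                    tremor_amp=cfg.tremor_amp,
                )
            )
    return sessions, logs, pd.DataFrame(truth_rows)


@dataclass
class CohortSim:
    """A simulated study cohort: sessions, intake logs, profiles, truth."""

    sessions: list[AccelSeries]
    logs: list[MedicationLog]
    profiles: list[ParticipantProfile]
    truth: pd.DataFrame

    def session_index(self) -> pd.DataFrame:
        return pd.DataFrame(
            dict(
                session_id=[s.session_id for s in self.sessions],
                participant_id=[s.participant_id for s in self.sessions],
                session_start=[s.session_start for s in self.sessions],
            )
        )


#: Cohort template mirroring the study's group structure: participant id →
#: (group, UPDRS II tremor item, UPDRS II total, tremor frequency Hz,
#:  intakes/day, rigidity, bradykinesia).  Tremor amplitudes scale with the
#: self-reported item; participants playing with the tremor hand get the
#: full amplitude.
STUDY_COHORT: dict[str, tuple[str, int, int, float, int, bool, bool]] = {
    "S01": ("hand_tremor", 2, 14, 4.5, 2, False, False),
    "S02": ("no_tremor", 0, 6, 4.0, 2, True, False),
    "S05": ("hand_tremor", 1, 9, 5.0, 3, False, False),
    "S06": ("tremor", 3, 31, 4.2, 3, False, False),
    "S07": ("tremor", 1, 12, 7.0, 2, False, False),
    "S08": ("tremor", 1, 10, 7.5, 4, False, False),
    "S09": ("no_tremor", 0, 3, 4.0, 2, True, False),
    "S10": ("plays_with_hand_tremor", 2, 15, 4.8, 3, False, False),
    "S11": ("no_tremor", 0, 8, 4.0, 3, True, True),
    "S12": ("tremor", 1, 11, 5.5, 2, False, False),
    "S13": ("plays_with_hand_tremor", 2, 20, 7.2, 4, False, False),
}

#: Tremor acceleration amplitude (m/s²) by UPDRS tremor item, for the
#: signal actually reaching the device.
_AMP_BY_ITEM = {0: 0.02, 1: 0.2, 2: 0.45, 3: 0.9, 4: 1.4}
#: Playing with the tremor-affected hand transmits the full oscillation.
_PLAYS_WITH_TREMOR_BOOST = 2.2


def simulate_cohort(
    seed: int,
    n_days: int = 28,
    sessions_per_day: int = 5,
    med: MedEffectModel | None = None,
    base_cfg: TremorSimConfig | None = None,
    cohort: dict | None = None,
) -> CohortSim:
    """Simulate a full study cohort with known ground truth.

    The default cohort mirrors the study's composition: 11 participants
    across the four tremor groups (3 with no tremor, 4 with tremor
    elsewhere, 2 with hand tremor playing with the unaffected hand, 2
    playing with the tremor-affected hand), one month of ~5 sessions a
    day, with medication attenuating the tremor amplitude by 50% at peak
    effect.
    """
    med = med or MedEffectModel()
    base_cfg = base_cfg or TremorSimConfig()
    cohort = cohort or STUDY_COHORT
    ss = np.random.SeedSequence(seed)
    pid_seeds = ss.generate_state(len(cohort)) % (2**31)

    all_sessions: list[AccelSeries] = []
    all_logs: list[MedicationLog] = []
    profiles: list[ParticipantProfile] = []
    truths = []
    for (pid, spec), pseed in zip(sorted(cohort.items()), pid_seeds):
        group, item, total, freq, intakes, rigid, brady = spec
        profile = ParticipantProfile(
            participant_id=pid,
            updrs2_total=total,
            updrs_tremor_item=item,
            group=group,
            rigidity=rigid,
            bradykinesia=brady,
        )
        amp = _AMP_BY_ITEM[item]
        if group == "plays_with_hand_tremor":
            amp *= _PLAYS_WITH_TREMOR_BOOST
        cfg = base_cfg.replace(tremor_freq_hz=freq, tremor_amp=amp)
        sessions, logs, truth = simulate_participant(
            profile,
            Regimen.evenly_spaced(intakes),
            med,
            cfg,
            n_days=n_days,
            sessions_per_day=sessions_per_day,
            seed=int(pseed),
        )
        profiles.append(profile)
        all_sessions.extend(sessions)
        all_logs.extend(logs)
        truths.append(truth)
    return CohortSim(
        sessions=all_sessions,
        logs=all_logs,
        profiles=profiles,
        truth=pd.concat(truths, ignore_index=True),
    )
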
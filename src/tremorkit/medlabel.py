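"""Before/after medication labeling of game sessions.

Each game session is attributed to the medication intake closest in time
and then labeled relative to that intake.  Window widths depend on the
participant's regimen, because a person on one or two intakes a day has
long stretches of un-medicated time while someone on more frequent
intakes cycles quickly:

* one or two intakes per day — "before" if played between 5 hours before
  and 15 minutes after the intake; "after" if between 30 minutes and
  3 hours after;
* more than two intakes per day — "before" between 1 hour before and
  15 minutes after; "after" between 30 and 90 minutes after.

The 15-minute grace period after an intake still counts as "before"
because oral PD medication needs at least that long to act.  Sessions
outside both windows are excluded from the medication-effect analysis.
All window endpoints are inclusive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import datetime

import pandas as pd

__all__ = [
    "MedicationLog",
    "LabeledSession",
    "nearest_intake",
    "label_session",
    "label_sessions",
]

# (before_lo, before_hi, after_lo, after_hi) in signed minutes from intake
_WINDOWS_LOW_FREQ = (-300.0, 15.0, 30.0, 180.0)   # <= 2 intakes/day
_WINDOWS_HIGH_FREQ = (-60.0, 15.0, 30.0, 90.0)    # > 2 intakes/day


@dataclass(frozen=True)
class MedicationLog:
    """A single logged medication intake."""

    participant_id: str
    intake_time: datetime
    intakes_per_day: int

    def __post_init__(self) -> None:
        if self.intakes_per_day < 1:
            raise ValueError("intakes_per_day must be >= 1")


@dataclass(frozen=True)
class LabeledSession:
    """A session's association with its nearest intake and its label."""

    session_id: str
    nearest_intake: datetime | None
    delta_min: float | None
    label: str  # "before" | "after" | "excluded"
    reason: str | None = None


def nearest_intake(
    session_start: datetime, logs: list[MedicationLog]
) -> tuple[MedicationLog, float]:
    """Find the intake minimizing ``|session_start − intake|``.

    Returns the winning log and the signed offset in minutes
    (positive = session played after the intake).  Exact ties are broken
    toward the earlier intake.
    """
    if not logs:
        raise ValueError("no medication logs for participant")
    best: MedicationLog | None = None
    best_delta = math.inf
    for log in sorted(logs, key=lambda lg: lg.intake_time):
        delta = (session_start - log.intake_time).total_seconds() / 60.0
        if abs(delta) < abs(best_delta):
            best, best_delta = log, delta
    assert best is not None
    return best, best_delta


def label_session(delta_min: float, intakes_per_day: int) -> str:
    """Label a session by its signed offset (minutes) from the intake."""
    if not math.isfinite(delta_min):
        raise ValueError("delta_min must be finite")
    if intakes_per_day < 1:
        raise ValueError("intakes_per_day must be >= 1")
    b_lo, b_hi, a_lo, a_hi = (
        _WINDOWS_LOW_FREQ if intakes_per_day <= 2 else _WINDOWS_HIGH_FREQ
    )
    if b_lo <= delta_min <= b_hi:
        return "before"
    if a_lo <= delta_min <= a_hi:
        return "after"
    return "excluded"


def label_sessions(
    sessions: pd.DataFrame, logs: list[MedicationLog]
) -> pd.DataFrame:
    """Label a batch of sessions against their participants' intake logs.

    Parameters
    ----------
    sessions : DataFrame
        Columns ``session_id``, ``participant_id``, ``session_start``
        (timezone-aware datetimes).
    logs : list of MedicationLog

    Returns
    -------
    DataFrame with columns ``session_id``, ``participant_id``,
    ``nearest_intake``, ``delta_min``, ``label``, ``reason``.  Sessions
    whose participant has no logged intakes are excluded with a reason.
    """
    by_pid: dict[str, list[MedicationLog]] = {}
    for log in logs:
        by_pid.setdefault(log.participant_id, []).append(log)

    rows = []
    for rec in sessions.itertuples(index=False):
        pid_logs = by_pid.get(rec.participant_id, [])
        if not pid_logs:
            rows.append(
                dict(
                    session_id=rec.session_id,
                    participant_id=rec.participant_id,
                    nearest_intake=pd.NaT,
                    delta_min=math.nan,
                    label="excluded",
                    reason="no medication logs",
                )
            )
            continue
        log, delta = nearest_intake(rec.session_start, pid_logs)
        label = label_session(delta, log.intakes_per_day)
        rows.append(
            dict(
                session_id=rec.session_id,
                participant_id=rec.participant_id,
                nearest_intake=log.intake_time,
                delta_min=delta,
                label=label,
                reason=None if label != "excluded" else "outside windows",
            )
        )
    return pd.DataFrame(rows)
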
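"""CSV/JSON persistence for sessions, medication logs, and profiles.

Sessions are stored one CSV per session (``timestamp_ms,x,y,z``) next to
a JSON manifest holding identities, UTC start instants and — for
simulated data — the ground truth.  Medication logs and participant
profiles are single CSVs.
"""

from __future__ import annotations

import json
from datetime import datetime
from pathlib import Path

import numpy as np
import pandas as pd

from .medlabel import MedicationLog
from .preprocess import AccelSeries
from .stats import ParticipantProfile
from .synth import CohortSim

__all__ = [
    "write_session_csv",
    "read_session_csv",
    "write_medication_csv",
    "read_medication_csv",
    "write_profiles_csv",
    "read_profiles_csv",
    "save_cohort",
    "load_sessions",
]


def write_session_csv(path: Path, series: AccelSeries) -> None:
    df = pd.DataFrame(
        dict(timestamp_ms=series.t, x=series.x, y=series.y, z=series.z)
    )
    df.to_csv(path, index=False)


def read_session_csv(
    path: Path,
    participant_id: str | None = None,
    session_id: str | None = None,
    session_start: datetime | None = None,
    nominal_rate_hz: float = 50.0,
) -> AccelSeries:
    df = pd.read_csv(path)
    return AccelSeries(
        t=df["timestamp_ms"].to_numpy(),
        x=df["x"].to_numpy(),
        y=df["y"].to_numpy(),
        z=df["z"].to_numpy(),
        participant_id=participant_id,
        session_id=session_id or Path(path).stem,
        session_start=session_start,
        nominal_rate_hz=nominal_rate_hz,
    )


def write_medication_csv(path: Path, logs: list[MedicationLog]) -> None:
    df = pd.DataFrame(
        dict(
            participant=[lg.participant_id for lg in logs],
            intake_iso8601=[lg.intake_time.isoformat() for lg in logs],
            intakes_per_day=[lg.intakes_per_day for lg in logs],
        )
    )
    df.to_csv(path, index=False)


def read_medication_csv(path: Path) -> list[MedicationLog]:
    df = pd.read_csv(path)
    return [
        MedicationLog(
            participant_id=str(r.participant),
            intake_time=datetime.fromisoformat(r.intake_iso8601),
            intakes_per_day=int(r.intakes_per_day),
        )
        for r in df.itertuples(index=False)
    ]


def write_profiles_csv(path: Path, profiles: list[ParticipantProfile]) -> None:
    df = pd.DataFrame(
        dict(
            participant_id=[p.participant_id for p in profiles],
            updrs2_total=[p.updrs2_total for p in profiles],
            updrs_tremor_item=[p.updrs_tremor_item for p in profiles],
            group=[p.group for p in profiles],
            rigidity=[p.rigidity for p in profiles],
            bradykinesia=[p.bradykinesia for p in profiles],
        )
    )
    df.to_csv(path, index=False)


def read_profiles_csv(path: Path) -> list[ParticipantProfile]:
    df = pd.read_csv(path)
    return [
        ParticipantProfile(
            participant_id=str(r.participant_id),
            updrs2_total=int(r.updrs2_total),
            updrs_tremor_item=int(r.updrs_tremor_item),
            group=str(r.group),
            rigidity=bool(r.rigidity),
            bradykinesia=bool(r.bradykinesia),
        )
        for r in df.itertuples(index=False)
    ]


def save_cohort(directory: Path, cohort: CohortSim) -> None:
    """Write a simulated cohort as CSVs plus a JSON manifest."""
    directory = Path(directory)
    sess_dir = directory / "sessions"
    sess_dir.mkdir(parents=True, exist_ok=True)
    manifest = []
    truth_by_sid = cohort.truth.set_index("session_id")
    for sess in cohort.sessions:
        fname = f"{sess.session_id}.csv"
        write_session_csv(sess_dir / fname, sess)
        row = truth_by_sid.loc[sess.session_id]
        manifest.append(
            dict(
                participant=sess.participant_id,
                session_id=sess.session_id,
                file=f"sessions/{fname}",
                session_start=sess.session_start.isoformat(),
                nominal_rate_hz=sess.nominal_rate_hz,
                ground_truth=dict(
                    amp_multiplier=float(row["amp_multiplier"]),
                    tremor_freq_hz=float(row["tremor_freq_hz"]),
                    tremor_amp=float(row["tremor_amp"]),
                ),
            )
        )
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=1))
    write_medication_csv(directory / "medication.csv", cohort.logs)
    write_profiles_csv(directory / "profiles.csv", cohort.profiles)


def load_sessions(directory: Path) -> list[AccelSeries]:
    """Load sessions recorded in a directory's ``manifest.json``."""
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    sessions = []
    for entry in manifest:
        sessions.append(
            read_session_csv(
                directory / entry["file"],
                participant_id=entry["participant"],
                session_id=entry["session_id"],
                session_start=datetime.fromisoformat(entry["session_start"]),
                nominal_rate_hz=float(entry.get("nominal_rate_hz", 50.0)),
            )
        )
    return sessions
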
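"""Resampling of irregular accelerometer streams to uniform scalar series.

Consumer smartphones deliver accelerometer samples at a nominal rate
(50 Hz here) but with device-dependent timing irregularity: some phones
hold the rate almost exactly, others drift or drop to a fraction of the
requested rate for stretches of a session.  Spectral estimation requires
a uniform grid, so each axis is linearly interpolated onto one; the
triaxial signal is then reduced to a single orientation-invariant scalar
(the Euclidean magnitude) and the session mean — dominated by gravity —
is removed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime

import numpy as np

__all__ = [
    "AccelSeries",
    "UniformSeries",
    "SessionTooShortError",
    "resample_uniform",
    "to_uniform_scalar",
]


class SessionTooShortError(ValueError):
    """Session span is too short to yield a usable uniform series."""


@dataclass
class AccelSeries:
    """Timestamped triaxial acceleration for one game session.

    Parameters
    ----------
    t : array_like
        Sample timestamps in milliseconds since the session start,
        strictly increasing.
    x, y, z : array_like
        Acceleration along each device axis, m/s².
    participant_id, session_id : str, optional
        Identifiers carried through the pipeline.
    session_start : datetime, optional
        Absolute UTC start instant of the session.
    nominal_rate_hz : float
        The rate the device was asked to sample at (informational).
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    participant_id: str | None = None
    session_id: str | None = None
    session_start: datetime | None = None
    nominal_rate_hz: float = 50.0

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        n = self.t.size
        if n < 2:
            raise ValueError("a session needs at least 2 samples")
        if not (self.x.size == self.y.size == self.z.size == n):
            raise ValueError("t, x, y, z must have equal length")
        for name, arr in (("t", self.t), ("x", self.x), ("y", self.y), ("z", self.z)):
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"non-finite values in {name}")
        dt = np.diff(self.t)
        if np.any(dt <= 0):
            raise ValueError("timestamps must be strictly increasing (no duplicates)")

    @property
    def duration_s(self) -> float:
        """Observed span of the session in seconds."""
        return float(self.t[-1] - self.t[0]) / 1000.0

    def magnitude(self) -> np.ndarray:
        """Per-sample Euclidean norm of the acceleration vector, m/s²."""
        return np.sqrt(self.x**2 + self.y**2 + self.z**2)


@dataclass
class UniformSeries:
    """A uniformly sampled, mean-removed scalar acceleration series."""

    values: np.ndarray
    rate_hz: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.rate_hz <= 0 or not np.isfinite(self.rate_hz):
            raise ValueError("rate_hz must be positive and finite")
        if self.values.size < 2:
            raise ValueError("uniform series needs at least 2 samples")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite values in series")

    def __len__(self) -> int:
        return self.values.size

    @property
    def duration_s(self) -> float:
        return (len(self) - 1) / self.rate_hz


def resample_uniform(series: AccelSeries, target_rate_hz: float = 50.0) -> AccelSeries:
    """Linearly interpolate each axis onto a uniform time grid.

    The grid is anchored at the first sample (relative t = 0) and extends
    in steps of ``1/target_rate_hz`` up to the last observed timestamp;
    no extrapolation beyond the observed span is performed.  Grid points
    that coincide with input timestamps reproduce the input values to
    machine precision.

    Raises
    ------
    ValueError
        If the session spans less than two grid intervals.
    """
    if target_rate_hz <= 0 or not np.isfinite(target_rate_hz):
        raise ValueError("target_rate_hz must be positive and finite")
    rel = series.t - series.t[0]
    span_s = rel[-1] / 1000.0
    if span_s < 2.0 / target_rate_hz:
        raise SessionTooShortError(
            f"session spans {span_s:.4f} s, below 2 grid intervals at "
            f"{target_rate_hz} Hz"
        )
    step_ms = 1000.0 / target_rate_hz
    n = int(np.floor(rel[-1] / step_ms + 1e-9)) + 1
    grid = np.arange(n) * step_ms
    return AccelSeries(
        t=grid,
        x=np.interp(grid, rel, series.x),
        y=np.interp(grid, rel, series.y),
        z=np.interp(grid, rel, series.z),
        participant_id=series.participant_id,
        session_id=series.session_id,
        session_start=series.session_start,
        nominal_rate_hz=target_rate_hz,
    )


def to_uniform_scalar(
    series: AccelSeries,
    target_rate_hz: float = 50.0,
    *,
    min_duration_s: float = 5.0,
    reduction: str = "magnitude",
) -> UniformSeries:
    """Resample and reduce a triaxial session to a mean-removed scalar.

    The default reduction takes the Euclidean magnitude of the resampled
    triaxial signal, which is invariant to how the phone rests on the
    palm, then removes the session mean (which absorbs gravity).
    Single-axis reductions (``"x"``, ``"y"``, ``"z"``) are available for
    sensitivity analyses.

    Sessions spanning less than ``min_duration_s`` after resampling are
    rejected as malformed (truncated recordings carry too few spectral
    averaging segments to be comparable).
    """
    uni = resample_uniform(series, target_rate_hz)
    if uni.duration_s < min_duration_s:
        raise SessionTooShortError(
            f"resampled session lasts {uni.duration_s:.2f} s "
            f"(< {min_duration_s} s minimum)"
        )
    if reduction == "magnitude":
        vals = uni.magnitude()
    elif reduction in ("x", "y", "z"):
        vals = getattr(uni, reduction)
    else:
        raise ValueError(f"unknown reduction {reduction!r}")
    vals = vals - vals.mean()
    return UniformSeries(values=vals, rate_hz=target_rate_hz)
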
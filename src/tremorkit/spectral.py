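"""Welch periodograms and spectral tremor features.

A game session's uniform acceleration series is summarised by its Welch
power spectral density (PSD) and seven scalar features computed inside
the 1–12 Hz analysis band where parkinsonian motor phenomena live:

====================  =====================================================
AUC                   band power (trapezoidal integral of the PSD), per
                      symptom band and over the full analysis band
PV                    peak value: the maximum PSD in the band
F0                    fundamental frequency: frequency of the PSD maximum
F50                   central frequency: splits in-band power in half
SF50                  frequency dispersion: width of the central band
                      holding 68% of the in-band power (16%–84% quantiles)
|F50−F0|              distance between central and fundamental frequency
TIP                   tremor intensity parameter, PV / SF50 — a tall,
                      narrow spectral peak (severe tremor) gives high TIP
====================  =====================================================

F0 further assigns the session to a symptom band: dyskinesia (1–3 Hz),
rest tremor (3–6 Hz), postural tremor (6–9 Hz) or kinetic tremor
(9–12 Hz).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as _signal

from .preprocess import UniformSeries

__all__ = [
    "Periodogram",
    "BandScheme",
    "SpectralFeatures",
    "ZeroPowerError",
    "DEFAULT_BANDS",
    "ANALYSIS_BAND",
    "welch_psd",
    "band_auc",
    "extract_features",
    "categorize",
]

#: Default analysis band (Hz): covers all four symptom bands.
ANALYSIS_BAND = (1.0, 12.0)


class ZeroPowerError(ValueError):
    """No in-band power: spectral features are undefined for the session."""


@dataclass(frozen=True)
class BandScheme:
    """Contiguous labelled frequency intervals used to categorize F0.

    Intervals are half-open ``[lo, hi)`` except the last, which is closed
    so the top of the analysis band is covered.
    """

    bands: tuple[tuple[str, float, float], ...]

    def __post_init__(self) -> None:
        if not self.bands:
            raise ValueError("at least one band required")
        prev_hi = None
        for label, lo, hi in self.bands:
            if not lo < hi:
                raise ValueError(f"band {label!r}: need lo < hi")
            if prev_hi is not None and lo != prev_hi:
                raise ValueError("bands must be contiguous and non-overlapping")
            prev_hi = hi

    @property
    def lo(self) -> float:
        return self.bands[0][1]

    @property
    def hi(self) -> float:
        return self.bands[-1][2]

    def labels(self) -> tuple[str, ...]:
        return tuple(b[0] for b in self.bands)


#: Symptom bands: dyskinesia 1–3 Hz, rest tremor 3–6 Hz,
#: postural tremor 6–9 Hz, kinetic tremor 9–12 Hz.
DEFAULT_BANDS = BandScheme(
    (
        ("dyskinesia", 1.0, 3.0),
        ("rest", 3.0, 6.0),
        ("postural", 6.0, 9.0),
        ("kinetic", 9.0, 12.0),
    )
)


@dataclass
class Periodogram:
    """One-sided PSD estimate on a uniform frequency grid."""

    freqs: np.ndarray
    psd: np.ndarray

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.psd = np.asarray(self.psd, dtype=float)
        if self.freqs.size != self.psd.size or self.freqs.size < 2:
            raise ValueError("freqs and psd must have equal length >= 2")
        df = np.diff(self.freqs)
        if np.any(df <= 0):
            raise ValueError("freqs must be strictly ascending")
        if not np.allclose(df, df[0], rtol=1e-9, atol=1e-12):
            raise ValueError("freqs must be equally spaced")
        if not np.all(np.isfinite(self.psd)):
            raise ValueError("psd contains non-finite values")
        if np.any(self.psd < 0):
            raise ValueError("psd must be nonnegative")

    @property
    def df(self) -> float:
        """Frequency resolution (bin width), Hz."""
        return float(self.freqs[1] - self.freqs[0])


@dataclass
class SpectralFeatures:
    """The per-session feature vector plus the F0 symptom category."""

    auc_dyskinesia: float
    auc_rest: float
    auc_postural: float
    auc_kinetic: float
    auc_band: float
    pv: float
    f0: float
    f50: float
    sf50: float
    f50_f0_abs: float
    tip: float
    category: str

    def as_dict(self) -> dict:
        return {
            "auc_dyskinesia": self.auc_dyskinesia,
            "auc_rest": self.auc_rest,
            "auc_postural": self.auc_postural,
            "auc_kinetic": self.auc_kinetic,
            "auc_band": self.auc_band,
            "pv": self.pv,
            "f0": self.f0,
            "f50": self.f50,
            "sf50": self.sf50,
            "f50_f0_abs": self.f50_f0_abs,
            "tip": self.tip,
            "category": self.category,
        }


def welch_psd(
    sig: UniformSeries,
    segment_s: float = 2.56,
    overlap_frac: float = 0.5,
    window: str = "hann",
) -> Periodogram:
    """Welch PSD of a uniform series (averaged windowed periodograms).

    Defaults use a Hann window with 2.56 s segments (128 samples at
    50 Hz, giving a bin width of ~0.39 Hz) and 50% overlap — a balance
    of frequency resolution against variance for a 10 s record.  Density
    normalisation is used, so the integral of the PSD over frequency
    approximates the signal variance (up to windowing bias).
    """
    if not 0 <= overlap_frac < 1:
        raise ValueError("overlap_frac must be in [0, 1)")
    nperseg = int(round(segment_s * sig.rate_hz))
    if nperseg < 2:
        raise ValueError("segment too short for the sampling rate")
    if nperseg > len(sig):
        raise ValueError(
            f"segment of {nperseg} samples exceeds signal length {len(sig)}"
        )
    noverlap = int(round(nperseg * overlap_frac))
    freqs, psd = _signal.welch(
        sig.values,
        fs=sig.rate_hz,
        window=window,
        nperseg=nperseg,
        noverlap=noverlap,
        detrend="constant",
        scaling="density",
    )
    # tiny negative values can arise from rounding in the FFT
    return Periodogram(freqs=freqs, psd=np.clip(psd, 0.0, None))


def band_auc(p: Periodogram, lo: float, hi: float) -> float:
    """Trapezoidal integral of the PSD over ``[lo, hi]`` (band power).

    Band edges that fall between grid points are handled by linear
    interpolation of the PSD at the edges, so adjacent bands tile
    exactly: the sum of contiguous band AUCs equals the AUC of their
    union.
    """
    eps = 1e-9
    if not lo < hi:
        raise ValueError("need lo < hi")
    if lo < p.freqs[0] - eps or hi > p.freqs[-1] + eps:
        raise ValueError(
            f"band [{lo}, {hi}] outside the PSD grid "
            f"[{p.freqs[0]}, {p.freqs[-1]}]"
        )
    inner = (p.freqs > lo) & (p.freqs < hi)
    xs = np.concatenate(([lo], p.freqs[inner], [hi]))
    ys = np.concatenate(
        (
            [np.interp(lo, p.freqs, p.psd)],
            p.psd[inner],
            [np.interp(hi, p.freqs, p.psd)],
        )
    )
    return float(np.trapezoid(ys, xs))


def categorize(f0: float, scheme: BandScheme = DEFAULT_BANDS) -> str:
    """Label of the scheme interval containing ``f0``.

    Intervals are half-open ``[lo, hi)``; the last interval is closed at
    the top so the full scheme range is covered.
    """
    if not np.isfinite(f0) or f0 < scheme.lo or f0 > scheme.hi:
        raise ValueError(
            f"f0={f0} outside categorization range [{scheme.lo}, {scheme.hi}]"
        )
    for i, (label, lo, hi) in enumerate(scheme.bands):
        last = i == len(scheme.bands) - 1
        if lo <= f0 < hi or (last and f0 <= hi):
            return label
    raise AssertionError("unreachable: contiguous bands cover the range")


def extract_features(
    p: Periodogram,
    band_lo: float = ANALYSIS_BAND[0],
    band_hi: float = ANALYSIS_BAND[1],
    scheme: BandScheme = DEFAULT_BANDS,
) -> SpectralFeatures:
    """Compute the seven spectral features inside the analysis band.

    PV and F0 come from the in-band PSD maximum (ties broken toward the
    lowest frequency).  F50 is the smallest grid frequency at which the
    cumulative in-band power reaches 50% of the in-band total; SF50 is
    the distance between the 16% and 84% cumulative-power frequencies
    (the central 68% of power), floored at one bin width so TIP = PV/SF50
    stays finite when all power concentrates in a single bin.

    Raises
    ------
    ZeroPowerError
        If the in-band power is zero — the session carries no signal and
        should be excluded.
    """
    if not band_lo < band_hi:
        raise ValueError("need band_lo < band_hi")
    eps = 1e-9
    mask = (p.freqs >= band_lo - eps) & (p.freqs <= band_hi + eps)
    if mask.sum() < 2:
        raise ValueError("analysis band covers fewer than 2 grid points")
    f = p.freqs[mask]
    s = p.psd[mask]
    total = float(s.sum())
    if total <= 0.0:
        raise ZeroPowerError("zero power in the analysis band")

    imax = int(np.argmax(s))  # first (lowest-frequency) maximum
    pv = float(s[imax])
    f0 = float(f[imax])

    cum = np.cumsum(s) / total

    def _quantile_freq(q: float) -> float:
        return float(f[int(np.searchsorted(cum, q - 1e-12))])

    f50 = _quantile_freq(0.50)
    f16 = _quantile_freq(0.16)
    f84 = _quantile_freq(0.84)
    sf50 = max(f84 - f16, p.df)
    tip = pv / sf50

    aucs = {label: band_auc(p, lo, hi) for label, lo, hi in scheme.bands}
    labels = scheme.labels()
    return SpectralFeatures(
        auc_dyskinesia=aucs[labels[0]],
        auc_rest=aucs[labels[1]],
        auc_postural=aucs[labels[2]],
        auc_kinetic=aucs[labels[3]],
        auc_band=band_auc(p, band_lo, band_hi),
        pv=pv,
        f0=f0,
        f50=f50,
        sf50=float(sf50),
        f50_f0_abs=abs(f50 - f0),
        tip=float(tip),
        category=categorize(f0, scheme),
    )
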
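"""Independent brute-force reference implementations used only by tests.

Each oracle re-derives a quantity from first principles (explicit loops,
exhaustive enumeration) without touching the implementation under test.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np


def features_cumsum_oracle(freqs, psd, lo=1.0, hi=12.0):
    """PV/F0/F50/SF50/TIP by explicit scan of the in-band cumulative sum."""
    f = [fi for fi in freqs if lo - 1e-9 <= fi <= hi + 1e-9]
    s = [si for fi, si in zip(freqs, psd) if lo - 1e-9 <= fi <= hi + 1e-9]
    total = sum(s)
    assert total > 0
    df = freqs[1] - freqs[0]

    pv, f0 = -1.0, None
    for fi, si in zip(f, s):
        if si > pv:  # strict: keeps the lowest frequency on ties
            pv, f0 = si, fi

    def quantile_freq(q):
        acc = 0.0
        for fi, si in zip(f, s):
            acc += si
            if acc >= q * total - 1e-12:
                return fi
        return f[-1]

    f50 = quantile_freq(0.50)
    sf50 = max(quantile_freq(0.84) - quantile_freq(0.16), df)
    return dict(pv=pv, f0=f0, f50=f50, sf50=sf50, tip=pv / sf50,
                f50_f0_abs=abs(f50 - f0))


def kendall_oracle(x, y):
    """Tau-b by O(n²) pair counting with tie correction."""
    n = len(x)
    conc = disc = tx = ty = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx = x[i] - x[j]
            dy = y[i] - y[j]
            if dx == 0 and dy == 0:
                continue
            if dx == 0:
                tx += 1
            elif dy == 0:
                ty += 1
            elif dx * dy > 0:
                conc += 1
            else:
                disc += 1
    denom = math.sqrt((conc + disc + tx) * (conc + disc + ty))
    return (conc - disc) / denom


def mannwhitney_u(a, b):
    """U statistic of sample a by explicit pair comparison."""
    u = 0.0
    for ai in a:
        for bj in b:
            if ai > bj:
                u += 1.0
            elif ai == bj:
                u += 0.5
    return u


def ranksum_exact_p(a, b):
    """Two-sided exact p by enumerating all assignments of pooled ranks."""
    pooled = list(a) + list(b)
    n = len(a)
    u_obs = mannwhitney_u(a, b)
    mu = len(a) * len(b) / 2.0
    count = total = 0
    for idx in combinations(range(len(pooled)), n):
        aa = [pooled[i] for i in idx]
        bb = [pooled[i] for i in range(len(pooled)) if i not in idx]
        u = mannwhitney_u(aa, bb)
        total += 1
        if abs(u - mu) >= abs(u_obs - mu) - 1e-12:
            count += 1
    return count / total


def med_window_oracle(delta, intakes_per_day):
    """Literal transcription of the labeling windows."""
    if intakes_per_day <= 2:
        if -300 <= delta <= 15:
            return "before"
        if 30 <= delta <= 180:
            return "after"
    else:
        if -60 <= delta <= 15:
            return "before"
        if 30 <= delta <= 90:
            return "after"
    return "excluded"


def random_periodogram(rng, n_bins=20, lo=1.0, hi=12.0):
    """Random nonnegative PSD on a uniform grid covering [lo, hi]."""
    df = (hi - lo) / (n_bins - 1)
    freqs = lo + np.arange(n_bins) * df
    psd = rng.gamma(shape=0.8, scale=1.0, size=n_bins)
    if rng.random() < 0.3:  # occasionally a sparse spectrum with zeros
        psd[rng.random(n_bins) < 0.5] = 0.0
        if psd.sum() == 0.0:
            psd[int(rng.integers(n_bins))] = 1.0
    return freqs, psd
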
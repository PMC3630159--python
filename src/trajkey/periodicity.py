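"""Lomb-Scargle periodicity screening for unevenly sampled expression series.

Each gene's log2 fold-change series (restricted to t <= t_max, default 72 h)
is mean-centered and its floating-mean (generalized) Lomb-Scargle power
evaluated at ``n_freq`` evenly spaced frequencies between f_min = 1/span
and f_max = 1/(2 * mean sampling interval); for the default 0-72 h grid of
10 timepoints the mean interval is 8 h, so the scanned band is [1/72, 1/16]
1/h and the critical 24 h period lies strictly inside it. Refitting the
constant offset per frequency removes the phase-dependent bias that plain
mean-centering suffers on strongly uneven grids. The power z equals the
per-frequency least-squares sinusoid fit's explained variance scaled by
(n-1)/2.

Peak significance combines the exact finite-sample null of the normalized
power at one frequency, Pr(Z > z) = (1 - 2 z/(n-1))^((n-3)/2) (a Beta(1,
(n-3)/2) tail; the familiar exp(-z) is its large-n limit, far too heavy for
n ~ 10 where z is capped at (n-1)/2), with the extreme-value argument over
M effectively independent frequencies: p = 1 - (1 - Pr(Z > z))^M. M
defaults to n - 1, the Horne-Baliunas-style effective count, which null
simulations on the default grid show calibrates the peak p-value to near
uniformity. The screen applies Benjamini-Hochberg FDR control across genes
and flags genes whose dominant period falls in a target band (default
24 +- 1 h).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal, stats

__all__ = [
    "PeriodogramResult",
    "lomb_scargle",
    "peak_significance",
    "periodicity_screen",
]


@dataclass
class PeriodogramResult:
    """Normalized Lomb-Scargle periodogram for one gene."""

    gene_id: str
    frequencies: np.ndarray  # 1/h
    power: np.ndarray  # dimensionless, variance-normalized
    dominant_period: float  # h
    peak_power: float
    n_obs: int  # number of timepoints entering the periodogram
    n_indep: float  # effective number of independent frequencies
    p_value: float = None
    q_value: float = None


def _frequency_grid(t: np.ndarray, n_freq: int):
    span = t.max() - t.min()
    mean_dt = span / (len(np.unique(t)) - 1)
    f_min = 1.0 / span
    f_max = 1.0 / (2.0 * mean_dt)
    return np.linspace(f_min, f_max, n_freq), span, f_min, f_max


def lomb_scargle(
    times,
    values,
    gene_id="",
    n_freq: int = 40,
    t_max: float = 72.0,
    frequencies=None,
) -> PeriodogramResult:
    """Normalized floating-mean Lomb-Scargle periodogram of one series.

    Restricts the series to ``t <= t_max``, mean-centers it and evaluates
    the periodogram at ``n_freq`` evenly spaced frequencies on
    [1/span, 1/(2 mean interval)] (or at explicit ``frequencies``). The
    constant offset is refit per frequency (floating mean). Power is
    normalized by the sample variance (ddof=1): z = (n-1)/2 * R^2 of the
    per-frequency sinusoid fit.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    keep = t <= t_max
    t, y = t[keep], y[keep]
    if len(np.unique(t)) < 4:
        raise ValueError("need at least 4 distinct timepoints")
    y = y - y.mean()
    var = y.var(ddof=1)
    if var == 0:
        raise ValueError("zero variance series")
    if frequencies is None:
        freqs, span, f_min, f_max = _frequency_grid(t, n_freq)
    else:
        freqs = np.asarray(frequencies, dtype=float)
    power = signal.lombscargle(t, y, 2.0 * np.pi * freqs, floating_mean=True) / var
    i_peak = int(np.argmax(power))
    return PeriodogramResult(
        gene_id=gene_id,
        frequencies=freqs,
        power=power,
        dominant_period=1.0 / freqs[i_peak],
        peak_power=float(power[i_peak]),
        n_obs=len(t),
        n_indep=float(len(t) - 1),
    )


def peak_significance(result: PeriodogramResult, n_indep: float = None, method: str = "exact") -> float:
    """Chance probability of the periodogram's peak power.

    p = 1 - (1 - Pr(Z > z))^M with z the peak power and M the effective
    number of independent frequencies (default n_obs - 1, the
    Horne-Baliunas-style count; calibrated on the default grid by null
    simulation). ``method='exact'`` uses the finite-sample null
    Pr(Z > z) = (1 - 2 z/(n-1))^((n-3)/2); ``method='exponential'`` uses
    the large-n limit exp(-z).
    """
    z = result.peak_power
    if z < 0:
        raise ValueError("peak power must be nonnegative")
    m = result.n_indep if n_indep is None else float(n_indep)
    if method == "exact":
        n = result.n_obs
        base = max(1.0 - 2.0 * z / (n - 1), 0.0)
        p_single = base ** ((n - 3) / 2.0)
    elif method == "exponential":
        p_single = float(np.exp(-z))
    else:
        raise ValueError(f"unknown method {method!r}")
    if p_single >= 1.0:
        return 1.0
    p = -np.expm1(m * np.log1p(-p_single))
    return float(np.clip(p, 0.0, 1.0))


def _detrend(t, y, order):
    coef = np.polynomial.polynomial.polyfit(t, y, order)
    return y - np.polynomial.polynomial.polyval(t, coef)


def periodicity_screen(
    fc,
    target_period: float = 24.0,
    band: float = 1.0,
    n_freq: int = 40,
    t_max: float = 72.0,
    n_indep: float = None,
    detrend_order: int = None,
) -> pd.DataFrame:
    """Per-gene periodicity screen with BH FDR control.

    Returns a DataFrame (gene_id, period_h, power, p, q, in_band); ``in_band``
    flags genes whose dominant period lies in
    [target_period - band, target_period + band]. ``detrend_order`` optionally
    removes a polynomial trend (e.g. 5) before the periodogram.
    """
    t = fc.times
    rows = []
    for gi, gene in enumerate(fc.gene_ids):
        y = fc.logfc[gi]
        if detrend_order is not None:
            keep = t <= t_max
            y = y.copy()
            y[keep] = _detrend(t[keep], y[keep], detrend_order)
        res = lomb_scargle(t, y, gene_id=gene, n_freq=n_freq, t_max=t_max)
        p = peak_significance(res, n_indep=n_indep)
        rows.append((gene, res.dominant_period, res.peak_power, p))
    df = pd.DataFrame(rows, columns=["gene_id", "period_h", "power", "p"])
    df["q"] = stats.false_discovery_control(df["p"].to_numpy(), method="bh")
    df["in_band"] = (df["period_h"] >= target_period - band) & (
        df["period_h"] <= target_period + band
    )
    return df
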
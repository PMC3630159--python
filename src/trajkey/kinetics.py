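"""Logistic fits to fold-change kinetics and induction-time estimation.

A gene's log2 fold-change time course is approximated by a four-parameter
logistic f(t) = d + A / (1 + exp(-k (t - t_mid))). The induction (onset)
time is the time of maximal change in acceleration, i.e. the first zero of
the fourth derivative of f. Writing s = sigma(k (t - t_mid)) for the
normalized logistic level, the fourth derivative vanishes (besides at the
midpoint) at the roots of 12 s^2 - 12 s + 1 = 0, s* = 1/2 -+ sqrt(6)/6, so

    t_on  = t_mid - ln((1 - s*)/s*) / k,
    t_max = t_mid + ln((1 - s*)/s*) / k,

symmetric about the midpoint; t_max is taken as the time of maximal fold
expression (saturation point).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

__all__ = [
    "LOGIT_OFFSET",
    "S_STAR",
    "LogisticKinetics",
    "CandidateSet",
    "logistic",
    "fit_logistic",
    "onset_time",
    "max_expression_time",
    "compare_timing",
    "select_candidates",
]

#: smaller root of 12 s^2 - 12 s + 1 = 0 (normalized level at onset)
S_STAR = 0.5 - np.sqrt(6.0) / 6.0
#: ln((1 - s*)/s*); (t_mid - t_on) * k and (t_max - t_mid) * k
LOGIT_OFFSET = float(np.log((1.0 - S_STAR) / S_STAR))


@dataclass
class LogisticKinetics:
    """Fitted logistic parameters and derived timing for one gene."""

    gene_id: str
    amplitude: float  # A, log2 units (negative for down-regulated genes)
    rate: float  # k, 1/h
    t_mid: float  # h
    baseline: float  # d, log2 units
    rss: float
    converged: bool
    informative: bool = True

    @property
    def t_on(self) -> float:
        return onset_time(self)

    @property
    def t_max(self) -> float:
        return max_expression_time(self)

    @property
    def plateau(self) -> float:
        return self.baseline + self.amplitude


@dataclass
class CandidateSet:
    """Candidate key-regulator TFs: top-ranked, peaking inside the window."""

    gene_ids: list
    table: "pd.DataFrame"  # noqa: F821 - columns gene_id, rank, t_on, t_max, peak_logfc


def logistic(t, A, k, t_mid, d=0.0):
    """f(t) = d + A / (1 + exp(-k (t - t_mid))), evaluated elementwise."""
    return d + A / (1.0 + np.exp(-np.clip(k * (np.asarray(t, float) - t_mid), -500, 500)))


def _grid_starts(t: np.ndarray, y: np.ndarray, n_keep: int = 3):
    """Coarse (k, t_mid) grid with analytic (A, d) per cell.

    For fixed (k, t_mid) the model is linear in (A, d); solving that 2x2
    least-squares problem over a log-spaced k grid and a t_mid grid locates
    the global RSS basin cheaply. Returns the ``n_keep`` best distinct
    starting points for the nonlinear polish.
    """
    span = t.max() - t.min()
    ks = np.geomspace(0.05, 4.0, 24)
    tms = np.linspace(t.min() - span * 0.1, t.max() * 0.75, 36)
    kk, mm = np.meshgrid(ks, tms, indexing="ij")
    u = np.clip(kk.ravel()[:, None] * (t[None, :] - mm.ravel()[:, None]), -500, 500)
    s = 1.0 / (1.0 + np.exp(-u))  # (n_cells, n_t)
    n = t.size
    s1 = s.sum(axis=1)
    s2 = (s * s).sum(axis=1)
    sy = s @ y
    y1 = y.sum()
    det = n * s2 - s1**2
    det = np.where(np.abs(det) < 1e-12, np.nan, det)
    A = (n * sy - s1 * y1) / det
    d = (y1 - A * s1) / n
    rss = ((y[None, :] - (d[:, None] + A[:, None] * s)) ** 2).sum(axis=1)
    rss = np.where(np.isfinite(rss), rss, np.inf)
    order = np.argsort(rss)
    starts, seen = [], set()
    for idx in order:
        key = (round(float(kk.ravel()[idx]), 3),)
        if key in seen:
            continue
        seen.add(key)
        starts.append((A[idx], kk.ravel()[idx], mm.ravel()[idx], d[idx]))
        if len(starts) >= n_keep:
            break
    return starts


def fit_logistic(times, logfc, gene_id="", starts=None) -> LogisticKinetics:
    """Least-squares logistic fit, global grid seeding plus LM polish.

    A coarse (k, t_mid) grid with analytic amplitude/baseline locates the
    global residual basin; the best grid cells seed Levenberg-Marquardt
    refinement and the best-RSS solution is kept. A fit with |A| below 3
    times the residual scale, or with a midpoint far outside the grid, is
    flagged non-informative.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(logfc, dtype=float)
    if t.size < 5:
        raise ValueError("need at least 5 timepoints")
    span = t.max() - t.min()
    if starts is None:
        starts = _grid_starts(t, y)

    def resid(p):
        return logistic(t, *p) - y

    best = None
    for p0 in starts:
        try:
            sol = optimize.least_squares(resid, p0, method="lm", max_nfev=400)
        except Exception:
            continue
        if not np.all(np.isfinite(sol.x)):
            continue
        rss = float(np.sum(sol.fun**2))
        if best is None or rss < best[0]:
            best = (rss, sol.x, sol.status > 0)
    if best is None:
        return LogisticKinetics(gene_id, np.nan, np.nan, np.nan, np.nan, np.inf, False, False)
    rss, (A, k, t_mid, d), ok = best
    if k < 0:  # mirror to the canonical k > 0 branch: same curve
        A, k, t_mid, d = -A, -k, t_mid, d + A
    resid_sd = np.sqrt(rss / max(t.size - 4, 1))
    informative = (
        abs(A) > max(3.0 * resid_sd, 1e-3)
        and t.min() - span <= t_mid <= t.max() + span
        and k > 0
    )
    return LogisticKinetics(gene_id, float(A), float(k), float(t_mid), float(d), rss, ok, informative)


def onset_time(fit: LogisticKinetics) -> float:
    """Induction time: first zero of the fitted logistic's 4th derivative."""
    if not fit.rate > 0:
        raise ValueError("onset time requires a positive rate k")
    if fit.amplitude == 0:
        raise ValueError("onset time undefined for zero amplitude")
    return fit.t_mid - LOGIT_OFFSET / fit.rate


def max_expression_time(fit: LogisticKinetics) -> float:
    """Time of maximal fold expression: mirrored 4th-derivative root."""
    if not fit.rate > 0:
        raise ValueError("max-expression time requires a positive rate k")
    if fit.amplitude == 0:
        raise ValueError("max-expression time undefined for zero amplitude")
    return fit.t_mid + LOGIT_OFFSET / fit.rate


def compare_timing(tf_fits, other_fits, alternative="less"):
    """Welch one-sided t-tests comparing TF vs non-TF timing distributions.

    Tests that TF onset times precede the others' (``alternative='less'``)
    and that the onset-to-peak intervals differ in the same direction.
    Returns a dict with p-values and group summaries.
    """
    tf_fits = [f for f in tf_fits if f.converged and f.informative]
    other_fits = [f for f in other_fits if f.converged and f.informative]
    if len(tf_fits) < 3 or len(other_fits) < 3:
        raise ValueError("need at least 3 converged fits per group")
    tf_on = np.array([f.t_on for f in tf_fits])
    ot_on = np.array([f.t_on for f in other_fits])
    tf_span = np.array([f.t_max - f.t_on for f in tf_fits])
    ot_span = np.array([f.t_max - f.t_on for f in other_fits])
    p_on = stats.ttest_ind(tf_on, ot_on, equal_var=False, alternative=alternative).pvalue
    p_span = stats.ttest_ind(tf_span, ot_span, equal_var=False, alternative=alternative).pvalue
    return {
        "p_onset": float(p_on),
        "p_span": float(p_span),
        "tf_onset_mean": float(tf_on.mean()),
        "other_onset_mean": float(ot_on.mean()),
        "tf_span_mean": float(tf_span.mean()),
        "other_span_mean": float(ot_span.mean()),
        "n_tf": len(tf_fits),
        "n_other": len(other_fits),
    }


def select_candidates(
    ranking,
    fits,
    tf_list,
    rank_cutoff: int = 1500,
    window=(12.0, 24.0),
    min_peak_logfc: float = 1.0,
) -> CandidateSet:
    """Select candidate key-regulator TFs.

    A candidate is an annotated TF ranked at or above ``rank_cutoff`` whose
    fitted kinetics are up-regulated, peak (t_max) inside ``window``, and
    plateau (d + A) at or above ``min_peak_logfc`` log2 units.
    """
    import pandas as pd

    tf_list = set(tf_list)
    if not tf_list:
        raise ValueError("empty TF list")
    lo, hi = window
    rank_of = dict(zip(ranking.gene_ids, ranking.rank))
    rows = []
    for f in fits:
        if f.gene_id not in tf_list or not (f.converged and f.informative):
            continue
        rk = rank_of.get(f.gene_id)
        if rk is None or rk > rank_cutoff:
            continue
        if f.amplitude <= 0 or not f.rate > 0:
            continue
        t_max = f.t_max
        if not (lo <= t_max <= hi):
            continue
        if f.plateau < min_peak_logfc:
            continue
        rows.append(
            {
                "gene_id": f.gene_id,
                "rank": rk,
                "t_on": f.t_on,
                "t_max": t_max,
                "peak_logfc": f.plateau,
            }
        )
    rows.sort(key=lambda r: r["rank"])
    table = pd.DataFrame(rows, columns=["gene_id", "rank", "t_on", "t_max", "peak_logfc"])
    return CandidateSet(gene_ids=[r["gene_id"] for r in rows], table=table)
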
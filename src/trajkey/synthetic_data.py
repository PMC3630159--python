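"""Seeded generator for time-course expression datasets with known structure.

The generator emulates the statistical shape of a detachment-induced
transdifferentiation time course: a handful of strongly responding
"phenotype" genes, a moderate tier of "driver" genes that track the global
transcriptome trend with gene-specific onsets, a small group of
transcription-factor drivers whose expression peaks inside the 12-24 h
decision window (their full-scale counterparts peak near 17-19 h), an optional
late-peaking TF that ranks highly but peaks outside the window, optional
24 h oscillators, and a large constant background. Abundances are
log-normal baselines modulated by log2 fold-change profiles with
multiplicative log-normal measurement noise; the 0 h timepoint is duplicated
so downstream noise estimation from t0 replicates sees exactly ``noise_sd``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from trajkey.expression_io import ExpressionDataset
from trajkey.kinetics import LOGIT_OFFSET  # ln((1-s*)/s*) with s* = 1/2 - sqrt(6)/6

__all__ = ["SimulationConfig", "GroundTruth", "simulate", "reference_fixture"]

DEFAULT_TIMES = (0.0, 0.0, 1.0, 2.0, 6.0, 12.0, 18.0, 24.0, 36.0, 48.0, 72.0, 96.0)


@dataclass
class SimulationConfig:
    """Parameters of one simulated time course.

    Counts partition the genes into classes; ``n_tf_driver`` and
    ``n_tf_late`` are subsets of the ``n_driver`` tier. ``noise_sd`` is the
    log2-scale standard deviation of the multiplicative measurement noise
    (also the true t0-replicate noise). ``window`` is the decision window in
    hours that TF drivers peak inside.
    """

    n_genes: int = 2000
    times: tuple = DEFAULT_TIMES
    n_strong: int = 20
    n_driver: int = 150
    n_tf_driver: int = 5
    n_tf_late: int = 1
    n_oscillator: int = 0
    osc_amplitude: float = 1.0
    osc_period: float = 24.0
    window: tuple = (12.0, 24.0)
    noise_sd: float = 0.2
    trend_bulk_mean: float = 0.0
    trend_bulk_sd: float = 0.35
    baseline_log2_mean: float = 1.0
    baseline_log2_sd: float = 1.5
    sample_scale_sd: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        counts = (self.n_strong, self.n_driver, self.n_tf_driver, self.n_tf_late, self.n_oscillator)
        if any(c < 0 for c in counts):
            raise ValueError("class counts must be nonnegative")
        if self.n_strong + self.n_driver + self.n_oscillator > self.n_genes:
            raise ValueError("class counts exceed n_genes")
        if self.n_tf_driver + self.n_tf_late > self.n_driver:
            raise ValueError("TF drivers must be a subset of drivers")
        t = np.asarray(self.times, dtype=float)
        if t.min() != 0 or np.sum(t == 0) < 1:
            raise ValueError("time grid must start at 0")
        lo, hi = self.window
        if not (t.min() <= lo < hi <= t.max()):
            raise ValueError("decision window must lie inside the time grid span")
        grid_res = np.min(np.diff(np.unique(t))) if len(np.unique(t)) > 1 else np.inf
        if hi - lo < grid_res:
            raise ValueError("decision window shorter than the grid resolution")
        if self.noise_sd < 0 or self.baseline_log2_sd < 0 or self.sample_scale_sd < 0:
            raise ValueError("spreads must be nonnegative")


@dataclass
class GroundTruth:
    """Per-gene true class labels and kinetic parameters.

    ``table`` columns: gene_id, label (strong | driver | tf_driver |
    oscillator | background), is_tf, onset_h, peak_h (NaN for non-kinetic
    classes), period_h, phase (oscillators only).
    """

    table: pd.DataFrame
    config: SimulationConfig = field(repr=False, default=None)

    def ids_with_label(self, label: str) -> list:
        return self.table.loc[self.table["label"] == label, "gene_id"].tolist()

    @property
    def tf_ids(self) -> list:
        return self.table.loc[self.table["is_tf"], "gene_id"].tolist()


def _logistic(t, A, k, t_mid, d=0.0):
    return d + A / (1.0 + np.exp(-k * (t - t_mid)))


def simulate(config: SimulationConfig):
    """Generate one (ExpressionDataset, GroundTruth) pair.

    Identical config (including seed) gives a bit-identical dataset.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    t = np.asarray(config.times, dtype=float)
    n = config.n_genes
    gene_ids = [f"G{i:05d}" for i in range(n)]

    labels = np.array(["background"] * n, dtype=object)
    is_tf = np.zeros(n, dtype=bool)
    onset = np.full(n, np.nan)
    peak = np.full(n, np.nan)
    period = np.full(n, np.nan)
    phase = np.full(n, np.nan)
    profiles = np.zeros((n, len(t)))

    order = rng.permutation(n)
    pos = 0
    strong_idx = order[pos : pos + config.n_strong]
    pos += config.n_strong
    driver_idx = order[pos : pos + config.n_driver]
    pos += config.n_driver
    osc_idx = order[pos : pos + config.n_oscillator]
    tf_idx = driver_idx[: config.n_tf_driver]
    late_idx = driver_idx[config.n_tf_driver : config.n_tf_driver + config.n_tf_late]

    # strong responders: high-amplitude, idiosyncratic phenotype genes whose
    # shapes do NOT track the gradual driver trend - immediate-early stress
    # pulses decaying again, or late risers (cell-wall/division-like)
    for g in strong_idx:
        A = rng.uniform(4.0, 6.0) * rng.choice([-1.0, 1.0])
        if rng.random() < 0.5:  # immediate-early pulse
            k = rng.uniform(0.8, 2.0)
            t_mid = rng.uniform(0.5, 4.0)
            t_off = t_mid + rng.uniform(8.0, 30.0)
            profiles[g] = _logistic(t, A, k, t_mid) - _logistic(t, A, k, t_off)
            onset[g] = t_mid - LOGIT_OFFSET / k
            fine = np.linspace(t.min(), t.max(), 2000)
            pf = _logistic(fine, A, k, t_mid) - _logistic(fine, A, k, t_off)
            peak[g] = fine[np.argmax(np.abs(pf))]
        else:  # late riser
            k = rng.uniform(0.15, 0.4)
            t_mid = rng.uniform(40.0, 80.0)
            profiles[g] = _logistic(t, A, k, t_mid)
            onset[g] = t_mid - LOGIT_OFFSET / k
            peak[g] = t_mid + LOGIT_OFFSET / k
        labels[g] = "strong"

    # moderate drivers tracking the global trend with gene-specific onsets
    for g in driver_idx:
        if g in set(tf_idx):
            A = rng.uniform(1.4, 2.0)
            k = rng.uniform(0.3, 0.6)
            t_peak = rng.uniform(16.0, 20.0)  # validated TFs peak ~17-19 h
            t_mid = t_peak - LOGIT_OFFSET / k
            labels[g] = "tf_driver"
            is_tf[g] = True
        elif g in set(late_idx):
            A = rng.uniform(1.5, 2.5)
            k = rng.uniform(0.3, 0.5)
            t_peak = rng.uniform(40.0, 60.0)  # late paralog, outside window
            t_mid = t_peak - LOGIT_OFFSET / k
            labels[g] = "driver"
            is_tf[g] = True
        else:
            A = rng.uniform(1.0, 2.0)
            k = rng.uniform(0.15, 0.5)
            t_mid = rng.uniform(LOGIT_OFFSET / k, 30.0)
            labels[g] = "driver"
        profiles[g] = _logistic(t, A, k, t_mid)
        onset[g] = t_mid - LOGIT_OFFSET / k
        peak[g] = t_mid + LOGIT_OFFSET / k

    # the attractor premise: the bulk transcriptome deviates coherently along
    # the driver trend at small gene-specific amplitude; sign-symmetric by
    # default so the common-mode shift that median (RIS) scaling removes is
    # zero and planted kinetics stay identifiable through normalization
    if config.n_driver > 0 and config.trend_bulk_sd > 0:
        trend = profiles[driver_idx].mean(axis=0)
        bg_mask = labels == "background"
        c = rng.normal(config.trend_bulk_mean, config.trend_bulk_sd, size=int(bg_mask.sum()))
        profiles[bg_mask] = c[:, None] * trend[None, :]

    for g in osc_idx:
        ph = rng.uniform(0, 2 * np.pi)
        profiles[g] = config.osc_amplitude * np.sin(2 * np.pi * t / config.osc_period + ph)
        labels[g] = "oscillator"
        period[g] = config.osc_period
        phase[g] = ph

    baseline_log2 = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, size=n)
    # responding genes are measurable by construction: well-expressed
    # baselines (narrower, elevated), as for array-detectable transcripts
    signal = labels != "background"
    baseline_log2[signal] = rng.normal(
        config.baseline_log2_mean + 1.5, 1.0, size=int(signal.sum())
    )
    baseline = 2.0**baseline_log2
    noise = rng.normal(0.0, config.noise_sd, size=(n, len(t))) if config.noise_sd > 0 else 0.0
    sample_scale = (
        2.0 ** rng.normal(0.0, config.sample_scale_sd, size=len(t))
        if config.sample_scale_sd > 0
        else np.ones(len(t))
    )
    values = baseline[:, None] * 2.0 ** (profiles + noise) * sample_scale[None, :]

    ds = ExpressionDataset(
        gene_ids=gene_ids,
        times=t,
        values=values,
        t0_replicate_mask=t == 0,
    )
    truth = GroundTruth(
        table=pd.DataFrame(
            {
                "gene_id": gene_ids,
                "label": labels,
                "is_tf": is_tf,
                "onset_h": onset,
                "peak_h": peak,
                "period_h": period,
                "phase": phase,
            }
        ),
        config=config,
    )
    bad = truth.table.dropna(subset=["onset_h", "peak_h"])
    assert (bad["onset_h"] < bad["peak_h"]).all()
    return ds, truth


def reference_fixture():
    """The canonical small fixture used by the test suite and docs.

    2,000 genes on the 0-96 h grid with duplicated 0 h, 20 strong genes,
    150 drivers of which 5 are decision-window TF drivers and 1 a
    late-peaking TF, seed 42.
    """
    return simulate(SimulationConfig(seed=42))


def write_ground_truth(truth: GroundTruth, path) -> None:
    truth.table.to_csv(path, sep="\t", index=False)


def config_to_dict(config: SimulationConfig) -> dict:
    d = asdict(config)
    d["times"] = list(d["times"])
    d["window"] = list(d["window"])
    return d
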
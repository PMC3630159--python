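"""Expression matrix I/O, rank-invariant-set normalization, probe filtering
and log2 fold-change computation against a replicated 0 h reference.

The on-disk format is a TSV/CSV table whose first column is ``gene_id`` and
whose remaining column headers encode sampling time in hours as
``T<float>[suffix]``, e.g. ``T0a, T0b, T6, T12``; a trailing non-numeric
suffix distinguishes replicates of the same timepoint.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionDataset",
    "FoldChangeMatrix",
    "read_matrix",
    "write_matrix",
    "ris_normalize",
    "filter_probes",
    "log2_foldchange",
]

_HEADER_RE = re.compile(r"^T?(\d+(?:\.\d+)?)(.*)$")


@dataclass
class ExpressionDataset:
    """A genes x samples abundance matrix on an uneven time grid.

    Attributes
    ----------
    gene_ids : list of str
        Unique gene/probe identifiers, one per row.
    times : ndarray
        Sampling time of each column in hours; nondecreasing, duplicates
        mark replicates.
    values : ndarray
        Nonnegative abundances, shape (n_genes, n_samples).
    t0_replicate_mask : ndarray of bool
        True for columns that are 0 h replicates.
    sample_names : list of str
        Column labels as read from / written to disk.
    """

    gene_ids: list
    times: np.ndarray
    values: np.ndarray
    t0_replicate_mask: np.ndarray
    sample_names: list = field(default_factory=list)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.t0_replicate_mask = np.asarray(self.t0_replicate_mask, dtype=bool)
        n_genes, n_samples = self.values.shape
        if len(self.gene_ids) != n_genes:
            raise ValueError("gene_ids length does not match value matrix rows")
        if self.times.shape != (n_samples,):
            raise ValueError("times length does not match value matrix columns")
        if self.t0_replicate_mask.shape != (n_samples,):
            raise ValueError("t0_replicate_mask length does not match columns")
        if len(set(self.gene_ids)) != n_genes:
            dupes = sorted({g for g in self.gene_ids if self.gene_ids.count(g) > 1})
            raise ValueError(f"duplicate gene IDs: {dupes[:5]}")
        if np.any(np.diff(self.times) < 0):
            raise ValueError("times must be nondecreasing")
        if not self.t0_replicate_mask.any():
            raise ValueError("no sample flagged as 0 h reference")
        if np.any(self.values < 0):
            raise ValueError("negative abundance values")
        if not self.sample_names:
            self.sample_names = _default_sample_names(self.times)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


@dataclass
class FoldChangeMatrix:
    """Per-gene log2 fold changes vs the mean of the 0 h replicates.

    ``times`` is strictly increasing and includes 0; the t=0 column is
    identically zero. ``t0_noise_sd`` is the per-gene measurement noise
    standard deviation (log2 scale) estimated from the 0 h replicates,
    with the global median as a fallback for genes where it is undefined.
    """

    gene_ids: list
    times: np.ndarray
    logfc: np.ndarray
    t0_noise_sd: np.ndarray
    t0_noise_global: float = 0.0

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.logfc = np.asarray(self.logfc, dtype=float)
        self.t0_noise_sd = np.asarray(self.t0_noise_sd, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if 0.0 not in self.times:
            raise ValueError("time grid must include 0")
        if self.logfc.shape != (len(self.gene_ids), len(self.times)):
            raise ValueError("logfc shape mismatch")
        if not np.all(np.isfinite(self.logfc)):
            raise ValueError("non-finite fold changes")

    @property
    def n_genes(self) -> int:
        return self.logfc.shape[0]

    def subset(self, gene_ids) -> "FoldChangeMatrix":
        idx = self.indexer(gene_ids)
        return FoldChangeMatrix(
            gene_ids=list(gene_ids),
            times=self.times.copy(),
            logfc=self.logfc[idx],
            t0_noise_sd=self.t0_noise_sd[idx],
            t0_noise_global=self.t0_noise_global,
        )

    def indexer(self, gene_ids) -> np.ndarray:
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        try:
            return np.array([lookup[g] for g in gene_ids], dtype=int)
        except KeyError as exc:
            raise KeyError(f"unknown gene ID: {exc.args[0]}") from None


def _default_sample_names(times) -> list:
    names = []
    seen = {}
    counts = {}
    for t in times:
        counts[t] = counts.get(t, 0) + 1
    for t in times:
        if counts[t] > 1:
            k = seen.get(t, 0)
            names.append(f"T{t:g}{chr(ord('a') + k)}")
            seen[t] = k + 1
        else:
            names.append(f"T{t:g}")
    return names


def _parse_sample_header(name: str):
    m = _HEADER_RE.match(name.strip())
    if m is None:
        raise ValueError(f"cannot parse time from sample header {name!r}")
    return float(m.group(1))


def read_matrix(path, t0_labels=None) -> ExpressionDataset:
    """Read a TSV/CSV expression matrix.

    Parameters
    ----------
    path : str or Path
        File with a ``gene_id`` first column and one numeric column per
        sample; headers encode time in hours (``T0a, T1, T2.5, ...``).
    t0_labels : set of str, optional
        Sample names to flag as 0 h replicates. By default every column
        whose parsed time is 0 is flagged.
    """
    with open(path) as fh:
        header = fh.readline()
    sep = "\t" if header.count("\t") >= header.count(",") else ","
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    if df.shape[1] < 2:
        raise ValueError("expected a gene-ID column plus at least one sample column")
    gene_col = df.columns[0]
    gene_ids = df[gene_col].astype(str).tolist()
    dupes = df[gene_col][df[gene_col].duplicated()].unique()
    if len(dupes):
        raise ValueError(f"duplicate gene IDs: {list(map(str, dupes[:5]))}")
    sample_names = [str(c) for c in df.columns[1:]]
    times = np.array([_parse_sample_header(c) for c in sample_names])
    vals = df.iloc[:, 1:]
    numeric = vals.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & vals.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"non-numeric cell at gene {gene_ids[r]!r}, sample {sample_names[c]!r}: "
            f"{vals.iat[r, c]!r}"
        )
    if numeric.isna().to_numpy().any():
        r, c = np.argwhere(numeric.isna().to_numpy())[0]
        raise ValueError(f"missing value at gene {gene_ids[r]!r}, sample {sample_names[c]!r}")
    if t0_labels is not None:
        mask = np.array([s in set(t0_labels) for s in sample_names])
    else:
        mask = times == 0
    if not mask.any():
        raise ValueError("no 0 h sample found")
    order = np.argsort(times, kind="stable")
    return ExpressionDataset(
        gene_ids=gene_ids,
        times=times[order],
        values=numeric.to_numpy(dtype=float)[:, order],
        t0_replicate_mask=mask[order],
        sample_names=[sample_names[i] for i in order],
    )


def write_matrix(ds: ExpressionDataset, path) -> None:
    """Write a dataset in the TSV/CSV dialect that :func:`read_matrix` reads."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.DataFrame(ds.values, columns=ds.sample_names)
    df.insert(0, "gene_id", ds.gene_ids)
    df.to_csv(path, sep=sep, index=False)


def ris_normalize(ds: ExpressionDataset, fc_cutoff: float = 1.25):
    """Normalize samples against a rank-invariant set (RIS) of genes.

    The RIS contains genes whose pair-median-centred abundance ratio stays
    below ``fc_cutoff`` (max/min of the pair, symmetric) in *every* pairwise
    sample comparison; centring each pair's ratios by their median removes
    the overall array scale so the criterion measures differential change
    only. Each sample is then rescaled so that the median abundance of its
    RIS genes equals 1.

    Returns
    -------
    (ExpressionDataset, list of str)
        Rescaled dataset and the RIS gene IDs.
    """
    if fc_cutoff <= 1:
        raise ValueError("fc_cutoff must exceed 1")
    if ds.n_samples < 2:
        raise ValueError("need at least 2 samples")
    x = ds.values
    expressed = np.all(x > 0, axis=1)
    invariant = expressed.copy()
    with np.errstate(divide="ignore", invalid="ignore"):
        for i in range(ds.n_samples):
            for j in range(i + 1, ds.n_samples):
                ratio = np.where(expressed, x[:, i] / np.where(x[:, j] > 0, x[:, j], 1.0), np.nan)
                med = np.nanmedian(ratio[expressed]) if expressed.any() else np.nan
                if not np.isfinite(med) or med == 0:
                    invariant[:] = False
                    break
                centred = ratio / med
                sym = np.fmax(centred, 1.0 / centred)
                invariant &= sym < fc_cutoff
    if not invariant.any():
        raise ValueError(
            "rank-invariant set is empty; consider a larger fc_cutoff than "
            f"{fc_cutoff}"
        )
    scale = np.median(x[invariant], axis=0)
    out = ExpressionDataset(
        gene_ids=list(ds.gene_ids),
        times=ds.times.copy(),
        values=x / scale,
        t0_replicate_mask=ds.t0_replicate_mask.copy(),
        sample_names=list(ds.sample_names),
    )
    ris_ids = [g for g, keep in zip(ds.gene_ids, invariant) if keep]
    return out, ris_ids


def filter_probes(
    ds: ExpressionDataset,
    abundance_thresh: float = 1.0,
    frac: float = 0.75,
    iqr_thresh: float = 0.25,
) -> ExpressionDataset:
    """Discard lowly expressed and flat probes.

    A gene is removed when its abundance is below ``abundance_thresh`` in
    strictly more than ``frac`` of the samples, or when its interquartile
    range across samples (linear-interpolation quantiles) is below
    ``iqr_thresh``. Genes sitting exactly at the ``frac`` boundary are kept.
    """
    if abundance_thresh <= 0 or iqr_thresh <= 0:
        raise ValueError("thresholds must be positive")
    low_counts = np.sum(ds.values < abundance_thresh, axis=1)
    low = low_counts > frac * ds.n_samples
    q75, q25 = np.percentile(ds.values, [75, 25], axis=1)
    flat = (q75 - q25) < iqr_thresh
    keep = ~(low | flat)
    if not keep.any():
        raise ValueError("all genes removed by abundance/IQR filter")
    return ExpressionDataset(
        gene_ids=[g for g, k in zip(ds.gene_ids, keep) if k],
        times=ds.times.copy(),
        values=ds.values[keep],
        t0_replicate_mask=ds.t0_replicate_mask.copy(),
        sample_names=list(ds.sample_names),
    )


def log2_foldchange(ds: ExpressionDataset, floor: float = 1e-6) -> FoldChangeMatrix:
    """log2 fold changes against the mean of the 0 h replicates.

    Replicated timepoints (0 h and, for generality, any other) are averaged
    before the ratio; the collapsed t=0 column is identically zero. The
    per-gene 0 h replicate spread yields ``t0_noise_sd`` (standard deviation
    of a single log2 measurement; for two replicates this is
    |log2(rep1/rep2)| / sqrt(2)).
    """
    if floor < 0:
        raise ValueError("floor must be nonnegative")
    t0_vals = ds.values[:, ds.t0_replicate_mask]
    mean_t0 = t0_vals.mean(axis=1)
    if floor == 0 and np.any(mean_t0 == 0):
        raise ValueError("zero mean 0 h abundance with floor=0")
    uniq = np.unique(ds.times)
    if 0.0 not in uniq:
        uniq = np.concatenate([[0.0], uniq])
    cols = np.empty((ds.n_genes, len(uniq)))
    for k, t in enumerate(uniq):
        if t == 0:
            avg = mean_t0
        else:
            avg = ds.values[:, ds.times == t].mean(axis=1)
        cols[:, k] = np.log2((avg + floor) / (mean_t0 + floor))
    cols[:, uniq == 0] = 0.0
    if t0_vals.shape[1] >= 2:
        noise = np.std(np.log2(t0_vals + floor), axis=1, ddof=1)
    else:
        noise = np.zeros(ds.n_genes)
    finite = noise[np.isfinite(noise)]
    global_sd = float(np.median(finite)) if finite.size else 0.0
    noise = np.where(np.isfinite(noise), noise, global_sd)
    return FoldChangeMatrix(
        gene_ids=list(ds.gene_ids),
        times=uniq,
        logfc=cols,
        t0_noise_sd=noise,
        t0_noise_global=global_sd,
    )
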
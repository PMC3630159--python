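"""Correlation-space state trajectories of the transcriptome.

For a gene set, the deviation vector V_i at timepoint t_i holds each gene's
log2 fold change minus that gene's temporal mean. The state of the system
at t_i relative to the initial state t_0 is summarized by two coordinates:

* r_v - a scale-free modified Pearson correlation, the uncentered cosine
  <V_0, V_i> / (||V_0|| ||V_i||) of the (already temporally centred)
  deviation vectors; it is insensitive to differences in expression
  variability while sensitive to profile shape.
* I - the mutual information of the discretized deviations (equal-width
  binning), minus a bias-correction constant C obtained as the minimum raw
  I over random permutations of V_i, which removes the systematic
  discretization offset.

Plotting (r_v(t_i), I(t_i)) for all timepoints traces a trajectory in
correlation space. The whole-transcriptome trajectory is the average over
repeated random gene sets of size p; ranked, non-overlapping gene subsets
of the same size are compared to it by Euclidean distance and Pearson
correlation, quantifying how closely each rank stratum follows the global
transcriptome trend.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DeviationVectors",
    "Trajectory",
    "SubsetDistanceProfile",
    "deviations",
    "r_v",
    "mutual_information",
    "global_trajectory",
    "subset_profiles",
    "n_subsets",
    "trajectory_for_genes",
]


@dataclass
class DeviationVectors:
    """Per-timepoint vectors over genes of deviations from temporal means."""

    times: np.ndarray
    matrix: np.ndarray  # (n_genes, n_times); column i is V_i
    gene_ids: list

    def vector(self, i: int) -> np.ndarray:
        return self.matrix[:, i]


@dataclass
class Trajectory:
    """An ordered (r_v, I) point per timepoint, t_0 self-point included."""

    times: np.ndarray
    r_v: np.ndarray
    mi: np.ndarray  # corrected mutual information, bits
    sd_r: np.ndarray = None
    sd_mi: np.ndarray = None
    p: int = 0
    n_repeats: int = 1

    def as_points(self) -> np.ndarray:
        return np.column_stack([self.r_v, self.mi])


@dataclass
class SubsetDistanceProfile:
    """Distances of equal-size ranked (or randomized) subsets to the global trajectory."""

    size: int
    mean_rank: np.ndarray  # per-subset mean rank position
    distance: np.ndarray  # Euclidean distance in (r_v, I) space
    correlation: np.ndarray  # Pearson r of concatenated (r_v, I) sequences
    ordering: str  # "ranked" | "randomized"
    seed: int = 0
    trajectories: list = field(default_factory=list, repr=False)


def deviations(fc, gene_subset=None) -> DeviationVectors:
    """Deviations of each gene's fold change from its temporal mean."""
    if gene_subset is None:
        genes = list(fc.gene_ids)
        mat = fc.logfc
    else:
        genes = list(gene_subset)
        if not genes:
            raise ValueError("empty gene subset")
        mat = fc.logfc[fc.indexer(genes)]
    dev = mat - mat.mean(axis=1, keepdims=True)
    return DeviationVectors(times=fc.times.copy(), matrix=dev, gene_ids=genes)


def r_v(V0, Vi) -> float:
    """Modified Pearson correlation: uncentered cosine of deviation vectors."""
    V0 = np.asarray(V0, dtype=float)
    Vi = np.asarray(Vi, dtype=float)
    if V0.shape != Vi.shape or V0.size < 2:
        raise ValueError("vectors must have equal length >= 2")
    n0, ni = np.linalg.norm(V0), np.linalg.norm(Vi)
    if n0 == 0 or ni == 0:
        raise ValueError("zero-norm deviation vector")
    return float(np.clip(V0 @ Vi / (n0 * ni), -1.0, 1.0))


def _bin_indices(v: np.ndarray, n_bins: int) -> np.ndarray:
    lo, hi = v.min(), v.max()
    if hi <= lo:
        raise ValueError("degenerate vector: all values in a single bin")
    idx = np.floor((v - lo) / (hi - lo) * n_bins).astype(np.int64)
    return np.minimum(idx, n_bins - 1)


def _mi_from_codes(ix, iy, n_bins: int) -> float:
    joint = np.bincount(ix * n_bins + iy, minlength=n_bins * n_bins).astype(float)
    joint /= joint.sum()
    px = joint.reshape(n_bins, n_bins).sum(axis=1)
    py = joint.reshape(n_bins, n_bins).sum(axis=0)
    outer = np.outer(px, py).ravel()
    nz = joint > 0
    return float(np.sum(joint[nz] * np.log2(joint[nz] / outer[nz])))


def mutual_information(
    V0,
    Vi,
    n_bins: int = 8,
    n_perm: int = 100,
    seed: int = 0,
    return_raw: bool = False,
):
    """Bias-corrected mutual information (bits) of two deviation vectors.

    Raw I from the n_bins x n_bins equal-width joint histogram; the
    correction constant C is the minimum raw I over ``n_perm`` random
    permutations of Vi, subtracted from the raw value. Small negative
    corrected values can occur and are reported as computed.
    """
    V0 = np.asarray(V0, dtype=float)
    Vi = np.asarray(Vi, dtype=float)
    if V0.shape != Vi.shape:
        raise ValueError("vectors must have equal length")
    if V0.size < 20:
        raise ValueError("need at least 20 genes for MI estimation")
    ix = _bin_indices(V0, n_bins)
    iy = _bin_indices(Vi, n_bins)
    raw = _mi_from_codes(ix, iy, n_bins)
    rng = np.random.default_rng(seed)
    # all permutations at once: row-offset trick -> single bincount
    perms = np.argsort(rng.random((n_perm, V0.size)), axis=1)
    codes = ix[None, :] * n_bins + iy[perms]
    nb2 = n_bins * n_bins
    codes += np.arange(n_perm)[:, None] * nb2
    counts = np.bincount(codes.ravel(), minlength=n_perm * nb2).reshape(n_perm, n_bins, n_bins)
    joint = counts / V0.size
    px = joint.sum(axis=2)
    py = joint.sum(axis=1)
    outer = px[:, :, None] * py[:, None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(joint > 0, joint * np.log2(joint / outer), 0.0)
    c = float(terms.sum(axis=(1, 2)).min())
    corrected = raw - c
    if return_raw:
        return corrected, raw, c
    return corrected


def trajectory_for_genes(fc, genes, n_bins=8, n_perm=100, seed=0) -> Trajectory:
    """The (r_v, I) trajectory of one explicit gene set (no sampling)."""
    dev = deviations(fc, genes)
    v0 = dev.matrix[:, fc.times == 0].ravel()
    rs, mis = [], []
    for i, _t in enumerate(fc.times):
        vi = dev.matrix[:, i]
        rs.append(r_v(v0, vi))
        mis.append(mutual_information(v0, vi, n_bins=n_bins, n_perm=n_perm, seed=seed + i))
    return Trajectory(
        times=fc.times.copy(),
        r_v=np.array(rs),
        mi=np.array(mis),
        p=len(genes),
        n_repeats=1,
    )


def global_trajectory(
    fc,
    p: int = 200,
    n_repeats: int = 1000,
    n_bins: int = 8,
    n_perm: int = 100,
    seed: int = 0,
) -> Trajectory:
    """Whole-transcriptome trajectory averaged over random gene sets.

    Each repeat samples ``p`` genes without replacement and computes the
    (r_v, I) point for every timepoint vs t_0; mean and standard deviation
    over repeats are reported. With p equal to the number of genes the
    sampling degenerates to a single repeat with zero spread.
    """
    n = fc.n_genes
    if p < 20:
        raise ValueError("p must be at least 20 for reliable MI")
    if p > n:
        raise ValueError("p exceeds the number of genes")
    rng = np.random.default_rng(seed)
    if p == n:
        traj = trajectory_for_genes(fc, list(fc.gene_ids), n_bins, n_perm, seed)
        traj.sd_r = np.zeros_like(traj.r_v)
        traj.sd_mi = np.zeros_like(traj.mi)
        traj.n_repeats = n_repeats
        return traj
    dev_all = fc.logfc - fc.logfc.mean(axis=1, keepdims=True)
    t0_col = int(np.flatnonzero(fc.times == 0)[0])
    n_t = len(fc.times)
    rs = np.empty((n_repeats, n_t))
    mis = np.empty((n_repeats, n_t))
    for rep in range(n_repeats):
        idx = rng.choice(n, size=p, replace=False)
        sub = dev_all[idx]
        v0 = sub[:, t0_col]
        for i in range(n_t):
            rs[rep, i] = r_v(v0, sub[:, i])
            mis[rep, i] = mutual_information(
                v0, sub[:, i], n_bins=n_bins, n_perm=n_perm, seed=seed + 1000 * rep + i
            )
    return Trajectory(
        times=fc.times.copy(),
        r_v=rs.mean(axis=0),
        mi=mis.mean(axis=0),
        sd_r=rs.std(axis=0, ddof=0),
        sd_mi=mis.std(axis=0, ddof=0),
        p=p,
        n_repeats=n_repeats,
    )


def _traj_distance(a: Trajectory, b: Trajectory) -> float:
    return float(
        np.sqrt(np.sum((a.r_v - b.r_v) ** 2 + (a.mi - b.mi) ** 2))
    )


def _traj_correlation(a: Trajectory, b: Trajectory) -> float:
    x = np.concatenate([a.r_v, a.mi])
    y = np.concatenate([b.r_v, b.mi])
    return float(np.corrcoef(x, y)[0, 1])


def n_subsets(n_genes: int, sizes) -> int:
    """Total count of full non-overlapping subsets over all sizes."""
    total = 0
    for s in sizes:
        if s <= 0:
            raise ValueError("subset sizes must be positive")
        total += n_genes // s
    return total


DEFAULT_SIZES = (100, 150, 200, 300, 400, 500, 1000)


def subset_profiles(
    fc,
    ranking,
    sizes=DEFAULT_SIZES,
    randomize: bool = False,
    n_repeats: int = 1000,
    n_bins: int = 8,
    n_perm: int = 100,
    seed: int = 0,
    global_trajectories: dict = None,
) -> list:
    """Distance profiles of ranked (or randomized) gene subsets.

    Genes are ordered by rank (or by a seeded shuffle when ``randomize``)
    and partitioned into floor(N/p) consecutive subsets per size p, the
    trailing partial subset discarded. Each subset's trajectory is compared
    to the whole-transcriptome trajectory recomputed at the same sampling
    size (reusable via ``global_trajectories``, keyed by p). ``mean_rank``
    is the subset's mean position in the ordering used - the rank itself
    for the ranked ordering - so ranked and randomized profiles share a
    common predictor scale.
    """
    import warnings

    n = fc.n_genes
    order = np.argsort(ranking.rank)
    if randomize:
        rng = np.random.default_rng(seed)
        order = rng.permutation(order)
    # list position 1..N in the ordering used; equals the rank for the
    # ranked ordering and keeps both orderings on a common predictor scale
    positions = np.arange(1, n + 1, dtype=float)
    genes_in_order = [fc.gene_ids[i] for i in order]
    if global_trajectories is None:
        global_trajectories = {}
    profiles = []
    for size_i, p in enumerate(sizes):
        if p > n:
            warnings.warn(f"subset size {p} exceeds gene count {n}; skipped")
            continue
        if p not in global_trajectories:
            global_trajectories[p] = global_trajectory(
                fc, p=p, n_repeats=n_repeats, n_bins=n_bins, n_perm=n_perm, seed=seed + 7919 * p
            )
        glob = global_trajectories[p]
        n_sub = n // p
        mean_rank = np.empty(n_sub)
        dist = np.empty(n_sub)
        corr = np.empty(n_sub)
        trajs = []
        for j in range(n_sub):
            sel = slice(j * p, (j + 1) * p)
            traj = trajectory_for_genes(
                fc, genes_in_order[sel], n_bins=n_bins, n_perm=n_perm,
                seed=seed + 104729 * size_i + 31 * j,
            )
            mean_rank[j] = positions[sel].mean()
            dist[j] = _traj_distance(traj, glob)
            corr[j] = _traj_correlation(traj, glob)
            trajs.append(traj)
        profiles.append(
            SubsetDistanceProfile(
                size=p,
                mean_rank=mean_rank,
                distance=dist,
                correlation=corr,
                ordering="randomized" if randomize else "ranked",
                seed=seed,
                trajectories=trajs,
            )
        )
    return profiles
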
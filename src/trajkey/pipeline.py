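"""End-to-end workflow orchestration with a machine-readable report.

Stages run in dependency order: simulate/load -> RIS normalization ->
abundance/IQR filtering -> log2 fold change -> MDS ranking -> periodicity
screen -> trajectory subset profiles -> nested-ANOVA subset test ->
per-timepoint DE -> logistic kinetics -> candidate TF selection. All
randomness derives from a single master seed via deterministic child
seeds; the same config yields a byte-identical JSON report.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from trajkey import expression_io as eio
from trajkey import kinetics as kin
from trajkey import mds_ranking as mds
from trajkey import periodicity as per
from trajkey import subset_significance as subsig
from trajkey import synthetic_data as synth
from trajkey import timepoint_de as tde
from trajkey import trajectory as traj

__all__ = ["PipelineConfig", "run_all", "REPORT_SCHEMA_VERSION"]

logger = logging.getLogger("trajkey")

REPORT_SCHEMA_VERSION = 1

_KNOWN_KEYS = None  # populated after PipelineConfig definition


@dataclass
class PipelineConfig:
    """All pipeline parameters with their standard defaults.

    ``input_matrix`` (path) and ``simulate`` (SimulationConfig-style dict)
    are mutually exclusive inputs; exactly one must be set. ``tf_list``
    optionally names a one-ID-per-line TF annotation file; when simulating,
    the generator's TF labels are used instead.
    """

    input_matrix: str = None
    tf_list: str = None
    simulate: dict = None
    # normalization / filtering
    ris_fc_cutoff: float = 1.25
    abundance_thresh: float = 1.0
    low_frac: float = 0.75
    iqr_thresh: float = 0.25
    fc_floor: float = 1e-6
    # ranking
    mds_dims: int = 2
    mds_max_iter: int = 2000
    mc_samples: int = 200_000
    # periodicity
    period: float = 24.0
    band: float = 1.0
    n_freq: int = 40
    t_max_periodogram: float = 72.0
    # trajectory
    sizes: tuple = traj.DEFAULT_SIZES
    sampling_p: int = 200
    n_repeats: int = 1000
    n_bins: int = 8
    n_perm: int = 100
    # subset significance
    poly_order: int = 7
    # DE
    alpha: float = 0.05
    # kinetics / candidates
    rank_cutoff: int = 1500
    window: tuple = (12.0, 24.0)
    min_peak_logfc: float = 1.0
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if (self.input_matrix is None) == (self.simulate is None):
            raise ValueError("exactly one of input_matrix / simulate must be set")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if self.rank_cutoff < 1 or self.poly_order < 0:
            raise ValueError("invalid rank_cutoff or poly_order")
        lo, hi = self.window
        if lo >= hi:
            raise ValueError("window must be an increasing pair of hours")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sizes"] = list(d["sizes"])
        d["window"] = list(d["window"])
        return d


_KNOWN_KEYS = {f.name for f in dataclasses.fields(PipelineConfig)}


def _child_seeds(master: int, n: int) -> list:
    ss = np.random.SeedSequence(master)
    return [int(s) % (2**31 - 1) for s in ss.generate_state(n)]


def run_all(config: PipelineConfig, outdir=None) -> dict:
    """Run the full workflow; write stage TSVs and return the JSON report."""
    config.validate()
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "config.yaml", "w") as fh:
            yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
    seeds = _child_seeds(config.seed, 8)
    report = {"schema_version": REPORT_SCHEMA_VERSION, "seed": config.seed, "stages": {}}

    # --- input ------------------------------------------------------------
    truth = None
    if config.simulate is not None:
        sim_kwargs = dict(config.simulate)
        sim_kwargs.setdefault("seed", seeds[0])
        if "times" in sim_kwargs:
            sim_kwargs["times"] = tuple(sim_kwargs["times"])
        if "window" in sim_kwargs:
            sim_kwargs["window"] = tuple(sim_kwargs["window"])
        sim_cfg = synth.SimulationConfig(**sim_kwargs)
        ds, truth = synth.simulate(sim_cfg)
        tf_ids = truth.tf_ids
        if out is not None:
            eio.write_matrix(ds, out / "matrix.tsv")
            synth.write_ground_truth(truth, out / "ground_truth.tsv")
    else:
        ds = eio.read_matrix(config.input_matrix)
        tf_ids = []
        if config.tf_list:
            tf_ids = [l.strip() for l in open(config.tf_list) if l.strip()]
    logger.info("input: %d genes x %d samples", ds.n_genes, ds.n_samples)
    report["stages"]["input"] = {"n_genes": ds.n_genes, "n_samples": ds.n_samples}

    # --- normalize & filter ------------------------------------------------
    ds_norm, ris_ids = eio.ris_normalize(ds, fc_cutoff=config.ris_fc_cutoff)
    ds_filt = eio.filter_probes(
        ds_norm, config.abundance_thresh, config.low_frac, config.iqr_thresh
    )
    logger.info("filter: %d -> %d genes (RIS size %d)", ds.n_genes, ds_filt.n_genes, len(ris_ids))
    report["stages"]["normalize_filter"] = {
        "ris_size": len(ris_ids),
        "n_genes_in": ds.n_genes,
        "n_genes_out": ds_filt.n_genes,
    }
    fc = eio.log2_foldchange(ds_filt, floor=config.fc_floor)

    # --- ranking -----------------------------------------------------------
    emb = mds.hitmds_embed(fc, dims=config.mds_dims, seed=seeds[1], max_iter=config.mds_max_iter)
    fit = mds.fit_skew_normal_2d(emb.coords)
    ranking = mds.rank_genes(emb, fit, mc_samples=config.mc_samples, seed=seeds[2])
    n_sig = int(np.sum(ranking.q_value < 0.05))
    report["stages"]["ranking"] = {
        "stress_correlation": round(float(emb.stress_correlation), 6),
        "n_q_lt_0.05": n_sig,
    }
    if out is not None:
        pd.DataFrame(
            {
                "gene_id": ranking.gene_ids,
                "x": emb.coords[:, 0],
                "y": emb.coords[:, 1],
                "p": ranking.p_value,
                "q": ranking.q_value,
                "rank": ranking.rank,
            }
        ).to_csv(out / "ranking.tsv", sep="\t", index=False)

    # --- periodicity -------------------------------------------------------
    screen = per.periodicity_screen(
        fc,
        target_period=config.period,
        band=config.band,
        n_freq=config.n_freq,
        t_max=config.t_max_periodogram,
    )
    report["stages"]["periodicity"] = {
        "n_in_band": int(screen["in_band"].sum()),
        "n_q_lt_0.05": int((screen["q"] < 0.05).sum()),
        "min_p": round(float(screen["p"].min()), 6),
    }
    if out is not None:
        screen.to_csv(out / "periodicity.tsv", sep="\t", index=False)

    # --- trajectories & subset significance --------------------------------
    glob_cache = {}
    ordered = traj.subset_profiles(
        fc, ranking, sizes=config.sizes, randomize=False,
        n_repeats=config.n_repeats, n_bins=config.n_bins, n_perm=config.n_perm,
        seed=seeds[3], global_trajectories=glob_cache,
    )
    randomized = traj.subset_profiles(
        fc, ranking, sizes=config.sizes, randomize=True,
        n_repeats=config.n_repeats, n_bins=config.n_bins, n_perm=config.n_perm,
        seed=seeds[4], global_trajectories=glob_cache,
    )
    anova = subsig.nested_anova(ordered, randomized, order=config.poly_order)
    _, _, argmin_rank = subsig.distance_rank_curve(ordered, order=config.poly_order)
    report["stages"]["trajectory"] = {
        "n_subsets": traj.n_subsets(fc.n_genes, [p.size for p in ordered]) if ordered else 0,
        "anova_p": float(anova.p_value),
        "anova_f": round(float(anova.f_stat), 4),
        "distance_argmin_rank": round(argmin_rank, 1),
    }
    if out is not None:
        rows = []
        for profs in (ordered, randomized):
            for prof in profs:
                for j in range(len(prof.distance)):
                    rows.append(
                        (prof.size, j, prof.mean_rank[j], prof.distance[j],
                         prof.correlation[j], prof.ordering)
                    )
        pd.DataFrame(
            rows,
            columns=["size", "subset_index", "mean_rank", "distance", "correlation", "ordering"],
        ).to_csv(out / "subset_profiles.tsv", sep="\t", index=False)

    # --- per-timepoint DE ---------------------------------------------------
    de = tde.call_de(fc, alpha_level=config.alpha)
    n_up = int(np.sum(de.direction == "up"))
    n_down = int(np.sum(de.direction == "down"))
    report["stages"]["de"] = {"n_up_calls": n_up, "n_down_calls": n_down}
    if out is not None:
        de.to_frame().to_csv(out / "de_calls.tsv", sep="\t", index=False)

    # --- kinetics & candidates ---------------------------------------------
    rank_of = dict(zip(ranking.gene_ids, ranking.rank))
    fit_genes = [g for g in fc.gene_ids if rank_of[g] <= config.rank_cutoff]
    sub = fc.subset(fit_genes)
    fits = [
        kin.fit_logistic(fc.times, sub.logfc[i], gene_id=g)
        for i, g in enumerate(fit_genes)
    ]
    n_conv = sum(f.converged and f.informative for f in fits)
    candidates = kin.select_candidates(
        ranking,
        fits,
        tf_list=tf_ids if tf_ids else fit_genes,
        rank_cutoff=config.rank_cutoff,
        window=config.window,
        min_peak_logfc=config.min_peak_logfc,
    )
    report["stages"]["kinetics"] = {
        "n_fitted": len(fits),
        "n_converged_informative": int(n_conv),
        "rank_cutoff": config.rank_cutoff,
        "window": list(config.window),
        "candidates": [
            {
                "gene_id": r.gene_id,
                "rank": int(r.rank),
                "t_on": round(float(r.t_on), 3),
                "t_max": round(float(r.t_max), 3),
                "peak_logfc": round(float(r.peak_logfc), 3),
            }
            for r in candidates.table.itertuples()
        ],
    }
    if truth is not None:
        planted = set(truth.ids_with_label("tf_driver"))
        report["stages"]["kinetics"]["planted_tf_drivers"] = sorted(planted)
        report["stages"]["kinetics"]["candidates_match_planted"] = (
            set(candidates.gene_ids) == planted
        )
    if out is not None:
        pd.DataFrame(
            [
                {
                    "gene_id": f.gene_id,
                    "A": f.amplitude,
                    "k": f.rate,
                    "t_mid": f.t_mid,
                    "d": f.baseline,
                    "rss": f.rss,
                    "converged": f.converged,
                    "informative": f.informative,
                }
                for f in fits
            ]
        ).to_csv(out / "kinetics.tsv", sep="\t", index=False)
        candidates.table.to_csv(out / "candidates.tsv", sep="\t", index=False)
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True, default=_json_default)
    return report


def _json_default(o):
    if isinstance(o, (np.integer, np.floating, np.bool_)):
        return o.item()
    raise TypeError(f"not JSON serializable: {type(o)}")
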
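"""Shared fixtures: the canonical simulated dataset and derived stages.

Expensive stages (normalization, MDS ranking) are computed once per session
and shared; tests must not mutate them.
"""

import warnings

import numpy as np
import pytest

import trajkey as tk


@pytest.fixture(scope="session")
def fixture_data():
    """Reference simulated dataset with ground truth (2,000 genes, seed 42)."""
    return tk.reference_fixture()


@pytest.fixture(scope="session")
def filtered(fixture_data):
    ds, truth = fixture_data
    ds_norm, ris = tk.ris_normalize(ds)
    ds_filt = tk.filter_probes(ds_norm)
    return ds_filt, truth, ris


@pytest.fixture(scope="session")
def fold_changes(filtered):
    ds_filt, truth, _ = filtered
    return tk.log2_foldchange(ds_filt), truth


@pytest.fixture(scope="session")
def ranking(fold_changes):
    fc, truth = fold_changes
    emb = tk.hitmds_embed(fc, seed=1)
    fit = tk.fit_skew_normal_2d(emb.coords)
    rk = tk.rank_genes(emb, fit, mc_samples=100_000, seed=2)
    return emb, fit, rk


@pytest.fixture(scope="session")
def subset_profiles_pair(fold_changes, ranking):
    fc, _ = fold_changes
    _, _, rk = ranking
    cache = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ordered = tk.subset_profiles(
            fc, rk, n_repeats=60, seed=3, global_trajectories=cache
        )
        randomized = tk.subset_profiles(
            fc, rk, randomize=True, n_repeats=60, seed=4, global_trajectories=cache
        )
    return ordered, randomized


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
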
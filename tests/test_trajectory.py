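import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import trajkey as tk
from trajkey.expression_io import FoldChangeMatrix
from trajkey.trajectory import (
    deviations,
    global_trajectory,
    mutual_information,
    n_subsets,
    r_v,
    subset_profiles,
    trajectory_for_genes,
)


def _fc(mat):
    mat = np.asarray(mat, dtype=float)
    mat = mat.copy()
    mat[:, 0] = 0.0
    return FoldChangeMatrix(
        gene_ids=[f"g{i}" for i in range(mat.shape[0])],
        times=np.arange(mat.shape[1], dtype=float),
        logfc=mat,
        t0_noise_sd=np.zeros(mat.shape[0]),
    )


class TestDeviations:
    def test_constant_gene_all_zero(self):
        fc = _fc(np.array([[0.0, 0.0, 0.0]]))
        dev = deviations(fc)
        np.testing.assert_array_equal(dev.matrix, 0.0)

    def test_two_point_example(self):
        fc = _fc(np.array([[0.0, 2.0]]))
        dev = deviations(fc)
        np.testing.assert_allclose(dev.matrix[0], [-1.0, 1.0])

    def test_per_gene_temporal_mean_is_zero(self, fold_changes):
        fc, _ = fold_changes
        dev = deviations(fc)
        np.testing.assert_allclose(dev.matrix.mean(axis=1), 0.0, atol=1e-9)

    def test_column_mean_identity(self, rng):
        # mean over genes of deviations = subset-mean profile minus its mean
        fc = _fc(rng.standard_normal((30, 7)))
        dev = deviations(fc)
        prof = np.asarray(fc.logfc).mean(axis=0)
        np.testing.assert_allclose(dev.matrix.mean(axis=0), prof - prof.mean(), atol=1e-12)

    def test_unknown_gene_rejected(self, fold_changes):
        fc, _ = fold_changes
        with pytest.raises(KeyError, match="nope"):
            deviations(fc, ["nope"])


class TestModifiedPearson:
    def test_self_correlation_one(self, rng):
        v = rng.standard_normal(100)
        assert r_v(v, v) == pytest.approx(1.0)

    def test_negated_vector_minus_one(self, rng):
        v = rng.standard_normal(100)
        assert r_v(v, -v) == pytest.approx(-1.0)

    def test_scale_invariance(self, rng):
        v = rng.standard_normal(100)
        assert r_v(v, 3.0 * v) == pytest.approx(1.0)

    def test_zero_norm_rejected(self):
        with pytest.raises(ValueError, match="zero-norm"):
            r_v(np.zeros(10), np.ones(10))

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_symmetric_and_bounded(self, seed):
        g = np.random.default_rng(seed)
        a, b = g.standard_normal(30), g.standard_normal(30)
        assert r_v(a, b) == pytest.approx(r_v(b, a))
        assert -1.0 <= r_v(a, b) <= 1.0


class TestMutualInformation:
    def test_independent_vectors_near_zero(self, rng):
        v0 = rng.standard_normal(10_000)
        vi = rng.permutation(v0)
        mi = mutual_information(v0, vi, seed=1)
        assert -0.01 <= mi <= 0.02

    def test_identity_raw_equals_marginal_entropy(self, rng):
        v = rng.standard_normal(5000)
        _, raw, _ = mutual_information(v, v, seed=1, return_raw=True)
        idx = np.minimum(
            np.floor((v - v.min()) / (v.max() - v.min()) * 8).astype(int), 7
        )
        p = np.bincount(idx, minlength=8) / v.size
        h = -np.sum(p[p > 0] * np.log2(p[p > 0]))
        assert raw == pytest.approx(h, abs=1e-9)

    def test_two_bin_diagonal_table_is_one_bit(self):
        # joint counts [[50, 0], [0, 50]] -> raw I = 1 bit exactly
        v0 = np.concatenate([np.zeros(50), np.ones(50)])
        _, raw, _ = mutual_information(v0, v0.copy(), n_bins=2, seed=0, return_raw=True)
        assert raw == pytest.approx(1.0, abs=1e-12)

    def test_null_concentration_across_seeds(self):
        # corrected MI of independent pairs concentrates near zero
        mis = []
        for seed in range(50):
            g = np.random.default_rng(seed)
            mis.append(
                mutual_information(
                    g.standard_normal(10_000), g.standard_normal(10_000), seed=seed
                )
            )
        assert np.mean(np.abs(mis)) < 0.02

    def test_degenerate_vector_rejected(self):
        with pytest.raises(ValueError, match="single bin|degenerate"):
            mutual_information(np.ones(100), np.arange(100.0))

    def test_short_vectors_rejected(self):
        with pytest.raises(ValueError, match="20"):
            mutual_information(np.arange(10.0), np.arange(10.0))


class TestGlobalTrajectory:
    def test_self_point_r_v_one_and_degenerate_sampling(self, fold_changes):
        fc, _ = fold_changes
        traj = global_trajectory(fc, p=fc.n_genes, n_repeats=10, seed=0)
        i0 = list(traj.times).index(0.0)
        assert traj.r_v[i0] == pytest.approx(1.0)
        np.testing.assert_array_equal(traj.sd_r, 0.0)
        np.testing.assert_array_equal(traj.sd_mi, 0.0)

    def test_small_p_rejected(self, fold_changes):
        fc, _ = fold_changes
        with pytest.raises(ValueError):
            global_trajectory(fc, p=10)

    def test_fixture_shape_decay_then_partial_recovery(self, fold_changes):
        fc, _ = fold_changes
        traj = global_trajectory(fc, p=200, n_repeats=50, seed=3)
        r = traj.r_v
        imin = int(np.argmin(r))
        assert 1 < imin < len(r) - 1  # interior minimum
        assert r[1] > r[imin]  # decays from the 1 h point
        assert r[-1] > r[imin]  # partially recovers at late times


class TestSubsets:
    @pytest.mark.parametrize(
        "n,sizes,expected",
        [
            (17_158, [100, 150, 200, 300, 400, 500, 1000], 520),
            (10, [5], 2),
            (7, [2, 3], 5),
        ],
    )
    def test_n_subsets(self, n, sizes, expected):
        assert n_subsets(n, sizes) == expected

    def test_nonpositive_size_rejected(self):
        with pytest.raises(ValueError):
            n_subsets(10, [0])

    def test_partition_covers_ranked_genes_without_overlap(self, fold_changes, ranking):
        fc, _ = fold_changes
        _, _, rk = ranking
        profs = subset_profiles(fc, rk, sizes=[200], n_repeats=30, seed=0)
        prof = profs[0]
        assert len(prof.distance) == fc.n_genes // 200
        # mean positions of consecutive subsets step by the subset size
        np.testing.assert_allclose(np.diff(prof.mean_rank), 200.0)

    def test_whole_set_subset_close_to_global(self, fold_changes, ranking):
        fc, _ = fold_changes
        _, _, rk = ranking
        profs = subset_profiles(fc, rk, sizes=[fc.n_genes], n_repeats=5, seed=0)
        # single subset == sampling population; only MI permutation seeds differ
        assert profs[0].distance[0] < 0.2

    def test_oversize_subset_skipped_with_warning(self, fold_changes, ranking):
        fc, _ = fold_changes
        _, _, rk = ranking
        with pytest.warns(UserWarning, match="exceeds"):
            profs = subset_profiles(fc, rk, sizes=[fc.n_genes + 1], n_repeats=5, seed=0)
        assert profs == []

    def test_strong_head_is_not_the_closest_stratum(self, subset_profiles_pair):
        # the most differentially regulated genes do not track the global
        # trajectory most closely: the minimum-distance subset lies beyond
        # the head of the ranking
        ordered, _ = subset_profiles_pair
        prof = ordered[0]  # smallest subset size
        assert int(np.argmin(prof.distance)) != 0
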
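import numpy as np
import pytest
import sympy

import trajkey as tk
from trajkey.kinetics import (
    LOGIT_OFFSET,
    LogisticKinetics,
    compare_timing,
    fit_logistic,
    logistic,
    max_expression_time,
    onset_time,
    select_candidates,
)

UNEVEN_GRID = np.array([0.0, 1, 2, 6, 12, 18, 24, 36, 48, 72, 96])


def _numeric_fourth_derivative_root(k, t_mid, after_mid):
    """Independent oracle: symbolic 4th derivative, bracketed root find."""
    t = sympy.symbols("t")
    f = 1 / (1 + sympy.exp(-k * (t - t_mid)))
    f4 = sympy.lambdify(t, sympy.diff(f, t, 4), "numpy")
    from scipy.optimize import brentq

    if after_mid:
        lo, hi = t_mid + 1e-9 / k, t_mid + 8.0 / k
    else:
        lo, hi = t_mid - 8.0 / k, t_mid - 1e-9 / k
    return brentq(f4, lo, hi, xtol=1e-12)


class TestFitLogistic:
    def test_noiseless_parameters_recovered(self):
        y = logistic(UNEVEN_GRID, 4.0, 0.5, 10.0, 0.0)
        f = fit_logistic(UNEVEN_GRID, y)
        assert f.amplitude == pytest.approx(4.0, rel=1e-4)
        assert f.rate == pytest.approx(0.5, rel=1e-4)
        assert f.t_mid == pytest.approx(10.0, rel=1e-4)
        assert f.baseline == pytest.approx(0.0, abs=1e-4)

    def test_constant_series_flagged_non_informative(self):
        f = fit_logistic(UNEVEN_GRID, np.full(11, 1.7))
        assert abs(f.amplitude) < 0.01 or not f.informative

    def test_decreasing_profile_fits_negative_amplitude(self):
        y = logistic(UNEVEN_GRID, -3.0, 0.4, 15.0, 1.0)
        f = fit_logistic(UNEVEN_GRID, y)
        assert f.amplitude == pytest.approx(-3.0, rel=1e-3)
        assert f.rate > 0

    def test_time_shift_equivariance(self):
        y = logistic(UNEVEN_GRID, 2.0, 0.3, 12.0, 0.5)
        f0 = fit_logistic(UNEVEN_GRID, y)
        f1 = fit_logistic(UNEVEN_GRID + 7.0, y)
        assert f1.t_mid == pytest.approx(f0.t_mid + 7.0, abs=1e-5)
        assert f1.t_on == pytest.approx(f0.t_on + 7.0, abs=1e-5)
        assert f1.t_max == pytest.approx(f0.t_max + 7.0, abs=1e-5)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_logistic(np.arange(4.0), np.arange(4.0))


class TestOnsetAndPeakTimes:
    def test_onset_closed_form_example(self):
        fit = LogisticKinetics("", 4.0, 1.0, 10.0, 0.0, 0.0, True)
        assert onset_time(fit) == pytest.approx(10.0 - 2.2924, abs=1e-4)
        assert max_expression_time(fit) == pytest.approx(10.0 + 2.2924, abs=1e-4)

    def test_closed_form_matches_numeric_fourth_derivative_roots(self):
        ks = np.geomspace(0.1, 3.0, 10)
        t_mids = np.linspace(5, 40, 10)
        for k in ks:
            for tm in t_mids:
                fit = LogisticKinetics("", 1.0, k, tm, 0.0, 0.0, True)
                assert onset_time(fit) == pytest.approx(
                    _numeric_fourth_derivative_root(k, tm, after_mid=False), abs=1e-8
                )
                assert max_expression_time(fit) == pytest.approx(
                    _numeric_fourth_derivative_root(k, tm, after_mid=True), abs=1e-8
                )

    def test_step_limit_and_rate_scaling(self):
        f_fast = LogisticKinetics("", 1.0, 1000.0, 10.0, 0.0, 0.0, True)
        assert onset_time(f_fast) == pytest.approx(10.0, abs=0.01)
        f1 = LogisticKinetics("", 1.0, 0.5, 10.0, 0.0, 0.0, True)
        f2 = LogisticKinetics("", 1.0, 1.0, 10.0, 0.0, 0.0, True)
        assert (10.0 - onset_time(f2)) == pytest.approx((10.0 - onset_time(f1)) / 2)

    def test_symmetry_about_midpoint(self):
        fit = LogisticKinetics("", 2.0, 0.7, 23.0, 0.1, 0.0, True)
        assert onset_time(fit) + max_expression_time(fit) == pytest.approx(46.0)

    def test_nonpositive_rate_rejected(self):
        fit = LogisticKinetics("", 1.0, -0.5, 10.0, 0.0, 0.0, True)
        with pytest.raises(ValueError):
            onset_time(fit)


def _fits_from_onsets(onsets, k=0.5, gene_prefix="g"):
    return [
        LogisticKinetics(f"{gene_prefix}{i}", 2.0, k, on + LOGIT_OFFSET / k, 0.0, 0.0, True)
        for i, on in enumerate(onsets)
    ]


class TestCompareTiming:
    def test_identical_groups_p_half(self, rng):
        onsets = rng.normal(10, 1, 25)
        res = compare_timing(_fits_from_onsets(onsets), _fits_from_onsets(onsets + 1e-9))
        assert res["p_onset"] == pytest.approx(0.5, abs=0.05)

    def test_earlier_tf_group_detected(self, rng):
        tf = _fits_from_onsets(rng.normal(7, 1, 25))
        other = _fits_from_onsets(rng.normal(10, 1, 25))
        assert compare_timing(tf, other)["p_onset"] < 1e-3

    def test_swapped_groups_complementary_p(self, rng):
        a = _fits_from_onsets(rng.normal(8, 1, 20))
        b = _fits_from_onsets(rng.normal(9, 1, 20))
        p_ab = compare_timing(a, b)["p_onset"]
        p_ba = compare_timing(b, a)["p_onset"]
        assert p_ab + p_ba == pytest.approx(1.0, abs=1e-9)

    def test_insufficient_fits_rejected(self):
        with pytest.raises(ValueError):
            compare_timing(_fits_from_onsets([1, 2]), _fits_from_onsets([1, 2, 3]))


class TestSelectCandidates:
    def test_empty_window_yields_empty_set(self, ranking, fixture_data):
        _, truth = fixture_data
        _, _, rk = ranking
        fits = _fits_from_onsets([10.0, 11.0], gene_prefix="G0000")
        cs = select_candidates(rk, fits, tf_list=truth.tf_ids, window=(0.0, 0.0))
        assert cs.gene_ids == []

    def test_empty_tf_list_rejected(self, ranking):
        _, _, rk = ranking
        with pytest.raises(ValueError, match="TF"):
            select_candidates(rk, [], tf_list=[])

    def test_fixture_candidates_are_window_tf_drivers_only(
        self, fold_changes, ranking, fixture_data
    ):
        fc, _ = fold_changes
        _, truth = fixture_data
        _, _, rk = ranking
        fits = [
            fit_logistic(fc.times, fc.logfc[i], gene_id=g)
            for i, g in enumerate(fc.gene_ids)
        ]
        cs = select_candidates(rk, fits, tf_list=truth.tf_ids)
        planted = set(truth.ids_with_label("tf_driver"))
        late = set(truth.tf_ids) - planted
        # no non-planted TF sneaks in, and the late paralog is excluded
        assert set(cs.gene_ids) <= planted
        assert not (set(cs.gene_ids) & late)
        # the majority of planted decision-window TFs are recovered
        assert len(set(cs.gene_ids) & planted) >= 3

    def test_late_peaking_top_ranked_tf_excluded(self, fold_changes, ranking, fixture_data):
        fc, _ = fold_changes
        _, truth = fixture_data
        _, _, rk = ranking
        tt = truth.table.set_index("gene_id")
        late = [g for g in truth.tf_ids if tt.loc[g, "label"] == "driver"]
        assert late, "fixture must plant a late TF"
        g = late[0]
        i = fc.gene_ids.index(g)
        f = fit_logistic(fc.times, fc.logfc[i], gene_id=g)
        ranks = dict(zip(rk.gene_ids, rk.rank))
        assert ranks[g] <= 1500  # top ranked
        cs = select_candidates(rk, [f], tf_list=truth.tf_ids)
        assert g not in cs.gene_ids  # peaks after the decision window


class TestFixtureTimingRecovery:
    def test_driver_midpoint_recovery(self, fold_changes, fixture_data):
        fc, _ = fold_changes
        _, truth = fixture_data
        tt = truth.table.set_index("gene_id")
        errs = []
        for i, g in enumerate(fc.gene_ids):
            if tt.loc[g, "label"] not in ("driver", "tf_driver"):
                continue
            f = fit_logistic(fc.times, fc.logfc[i], gene_id=g)
            if not (f.converged and f.informative):
                continue
            true_mid = (tt.loc[g, "onset_h"] + tt.loc[g, "peak_h"]) / 2.0
            errs.append(abs(f.t_mid - true_mid))
        # midpoints are recovered to a few hours at the fixture's noise;
        # the information limit at amplitude ~1-2 and sd ~0.25 is ~1.5-2.5 h
        assert np.median(errs) < 3.0
        assert len(errs) > 100
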
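"""Balance-variable extraction, curve errors, and between-group statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gaitbalance import clinstat
from gaitbalance.balance import BalanceCurves, GaitEvents
from gaitbalance.clinstat import (VARIABLE_INFO, GroupComparison,
                                  VariableTable, agreement,
                                  agreement_from_counts, cohens_d,
                                  compare_models, extract_variables,
                                  group_comparison, independent_t,
                                  rmse_curves, rrmse_curves)

EVENTS = GaitEvents(hs=0, cto=12, chs=50, to=62, next_hs=100, rate_hz=100.0)


def _curves(sag_ia=None, fro_ia=None, sag_rc=None, fro_rc=None):
    z = np.zeros(101)
    return BalanceCurves(
        z if sag_ia is None else sag_ia, z if fro_ia is None else fro_ia,
        z.copy() if sag_rc is None else sag_rc,
        z.copy() if fro_rc is None else fro_rc)


class TestExtractVariables:
    def test_metadata_has_48_variables(self):
        assert len(VARIABLE_INFO) == 48
        assert (VARIABLE_INFO.kind == "event").sum() == 16
        assert (VARIABLE_INFO.kind == "mean").sum() == 16
        assert (VARIABLE_INFO.kind == "range").sum() == 16
        # numbering blocks: 10 is sagittal RCIA at CTO, 20 sagittal IA SW mean,
        # 46 frontal RCIA SLS range
        assert VARIABLE_INFO.loc[10].tolist() == ["sagittal", "RCIA", "event",
                                                  "CTO", "deg/s"]
        assert VARIABLE_INFO.loc[20].tolist() == ["sagittal", "IA", "mean",
                                                  "SW", "deg"]
        assert VARIABLE_INFO.loc[46].tolist() == ["frontal", "RCIA", "range",
                                                  "SLS", "deg/s"]

    def test_constant_curve(self):
        c = 4.2
        vals = extract_variables(_curves(sag_ia=np.full(101, c)), EVENTS)
        sag_ia = VARIABLE_INFO[(VARIABLE_INFO.plane == "sagittal")
                               & (VARIABLE_INFO.quantity == "IA")]
        for num, row in sag_ia.iterrows():
            expected = 0.0 if row.kind == "range" else c
            assert vals[num - 1] == pytest.approx(expected)

    def test_sine_value_at_cto(self):
        pct = np.arange(101.0)
        sine = np.sin(2 * np.pi * pct / 100.0)
        vals = extract_variables(_curves(sag_ia=sine), EVENTS)
        # variable 2: sagittal IA at CTO (12% -> sin(0.24 pi))
        assert vals[1] == pytest.approx(np.sin(0.24 * np.pi), abs=1e-12)
        assert vals[1] == pytest.approx(0.6845, abs=1e-4)

    def test_window_mean_and_range_of_ramp(self):
        ramp = np.arange(101.0) / 2.0
        vals = extract_variables(_curves(fro_ia=ramp), EVENTS)
        # variable 22: frontal IA mean over the SLS window [12, 50]
        assert vals[21] == pytest.approx(np.mean(ramp[12:51]))
        # variable 38: frontal IA range over SLS
        assert vals[37] == pytest.approx((50.0 - 12.0) / 2.0)

    def test_bad_event_percents_rejected(self):
        ev = GaitEvents(hs=0, cto=12, chs=50, to=62, next_hs=100,
                        rate_hz=100.0)
        object.__setattr__(ev, "cto", 0)  # force CTO onto HS
        with pytest.raises(ValueError):
            extract_variables(_curves(), ev)


class TestCurveErrors:
    def test_identical_curves(self, rng):
        y = rng.standard_normal((2, 101))
        assert np.allclose(rmse_curves(y, y), 0.0)
        assert np.allclose(rrmse_curves(y, y), 0.0)

    def test_hand_example(self):
        truth = np.array([[0.0, 1.0, 2.0]])
        pred = np.array([[1.0, 1.0, 1.0]])
        assert rmse_curves(pred, truth)[0] == pytest.approx(np.sqrt(2 / 3))
        assert rrmse_curves(pred, truth)[0] == pytest.approx(
            100 * np.sqrt(2 / 3) / 2, abs=1e-9)

    def test_scale_equivariance(self, rng):
        truth = rng.standard_normal((2, 101))
        pred = truth + rng.standard_normal((2, 101)) * 0.3
        assert np.allclose(rmse_curves(2 * pred, 2 * truth),
                           2 * rmse_curves(pred, truth))
        assert np.allclose(rrmse_curves(2 * pred, 2 * truth),
                           rrmse_curves(pred, truth))

    def test_flat_truth_flagged(self):
        with pytest.raises(ValueError, match="flat"):
            rrmse_curves(np.ones((2, 101)), np.ones((2, 101)))


class TestCohensD:
    def test_zero_for_equal_means(self):
        assert cohens_d(1.0, 2.0, 13, 1.0, 3.0, 13) == 0.0

    def test_symmetric_in_group_order(self):
        a = cohens_d(-37.93, 26.53, 13, 0.24, 21.58, 13)
        b = cohens_d(0.24, 21.58, 13, -37.93, 26.53, 13)
        assert a == b

    def test_affine_invariance(self):
        a = cohens_d(10.0, 2.0, 13, 12.0, 3.0, 13)
        b = cohens_d(10.0 * 5 + 7, 2.0 * 5, 13, 12.0 * 5 + 7, 3.0 * 5, 13)
        assert a == pytest.approx(b)

    def test_unequal_group_sizes_use_pooled_sd(self):
        d = cohens_d(0.0, 1.0, 10, 1.0, 2.0, 30)
        pooled = np.sqrt((9 * 1 + 29 * 4) / 38)
        assert d == pytest.approx(1.0 / pooled)

    def test_nonpositive_sd_rejected(self):
        with pytest.raises(ValueError):
            cohens_d(0.0, 0.0, 13, 1.0, 1.0, 13)


class TestIndependentT:
    def test_identical_groups(self, rng):
        x = rng.standard_normal(13)
        t, p = independent_t(x, x.copy())
        assert t == 0.0
        assert p == 1.0

    def test_summary_and_raw_paths_agree(self, rng):
        a = rng.standard_normal(13) * 2 + 1
        b = rng.standard_normal(13) * 3
        t1, p1 = independent_t(a, b)
        t2, p2 = independent_t((a.mean(), a.std(ddof=1), 13),
                               (b.mean(), b.std(ddof=1), 13))
        assert t1 == pytest.approx(t2, abs=1e-12)
        assert p1 == pytest.approx(p2, abs=1e-12)

    def test_matches_scipy_pooled_ttest(self, rng):
        for _ in range(5):
            a = rng.standard_normal(9) * 2
            b = rng.standard_normal(14) + 0.5
            t, p = independent_t(a, b)
            ref = stats.ttest_ind(a, b, equal_var=True)
            assert t == pytest.approx(ref.statistic, abs=1e-10)
            assert p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_degenerate_variance_convention(self):
        t, p = independent_t(np.ones(5), np.ones(5))
        assert (t, p) == (0.0, 1.0)


def _comparison(sig_vars, d_values=None, n_vars=48):
    sig = pd.Series(False, index=range(1, n_vars + 1))
    sig[list(sig_vars)] = True
    d = pd.Series(0.5, index=range(1, n_vars + 1))
    if d_values is not None:
        for k, v in d_values.items():
            d[k] = v
    table = pd.DataFrame({"significant": sig, "d": d})
    table.index.name = "number"
    return GroupComparison(table=table)


class TestAgreement:
    def test_published_confusion_arithmetic(self):
        """Sensitivity/specificity/accuracy reproduce the printed values for
        the reported false-negative/false-positive counts."""
        assert agreement_from_counts(2, 3, 0, 45) == pytest.approx(
            (100 / 3, 100.0, 95.833333), abs=5e-3)
        assert agreement_from_counts(3, 3, 4, 45) == pytest.approx(
            (0.0, 91.111111, 85.416667), abs=5e-3)

    def test_truth_vs_itself_is_perfect(self):
        truth = _comparison({10, 14, 20}, {10: 1.58, 14: 1.39, 20: 0.93})
        rep = agreement(truth, truth)
        assert rep.false_negatives == [] and rep.false_positives == []
        assert rep.sensitivity_pct == 100.0
        assert rep.specificity_pct == 100.0
        assert rep.accuracy_pct == 100.0
        assert rep.pearson_r_effect_sizes == pytest.approx(1.0)

    def test_fn_fp_classification(self):
        truth = _comparison({10, 14, 20})
        model = _comparison({10, 4, 35})
        rep = agreement(model, truth)
        assert rep.false_negatives == [14, 20]
        assert rep.false_positives == [4, 35]
        assert rep.sensitivity_pct == pytest.approx(100 / 3)
        assert rep.specificity_pct == pytest.approx(100 * 43 / 45)

    def test_variable_set_mismatch_rejected(self):
        with pytest.raises(ValueError, match="differ"):
            agreement(_comparison({1}, n_vars=48), _comparison({1}, n_vars=47))


class TestCompareModels:
    def test_identical_vectors(self, rng):
        x = rng.standard_normal(13)
        assert compare_models(x, x.copy()) == (0.0, 1.0)

    def test_constant_shift_flagged_degenerate(self):
        x = np.ones(13)
        t, p = compare_models(x + 0.5, x)
        assert np.isinf(t) and t > 0
        assert p == 0.0

    def test_matches_one_sample_oracle(self, rng):
        a = rng.standard_normal(13)
        b = rng.standard_normal(13)
        t, p = compare_models(a, b)
        ref = stats.ttest_1samp(a - b, 0.0)
        assert t == pytest.approx(ref.statistic, abs=1e-10)
        assert p == pytest.approx(ref.pvalue, abs=1e-10)


class TestGroupComparison:
    def test_recovers_known_shift(self, rng):
        vals = pd.DataFrame(rng.standard_normal((26, 48)),
                            index=[f"s{i}" for i in range(26)],
                            columns=range(1, 49))
        groups = pd.Series(["old"] * 13 + ["young"] * 13, index=vals.index)
        vals.loc[groups == "old", 7] += 3.0
        cmp_ = group_comparison(VariableTable(values=vals, groups=groups))
        assert bool(cmp_.significant[7])
        assert cmp_.table.loc[7, "d"] > 1.5

    def test_bonferroni_flag_tightens_threshold(self, rng):
        vals = pd.DataFrame(rng.standard_normal((26, 48)),
                            index=[f"s{i}" for i in range(26)],
                            columns=range(1, 49))
        groups = pd.Series(["old"] * 13 + ["young"] * 13, index=vals.index)
        vals.loc[groups == "old", 7] += 1.0  # moderate effect
        plain = group_comparison(VariableTable(values=vals, groups=groups))
        corr = group_comparison(VariableTable(values=vals, groups=groups),
                                correction="bonferroni")
        assert corr.significant.sum() <= plain.significant.sum()
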
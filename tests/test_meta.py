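"""Random-effects meta-analysis: pooling, heterogeneity, bias tests."""

import numpy as np
import pytest
from scipy import stats

from predimr.meta import (
    MetaError,
    StudyRecord,
    begg_bias_test,
    dl_pool,
    egger_bias_test,
    funnel_table,
    leave_one_study_out,
    pool_studies,
    read_study_table,
    subgroup_pool,
    to_log_effect,
    write_study_table,
)
from predimr.simulate import MetaSimConfig, gen_meta_studies


def study(sid, est, lo, hi, measure="RR", **kw):
    return StudyRecord(sid, measure, est, lo, hi, **kw)


class TestLogTransform:
    def test_rr_ci_back_conversion(self):
        # RR 1.16 (1.09, 1.23): y = ln 1.16, se = (ln1.23 - ln1.09)/(2*1.959964)
        y, v = to_log_effect(study("s", 1.16, 1.09, 1.23))
        assert y == pytest.approx(np.log(1.16), rel=1e-12)
        assert np.sqrt(v) == pytest.approx(
            (np.log(1.23) - np.log(1.09)) / (2 * 1.959964), rel=1e-12
        )
        assert y == pytest.approx(0.14842, abs=5e-6)
        assert np.sqrt(v) == pytest.approx(0.03083, abs=1e-5)

    def test_degenerate_ci_rejected(self):
        with pytest.raises(MetaError, match="bracket"):
            study("s", 1.0, 1.0, 1.0)

    def test_or_to_rr_conversion(self):
        rec = study("s", 2.0, 1.5, 2.7, measure="OR", baseline_risk=0.1)
        y, _ = to_log_effect(rec, convert_or_to_rr=True)
        assert np.exp(y) == pytest.approx(2.0 / (0.9 + 0.2), rel=1e-12)

    def test_conversion_off_by_default(self):
        rec = study("s", 2.0, 1.5, 2.7, measure="OR", baseline_risk=0.1)
        y, _ = to_log_effect(rec)
        assert np.exp(y) == pytest.approx(2.0, rel=1e-12)

    def test_hr_treated_as_rr(self):
        y_hr, v_hr = to_log_effect(study("s", 1.3, 1.1, 1.55, measure="HR"))
        y_rr, v_rr = to_log_effect(study("s", 1.3, 1.1, 1.55, measure="RR"))
        assert (y_hr, v_hr) == (y_rr, v_rr)


class TestDlPool:
    def test_hand_worked_example(self):
        # y=(0,2), v=(1,1): mu_F=1, Q=2, tau2=(2-1)/(2-2/2)=1, I2=50%,
        # random weights 1/2 each -> mu=1, se=1
        res = dl_pool([(0.0, 1.0), (2.0, 1.0)])
        assert res.pooled_log == pytest.approx(1.0)
        assert res.Q == pytest.approx(2.0)
        assert res.tau2 == pytest.approx(1.0)
        assert res.i2_percent == pytest.approx(50.0)
        assert res.se == pytest.approx(1.0)

    def test_identical_studies_degenerate(self):
        res = dl_pool([(0.3, 0.04)] * 5)
        assert res.pooled_log == pytest.approx(0.3)
        assert res.Q == pytest.approx(0.0)
        assert res.tau2 == 0.0
        assert res.i2_percent == 0.0

    def test_single_study_returned_as_is(self):
        res = dl_pool([(0.5, 0.09)])
        assert res.k == 1
        assert res.pooled_log == pytest.approx(0.5)
        assert res.se == pytest.approx(0.3)
        assert res.Q is None and res.p_Q is None

    def test_zero_studies_rejected(self):
        with pytest.raises(MetaError):
            dl_pool([])

    def test_matches_statsmodels_oracle(self):
        """Independent cross-check against statsmodels' DL implementation."""
        from statsmodels.stats.meta_analysis import combine_effects

        rng = np.random.default_rng(60)
        y = rng.normal(0.2, 0.3, 20)
        v = rng.uniform(0.01, 0.2, 20)
        ours = dl_pool(list(zip(y, v)))
        sm_res = combine_effects(y, v, method_re="dl")
        assert ours.tau2 == pytest.approx(float(sm_res.tau2), rel=1e-10)
        frame = sm_res.summary_frame()
        assert ours.pooled_log == pytest.approx(
            float(frame.loc["random effect", "eff"]), rel=1e-10
        )
        assert ours.se == pytest.approx(
            float(frame.loc["random effect", "sd_eff"]), rel=1e-10
        )

    def test_homogeneous_reduces_to_fixed_effect(self):
        # when Q <= df, tau2 = 0 and DL equals inverse-variance fixed pooling
        y = np.array([0.10, 0.11, 0.09])
        v = np.array([0.5, 0.5, 0.5])
        res = dl_pool(list(zip(y, v)))
        w = 1 / v
        assert res.tau2 == 0.0
        assert res.pooled_log == pytest.approx(float(np.sum(w * y) / np.sum(w)), rel=1e-12)

    def test_pooled_within_study_range(self):
        rng = np.random.default_rng(61)
        for _ in range(10):
            y = rng.normal(0, 1, 8)
            v = rng.uniform(0.01, 1, 8)
            res = dl_pool(list(zip(y, v)))
            assert y.min() - 1e-12 <= res.pooled_log <= y.max() + 1e-12

    def test_location_equivariance(self):
        rng = np.random.default_rng(62)
        y = rng.normal(0, 0.5, 12)
        v = rng.uniform(0.02, 0.3, 12)
        a = dl_pool(list(zip(y, v)))
        b = dl_pool(list(zip(y + 0.7, v)))
        assert b.pooled_log == pytest.approx(a.pooled_log + 0.7, rel=1e-10)
        assert b.Q == pytest.approx(a.Q, rel=1e-10)
        assert b.tau2 == pytest.approx(a.tau2, rel=1e-10)
        assert b.i2_percent == pytest.approx(a.i2_percent, rel=1e-10)


class TestSubgroupsAndLoo:
    def test_disjoint_single_study_groups(self):
        recs = [
            study("a", 1.2, 1.0, 1.44, labels={"sex": "F"}),
            study("b", 1.5, 1.2, 1.875, labels={"sex": "M"}),
        ]
        res = subgroup_pool(recs, "sex")
        assert set(res) == {"F", "M", "(overall)"}
        assert res["F"].pooled_ratio == pytest.approx(1.2, rel=1e-10)
        assert res["M"].k == 1

    def test_unknown_label_key_rejected(self):
        recs = [study("a", 1.2, 1.0, 1.44, labels={"sex": "F"})]
        with pytest.raises(MetaError, match="no label"):
            subgroup_pool(recs, "ethnicity")

    def test_subgroup_ordering_matches_generated_shift(self):
        lo, _ = gen_meta_studies(
            MetaSimConfig(k_studies=30, mu_true=0.05, tau=0.02, seed=41)
        )
        hi, _ = gen_meta_studies(
            MetaSimConfig(k_studies=30, mu_true=0.40, tau=0.02, seed=42)
        )
        recs = [
            StudyRecord(f"lo_{r.study_id}", r.effect_measure, r.estimate, r.ci_low,
                        r.ci_high, r.outcome, {"definition": "A"})
            for r in lo
        ] + [
            StudyRecord(f"hi_{r.study_id}", r.effect_measure, r.estimate, r.ci_low,
                        r.ci_high, r.outcome, {"definition": "B"})
            for r in hi
        ]
        res = subgroup_pool(recs, "definition")
        assert res["A"].pooled_log < res["B"].pooled_log

    def test_loo_counts_and_k2_reduction(self):
        recs = [study(f"s{i}", 1.2, 1.0, 1.44) for i in range(5)]
        assert len(leave_one_study_out(recs)) == 6
        two = [study("a", 1.2, 1.0, 1.44), study("b", 1.5, 1.2, 1.875)]
        rows = leave_one_study_out(two)
        omit_a = dict(rows)["a"]
        assert omit_a.pooled_ratio == pytest.approx(1.5, rel=1e-10)

    def test_loo_homogeneous_cis_overlap_full(self):
        recs, _ = gen_meta_studies(MetaSimConfig(k_studies=15, tau=0.0, seed=44))
        rows = leave_one_study_out(recs)
        full = rows[0][1]
        for _, res in rows[1:]:
            assert max(full.ci_low, res.ci_low) < min(full.ci_high, res.ci_high)


class TestBiasTests:
    def test_egger_symmetric_fixture_zero_intercept(self):
        # y mirrored about mu with matched se pairs -> exact symmetry
        mu = 0.2
        recs = []
        for i, (d, se) in enumerate([(0.1, 0.05), (0.2, 0.1), (0.3, 0.2)]):
            for sgn in (1, -1):
                y = mu + sgn * d
                recs.append(
                    study(f"s{i}{sgn}", np.exp(y), np.exp(y - 1.959964 * se),
                          np.exp(y + 1.959964 * se))
                )
        b0, _, _ = egger_bias_test(recs)
        assert b0 == pytest.approx(0.0, abs=1e-10)

    def test_egger_minimal_k3_runs(self):
        recs = [study("a", 1.1, 1.0, 1.21), study("b", 1.3, 1.1, 1.54),
                study("c", 1.6, 1.2, 2.14)]
        b0, se, p = egger_bias_test(recs)
        assert se > 0 and 0 <= p <= 1

    def test_egger_requires_three(self):
        with pytest.raises(MetaError):
            egger_bias_test([study("a", 1.1, 1.0, 1.21), study("b", 1.3, 1.1, 1.54)])

    def test_begg_perfect_concordance(self):
        # construct three studies whose deviates and variances rank together
        recs = [
            study("a", 1.05, 1.005, 1.097),
            study("b", 1.3, 1.05, 1.61),
            study("c", 1.9, 1.1, 3.28),
        ]
        tau, _ = begg_bias_test(recs)
        assert tau == pytest.approx(1.0)

    def test_begg_matches_scipy_pair_counting(self):
        rng = np.random.default_rng(55)
        recs = []
        for i in range(12):
            y = rng.normal(0.1, 0.3)
            se = rng.uniform(0.05, 0.4)
            recs.append(
                study(f"s{i}", np.exp(y), np.exp(y - 1.959964 * se),
                      np.exp(y + 1.959964 * se))
            )
        tau, p = begg_bias_test(recs)
        # recompute deviates exactly as the test defines them
        eff = [to_log_effect(r) for r in recs]
        y = np.array([e[0] for e in eff])
        v = np.array([e[1] for e in eff])
        w = 1 / v
        u = (y - np.sum(w * y) / np.sum(w)) / np.sqrt(v - 1 / np.sum(w))
        tau_sp, p_sp = stats.kendalltau(u, v, method="asymptotic")
        assert tau == pytest.approx(float(tau_sp), rel=1e-10)
        assert p == pytest.approx(float(p_sp), rel=1e-6)

    def test_begg_all_tied_variances(self):
        # shared CI bounds -> identical se for every study: all v tied
        recs = [study(f"s{i}", est, 1.0, 2.0) for i, est in
                enumerate([1.3, 1.4, 1.5])]
        tau, p = begg_bias_test(recs)
        assert tau == 0.0
        assert p == 1.0


class TestFunnelAndIo:
    def test_funnel_rows_sorted_by_se(self):
        recs = [study("a", 1.2, 1.0, 1.44), study("b", 1.2, 1.1, 1.31),
                study("c", 1.2, 0.8, 1.8)]
        res = pool_studies(recs)
        tab = funnel_table(recs, res)
        assert len(tab) == 3
        assert list(tab["se"]) == sorted(tab["se"])
        assert (tab["pooled"] == res.pooled_log).all()

    def test_study_table_round_trip(self, tmp_path):
        recs, _ = gen_meta_studies(
            MetaSimConfig(k_studies=8, seed=3,
                          label_scheme={"definition": ["IFG", "IGT"], "sex": ["F", "M"]})
        )
        path = write_study_table(recs, tmp_path / "studies.tsv")
        back = read_study_table(path)
        assert len(back) == len(recs)
        for a, b in zip(recs, back):
            assert a.study_id == b.study_id
            assert a.estimate == pytest.approx(b.estimate, rel=1e-12)
            assert a.labels == b.labels

    def test_missing_columns_rejected(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("study_id\testimate\ns1\t1.2\n")
        with pytest.raises(MetaError, match="missing columns"):
            read_study_table(p)
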
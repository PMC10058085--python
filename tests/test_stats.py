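"""Diagnostic statistics: 2x2 metrics, ROC/DeLong, McNemar, agreement."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ctpffr.stats import (ConfusionTable, VesselRecord,
                          bland_altman, chi_square_accuracy, classify,
                          clopper_pearson, combine_tests, confusion_metrics,
                          delong_test, mcnemar_test, pearson_with_ci,
                          per_patient_records, records_from_band_counts,
                          roc_auc, stratify)

#: per-FFR-band (total, correctly classified) vessel counts of the target
#: cohort: all 22 below 0.70 and all 12 above 0.90 correct, 19/25 and 37/44
#: in the middle bands
BAND_COUNTS = {"≤0.70": (22, 22), "0.70-0.80": (25, 19),
               "0.80-0.90": (44, 37), ">0.90": (12, 12)}


def _rec(vid, ctp, inv, qca=60.0, cac="<400", name="LAD", loc="proximal",
         pid=None):
    return VesselRecord(vid, pid or vid, ctp, inv, qca, cac, name, loc)


class TestClassify:
    def test_band_counts_give_published_table(self):
        table = classify(records_from_band_counts(BAND_COUNTS))
        assert (table.tp, table.fp, table.tn, table.fn) == (41, 7, 49, 6)

    def test_perfect_agreement(self):
        recs = [_rec(f"v{i}", f, f) for i, f in
                enumerate(np.linspace(0.3, 1.0, 10))]
        t = classify(recs)
        assert t.fp == t.fn == 0

    def test_boundary_value_is_positive(self):
        t = classify([_rec("v", 0.80, 0.80)])
        assert t.tp == 1

    def test_saturated_threshold(self):
        recs = [_rec(f"v{i}", f, f) for i, f in
                enumerate(np.linspace(0.3, 1.0, 10))]
        t = classify(recs, index_threshold=1.0, reference_threshold=1.0)
        assert t.tn == 0 and t.fn == 0 and t.tp == len(recs)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            classify([])


class TestConfusionMetrics:
    def test_published_point_estimates(self):
        m = confusion_metrics(ConfusionTable(tp=41, fp=7, tn=49, fn=6))
        assert m.sensitivity.estimate == pytest.approx(41 / 47)
        assert m.specificity.estimate == pytest.approx(49 / 56)
        assert m.accuracy.estimate == pytest.approx(90 / 103)
        assert m.ppv.estimate == pytest.approx(41 / 48)
        assert m.npv.estimate == pytest.approx(49 / 55)
        # printed to one decimal as percentages: 87.2 / 87.5 / 87.3-87.4 / 85.4 / 89.1
        assert round(100 * m.sensitivity.estimate, 1) == 87.2
        assert round(100 * m.specificity.estimate, 1) == 87.5
        assert round(100 * m.ppv.estimate, 1) == 85.4
        assert round(100 * m.npv.estimate, 1) == 89.1

    def test_sensitivity_exact_interval(self):
        m = confusion_metrics(ConfusionTable(41, 7, 49, 6))
        assert round(100 * m.sensitivity.ci_low, 1) == 74.3
        assert round(100 * m.sensitivity.ci_high, 1) == 95.2

    def test_perfect_and_symmetric_tables(self):
        perfect = confusion_metrics(ConfusionTable(10, 0, 10, 0))
        for name in ("sensitivity", "specificity", "accuracy", "ppv", "npv"):
            assert getattr(perfect, name).estimate == 1.0
        half = confusion_metrics(ConfusionTable(1, 1, 1, 1))
        for name in ("sensitivity", "specificity", "accuracy", "ppv", "npv"):
            assert getattr(half, name).estimate == 0.5

    def test_zero_denominator_reported_undefined(self):
        m = confusion_metrics(ConfusionTable(tp=0, fp=0, tn=5, fn=0))
        assert m.sensitivity is None
        assert m.ppv is None
        assert m.specificity.estimate == 1.0

    def test_cis_contain_estimates_and_stay_in_unit_interval(self):
        for k, n in [(0, 5), (5, 5), (3, 7), (41, 47)]:
            p = clopper_pearson(k, n)
            assert 0.0 <= p.ci_low <= p.estimate <= p.ci_high <= 1.0


class TestROC:
    def test_perfect_separation(self):
        scores = np.array([0.5, 0.6, 0.9, 0.95])
        labels = np.array([True, True, False, False])
        auc, _ = roc_auc(scores, labels)
        assert auc == 1.0

    def test_pure_ties(self):
        auc, _ = roc_auc(np.full(10, 0.8), np.arange(10) < 5)
        assert auc == 0.5

    def test_matches_pair_counting_oracle(self):
        rng = np.random.default_rng(2)
        scores = rng.random(30)
        labels = rng.random(30) < 0.4
        auc, _ = roc_auc(scores, labels, positive_lower=True)
        pos = scores[labels]
        neg = scores[~labels]
        wins = sum((p < n) + 0.5 * (p == n) for p in pos for n in neg)
        assert auc == pytest.approx(wins / (len(pos) * len(neg)), rel=1e-12)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(3)
        scores = rng.random(50)
        labels = rng.random(50) < 0.5
        a1, _ = roc_auc(scores, labels)
        a2, _ = roc_auc(np.exp(3.0 * scores) + 7.0, labels)
        assert a1 == pytest.approx(a2, rel=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], [True, True])

    def test_delong_variance_close_to_bootstrap(self):
        """DeLong SE vs 1000-resample bootstrap on n = 100 synthetic scores."""
        rng = np.random.default_rng(4)
        latent = rng.standard_normal(100)
        scores = latent + rng.standard_normal(100)
        labels = latent > 0
        _, var = roc_auc(scores, labels, positive_lower=False)
        boots = []
        for _ in range(1000):
            idx = rng.integers(0, 100, 100)
            if labels[idx].all() or not labels[idx].any():
                continue
            boots.append(roc_auc(scores[idx], labels[idx],
                                 positive_lower=False)[0])
        bvar = np.var(boots, ddof=1)
        assert abs(var - bvar) / bvar < 0.2


class TestDeLong:
    def test_identical_scores(self):
        rng = np.random.default_rng(0)
        s = rng.random(40)
        y = rng.random(40) < 0.5
        z, p = delong_test(s, s, y)
        assert z == 0.0 and p == 1.0

    def test_sign_matches_auc_difference(self):
        rng = np.random.default_rng(1)
        latent = rng.standard_normal(80)
        labels = latent > 0
        good = -latent + 0.3 * rng.standard_normal(80)  # low score = positive
        bad = rng.standard_normal(80)
        z, p = delong_test(good, bad, labels, positive_lower=True)
        auc_good, _ = roc_auc(good, labels)
        auc_bad, _ = roc_auc(bad, labels)
        assert np.sign(z) == np.sign(auc_good - auc_bad)
        assert p < 0.05

    def test_degenerate_zero_variance(self):
        # two perfectly separating but different classifiers
        y = np.array([True] * 5 + [False] * 5)
        a = np.concatenate([np.zeros(5), np.ones(5)])
        b = np.concatenate([np.full(5, 0.2), np.full(5, 0.9)])
        z, p = delong_test(a, b, y)  # equal AUCs of 1.0
        assert p == 1.0


class TestMcNemar:
    def test_one_sided_discordance_exact(self):
        # b=6, c=0: exact two-sided p = 2 * (1/2)^6
        assert mcnemar_test(6, 0) == pytest.approx(0.03125)

    def test_balanced_discordance(self):
        assert mcnemar_test(10, 10) >= 0.99

    def test_chi2_branch_close_to_exact(self):
        from scipy.stats import binomtest
        p_chi = mcnemar_test(40, 20)
        p_exact = binomtest(40, 60, 0.5).pvalue
        assert abs(p_chi - p_exact) < 0.02

    def test_no_discordance_convention(self):
        assert mcnemar_test(0, 0) == 1.0

    def test_matches_statsmodels(self):
        from statsmodels.stats.contingency_tables import mcnemar as sm_mcnemar
        for b, c in [(3, 8), (12, 5), (30, 22)]:
            table = [[0, b], [c, 0]]
            exact = b + c < 25
            expected = sm_mcnemar(table, exact=exact, correction=True).pvalue
            assert mcnemar_test(b, c) == pytest.approx(expected, rel=1e-10)


class TestCorrelationAgreement:
    def test_pearson_identity_and_reflection(self):
        x = np.linspace(0.0, 1.0, 20)
        r, _ = pearson_with_ci(x, x)
        assert r == pytest.approx(1.0)
        r, _ = pearson_with_ci(x, -x)
        assert r == pytest.approx(-1.0)

    def test_pearson_toy_hand_value(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.0, 1.0, 4.0, 3.0, 5.0])
        r, ci = pearson_with_ci(x, y)
        cov = np.mean((x - x.mean()) * (y - y.mean()))
        hand = cov / (x.std() * y.std())
        assert r == pytest.approx(hand, rel=1e-12)
        assert ci[0] <= r <= ci[1]

    def test_pearson_constant_rejected(self):
        with pytest.raises(ValueError):
            pearson_with_ci([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_bland_altman_identical_and_offset(self):
        x = np.linspace(0.5, 1.0, 8)
        assert bland_altman(x, x) == (0.0, 0.0, 0.0)
        mean, lo, hi = bland_altman(x, x - 0.05)
        assert (mean, lo, hi) == pytest.approx((0.05, 0.05, 0.05))

    def test_bland_altman_toy_hand_value(self):
        x = np.array([0.80, 0.75, 0.90, 0.85, 0.70, 0.95])
        y = np.array([0.82, 0.70, 0.88, 0.90, 0.72, 0.93])
        mean, lo, hi = bland_altman(x, y)
        d = x - y
        assert mean == pytest.approx(d.mean())
        assert hi == pytest.approx(d.mean() + 1.96 * d.std(ddof=1))
        assert lo == pytest.approx(d.mean() - 1.96 * d.std(ddof=1))

    @given(st.floats(min_value=-0.2, max_value=0.2))
    def test_bland_altman_pure_offset_property(self, d):
        x = np.linspace(0.5, 1.0, 6)
        mean, lo, hi = bland_altman(x + d, x)
        assert mean == pytest.approx(d, abs=1e-12)
        assert lo == pytest.approx(d, abs=1e-9)


class TestStratify:
    def test_band_accuracies_match_published_counts(self):
        recs = records_from_band_counts(BAND_COUNTS)
        strata = stratify(recs, "ffr_band")
        acc = {k: (t.tp + t.tn, t.total) for k, (t, m) in strata.items()}
        assert acc["≤0.70"] == (22, 22)
        assert acc["0.70-0.80"] == (19, 25)
        assert acc["0.80-0.90"] == (37, 44)
        assert acc[">0.90"] == (12, 12)

    def test_single_stratum_reproduces_global_table(self):
        recs = records_from_band_counts(BAND_COUNTS)
        strata = stratify(recs, "cac")  # all "<400"
        assert set(strata) == {"<400"}
        t, _ = strata["<400"]
        g = classify(recs)
        assert (t.tp, t.fp, t.tn, t.fn) == (g.tp, g.fp, g.tn, g.fn)

    def test_partition_conserves_counts_and_pools(self):
        rng = np.random.default_rng(8)
        recs = [_rec(f"v{i}", float(rng.uniform(0.3, 1.0)),
                     float(rng.uniform(0.3, 1.0)),
                     qca=float(rng.uniform(30, 90)),
                     cac="<400" if rng.random() < 0.7 else ">=400",
                     name="LAD" if rng.random() < 0.8 else "LCX",
                     loc=str(rng.choice(["proximal", "middle", "distal"])))
                for i in range(60)]
        pooled = classify(recs)
        for scheme in ("qca", "cac", "vessel_name", "lesion_location",
                       "ffr_band"):
            strata = stratify(recs, scheme)
            total = sum(t.total for t, _ in strata.values())
            assert total == len(recs)
            combined = ConfusionTable(0, 0, 0, 0)
            for t, _ in strata.values():
                combined = combined + t
            assert (combined.tp, combined.fp, combined.tn, combined.fn) == \
                (pooled.tp, pooled.fp, pooled.tn, pooled.fn)
            # pooled accuracy equals the count-weighted stratum accuracy
            weighted = sum((t.tp + t.tn) for t, _ in strata.values()) / total
            assert weighted == pytest.approx(
                confusion_metrics(pooled).accuracy.estimate)

    def test_chi_square_accuracy_comparison(self):
        chi2, p = chi_square_accuracy({"a": (37, 44), "b": (19, 25)})
        assert 0.0 <= p <= 1.0

    def test_unknown_scheme_rejected(self):
        with pytest.raises(ValueError):
            stratify([_rec("v", 0.8, 0.8)], "bogus")


class TestAggregation:
    def test_worst_vessel_rule(self):
        recs = [_rec("v1", 0.9, 0.95, pid="p1"),
                _rec("v2", 0.6, 0.7, pid="p1"),
                _rec("v3", 0.85, 0.9, pid="p2")]
        per_pat = per_patient_records(recs)
        assert len(per_pat) == 2
        p1 = next(r for r in per_pat if r.patient_id == "p1")
        assert p1.ctp_ffr == 0.6 and p1.invasive_ffr == 0.7

    def test_combiner_rules(self):
        a = np.array([True, False, True])
        b = np.array([False, False, True])
        assert combine_tests([a, b], "or").tolist() == [True, False, True]
        assert combine_tests([a, b], "and").tolist() == [False, False, True]
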
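"""Tests of ROC/AUC, Kaplan–Meier, log-rank and cohort comparisons."""

import numpy as np
import pandas as pd
import pytest

from episcope.io import CohortTable
from episcope.simulate import SynthConfig, generate
from episcope.survival import (
    clinical_score_benchmark,
    compare_groups,
    km_curve,
    logrank_test,
    roc_auc,
)


def pair_counting_auc(scores, labels):
    """Independent oracle: concordant pairs + half ties over all pos/neg pairs."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
    return wins / (len(pos) * len(neg))


def naive_logrank_chi2(ta, ea, tb, eb):
    """Independent oracle: explicit 2x2 table at every event time."""
    o_minus_e, var = 0.0, 0.0
    for t in sorted(set(np.concatenate([ta[ea], tb[eb]]))):
        n1 = (ta >= t).sum()
        n2 = (tb >= t).sum()
        d1 = ((ta == t) & ea).sum()
        d2 = ((tb == t) & eb).sum()
        n, d = n1 + n2, d1 + d2
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n - d) / (n - 1) * (n1 / n) * (n2 / n)
    return o_minus_e**2 / var


class TestRocAuc:
    def test_perfect_separation(self):
        res = roc_auc([0.9, 0.8, 0.7, 0.2, 0.1], [1, 1, 1, 0, 0])
        assert res.auc == 1.0

    def test_matches_pair_counting_oracle(self, rng):
        for _ in range(200):
            n = rng.integers(6, 30)
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                continue
            scores = np.round(rng.normal(size=n), 1)  # rounding forces ties
            res = roc_auc(scores, labels)
            assert res.auc == pytest.approx(pair_counting_auc(scores, labels), abs=1e-12)

    def test_score_negation_mirrors_auc(self, rng):
        for _ in range(20):
            labels = rng.integers(0, 2, size=25)
            if labels.min() == labels.max():
                continue
            scores = rng.normal(size=25)
            a1 = roc_auc(scores, labels).auc
            a2 = roc_auc(-scores, labels).auc
            assert a1 + a2 == pytest.approx(1.0, abs=1e-12)

    def test_direction_flag_flips_orientation(self, rng):
        labels = np.array([1, 1, 0, 0, 1, 0])
        scores = np.array([1.0, 2.0, 5.0, 6.0, 0.5, 4.0])  # low = positive class
        assert roc_auc(scores, labels, direction=-1).auc == 1.0

    def test_null_distribution_centered_at_half(self, rng):
        scores = rng.normal(size=34)
        aucs = []
        for _ in range(500):
            labels = np.zeros(34, dtype=int)
            labels[rng.choice(34, 22, replace=False)] = 1
            aucs.append(roc_auc(scores, labels).auc)
        # mean near 0.5 and ~95% within 2 SD of the rank-sum null
        sd = np.sqrt((34 + 1) / (12 * 22 * 12))
        assert abs(np.mean(aucs) - 0.5) < 0.02
        assert np.mean(np.abs(np.array(aucs) - 0.5) < 2 * sd) > 0.9

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_auc([1.0, 2.0], [1, 1])


class TestKaplanMeier:
    def test_all_events_stepwise(self):
        km = km_curve([1.0, 2.0, 3.0, 4.0], [True] * 4)
        np.testing.assert_allclose(km.survival, [0.75, 0.5, 0.25, 0.0])

    def test_all_censored_flat(self):
        km = km_curve([5.0, 6.0, 7.0], [False] * 3)
        assert (km.survival == 1.0).all()

    def test_hand_computed_mixed_examples(self):
        # events at 2 and 5 with censoring at 3: S(2) = 2/3, and the subject
        # censored at 3 has left the risk set, so the event at 5 empties it
        km = km_curve([2.0, 3.0, 5.0], [True, False, True])
        s = dict(zip(km.times, km.survival))
        assert s[2.0] == pytest.approx(2 / 3)
        assert s[5.0] == pytest.approx(0.0)
        # four subjects: S(2) = 3/4, then 2 at risk at 5 -> S(5) = 3/4 * 1/2
        km = km_curve([2.0, 3.0, 5.0, 7.0], [True, False, True, False])
        s = dict(zip(km.times, km.survival))
        assert s[2.0] == pytest.approx(3 / 4)
        assert s[5.0] == pytest.approx(3 / 8)

    def test_no_censoring_equals_empirical_survival(self, rng):
        times = rng.exponential(10, size=40).round(1) + 0.1
        km = km_curve(times, np.ones(40, dtype=bool))
        for t, s in zip(km.times, km.survival):
            assert s == pytest.approx((times > t).mean(), abs=1e-12)

    def test_monotone_invariants(self, rng):
        times = rng.exponential(20, size=50) + 0.1
        events = rng.random(50) < 0.6
        km = km_curve(times, events)
        assert (np.diff(km.survival) <= 1e-12).all()
        assert (np.diff(km.at_risk) <= 0).all()
        assert km.survival[0] <= 1.0

    def test_nonpositive_time_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            km_curve([0.0, 1.0], [True, True])


class TestLogRank:
    def test_identical_groups_null(self):
        t = np.array([2.0, 4.0, 6.0, 8.0])
        e = np.array([True, True, False, True])
        res = logrank_test(t, e, t, e)
        assert res.chi_square == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_observed_equals_expected_total(self, rng):
        ta, tb = rng.exponential(10, 20) + 0.1, rng.exponential(5, 15) + 0.1
        ea, eb = rng.random(20) < 0.7, rng.random(15) < 0.7
        if not (ea.any() or eb.any()):
            ea[0] = True
        res = logrank_test(ta, ea, tb, eb)
        assert sum(res.observed) == pytest.approx(sum(res.expected), abs=1e-9)

    def test_matches_naive_oracle_on_random_cohorts(self, rng):
        for _ in range(50):
            na, nb = rng.integers(5, 20, size=2)
            ta = rng.exponential(10, na).round(0) + 1  # rounding creates tied times
            tb = rng.exponential(6, nb).round(0) + 1
            ea = rng.random(na) < 0.7
            eb = rng.random(nb) < 0.7
            if not (ea.any() or eb.any()):
                ea[0] = True
            res = logrank_test(ta, ea, tb, eb)
            assert res.chi_square == pytest.approx(naive_logrank_chi2(ta, ea, tb, eb), rel=1e-9)

    def test_matches_lifelines(self, rng):
        from lifelines.statistics import logrank_test as ll_logrank

        for _ in range(10):
            ta = rng.exponential(10, 15) + 0.1
            tb = rng.exponential(5, 12) + 0.1
            ea = rng.random(15) < 0.8
            eb = rng.random(12) < 0.8
            if not (ea.any() or eb.any()):
                ea[0] = True
            ours = logrank_test(ta, ea, tb, eb)
            ref = ll_logrank(ta, tb, event_observed_A=ea, event_observed_B=eb)
            assert ours.chi_square == pytest.approx(ref.test_statistic, rel=1e-6)
            assert ours.p_value == pytest.approx(ref.p_value, rel=1e-6)

    def test_chi2_p_close_to_permutation_p(self, rng):
        ta = rng.weibull(1.2, 17) * 8 + 0.1
        tb = rng.weibull(1.2, 17) * 16 + 0.1
        ea = np.ones(17, dtype=bool)
        eb = rng.random(17) < 0.5
        res = logrank_test(ta, ea, tb, eb)
        t_all = np.concatenate([ta, tb])
        e_all = np.concatenate([ea, eb])
        stat = res.chi_square
        count = 0
        for _ in range(500):
            idx = rng.permutation(34)
            s = logrank_test(t_all[idx[:17]], e_all[idx[:17]],
                             t_all[idx[17:]], e_all[idx[17:]]).chi_square
            count += s >= stat
        assert abs(res.p_value - count / 500) < 0.03

    def test_power_at_hazard_ratio_three(self, rng):
        # HR = 3 with n = 17 + 17: the test should usually reject
        ps = []
        for _ in range(100):
            ta = rng.weibull(1.2, 17) * 5 + 0.05
            tb = rng.weibull(1.2, 17) * 5 * 3 ** (1 / 1.2) + 0.05
            ps.append(logrank_test(ta, np.ones(17, bool), tb, np.ones(17, bool)).p_value)
        assert np.median(ps) < 0.05

    def test_no_events_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            logrank_test([1.0, 2.0], [False, False], [3.0], [False])


@pytest.fixture(scope="module")
def printed_cohort():
# cohort reproducing published 2x2 comorbidity splits:
# diabetes 12/12 survivors vs 14/22 non-survivors, etc.
    n = 34
    outcome = ["survivor"] * 12 + ["non_survivor"] * 22
    diabetes = [1] * 12 + [1] * 14 + [0] * 8
    hypertension = [1] * 8 + [0] * 4 + [1] * 11 + [0] * 11
    df = pd.DataFrame(
        {
            "outcome": outcome,
            "early_outcome": ["success"] * 17 + ["failure"] * 17,
            "time_to_event": np.linspace(1, 60, n),
            "event_observed": [o == "non_survivor" for o in outcome],
            "save_score": np.zeros(n),
            "apache2": np.zeros(n),
            "lods": np.zeros(n),
            "mods": np.zeros(n),
            "sofa": np.zeros(n),
            "diabetes": diabetes,
            "hypertension": hypertension,
            "age": np.linspace(40.0, 65.0, n),
            "constant": np.ones(n),
            "has_tr": [True] * 14 + [False] * 20,
        },
        index=[f"P{i}" for i in range(n)],
    )
    return CohortTable(df, covariates=["diabetes", "hypertension", "age", "constant"])


class TestCompareGroups:
    def test_fisher_rows_reproduce_printed_pvalues(self, printed_cohort):
        tab = compare_groups(printed_cohort, "outcome").set_index("variable")
        assert tab.loc["diabetes", "p_value"] == pytest.approx(0.030, abs=5e-4)
        assert tab.loc["hypertension", "p_value"] == pytest.approx(0.476, abs=5e-4)
        assert tab.loc["diabetes", "test"] == "fisher_exact"

    def test_continuous_uses_welch(self, printed_cohort):
        tab = compare_groups(printed_cohort, "outcome").set_index("variable")
        assert tab.loc["age", "test"] == "welch_t"

    def test_constant_covariate_flagged_not_testable(self, printed_cohort):
        tab = compare_groups(printed_cohort, "outcome").set_index("variable")
        assert tab.loc["constant", "test"] == "not_testable"
        assert np.isnan(tab.loc["constant", "p_value"])

    def test_identical_groups_give_p_one(self):
        df = pd.DataFrame(
            {
                "outcome": ["survivor"] * 6 + ["non_survivor"] * 6,
                "early_outcome": ["success"] * 12,
                "time_to_event": np.arange(1.0, 13.0),
                "event_observed": [False] * 6 + [True] * 6,
                "save_score": 0.0, "apache2": 0.0, "lods": 0.0, "mods": 0.0, "sofa": 0.0,
                "flag": [0, 0, 0, 1, 1, 1] * 2,
                "has_tr": True,
            },
            index=[f"P{i}" for i in range(12)],
        )
        tab = compare_groups(
            CohortTable(df, covariates=["flag"]), "outcome"
        ).set_index("variable")
        assert tab.loc["flag", "p_value"] == pytest.approx(1.0)


class TestClinicalScoreBenchmark:
    def test_latent_risk_score_discriminates_at_large_n(self):
        sim = generate(SynthConfig(
            n_patients=400, n_survivors=170, n_tr=20, n_probes=20,
            n_prognostic=2, n_responsive=2, score_signal=2.5, seed=21,
        ))
        res = clinical_score_benchmark(sim.cohort, "outcome")
        assert res["apache2"].auc > 0.85
        assert res["save_score"].auc > 0.5  # direction handled: SAVE flipped

    def test_null_scores_have_nominal_type_one_error(self):
        # with no outcome loading, each score's AUC test should reject at
        # roughly the nominal 5% rate across seeds
        rejections = {}
        for seed in range(100):
            sim = generate(SynthConfig(
                n_probes=10, n_prognostic=1, n_responsive=1, score_signal=0.0, seed=seed,
            ))
            res = clinical_score_benchmark(sim.cohort, "early_outcome")
            for name, r in res.items():
                rejections.setdefault(name, []).append(r.p_value < 0.05)
        for name, hits in rejections.items():
            assert np.mean(hits) <= 0.10, name

    def test_all_missing_score_skipped_with_warning(self, small_sim):
        data = small_sim.cohort.data.copy()
        data["sofa"] = np.nan
        cohort = CohortTable(data, covariates=small_sim.cohort.covariates)
        with pytest.warns(UserWarning, match="sofa"):
            res = clinical_score_benchmark(cohort, "outcome")
        assert "sofa" not in res
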
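"""Tests of the random-forest classifier, LOOCV conventions and EpiSAVE."""

import math

import numpy as np
import pandas as pd
import pytest

from episcope.classifier import (
    ForestConfig,
    episave_augment,
    fold_indicators,
    loocv_evaluate,
    pooled_metrics,
    predict_vote_fraction,
    self_test,
    summarize_indicators,
    train_forest,
    transfer_test,
)
from episcope.io import CohortTable


def separated_clusters(rng, n=40, p=5, gap=4.0):
    y = np.repeat([0, 1], n // 2)
    X = rng.normal(size=(n, p)) + gap * y[:, None]
    return X, y


class TestForest:
    def test_self_test_is_perfect_with_deep_trees(self, rng):
        X, y = separated_clusters(rng, gap=0.5)  # even overlapping classes
        forest = train_forest(X, y, ForestConfig(seed=1))
        m = self_test(forest, X, y)
        assert (m["accuracy"], m["precision"], m["recall"], m["f1"]) == (1, 1, 1, 1)

    def test_separated_clusters_generalize(self, rng):
        X, y = separated_clusters(rng, n=80)
        hold = np.arange(0, 80, 4)
        train = np.setdiff1d(np.arange(80), hold)
        forest = train_forest(X[train], y[train], ForestConfig(seed=2))
        acc = pooled_metrics(y[hold], predict_vote_fraction(forest, X[hold]) >= 0.5)["accuracy"]
        assert acc > 0.95

    def test_same_seed_identical_predictions(self, rng):
        X, y = separated_clusters(rng, gap=1.0)
        v1 = predict_vote_fraction(train_forest(X, y, ForestConfig(seed=3)), X)
        v2 = predict_vote_fraction(train_forest(X, y, ForestConfig(seed=3)), X)
        np.testing.assert_array_equal(v1, v2)

    def test_single_class_rejected(self, rng):
        X = rng.normal(size=(10, 3))
        with pytest.raises(ValueError, match="per class"):
            train_forest(X, np.ones(10, dtype=int))

    def test_feature_mismatch_rejected(self, rng):
        X, y = separated_clusters(rng)
        forest = train_forest(X, y)
        with pytest.raises(ValueError, match="feature mismatch"):
            predict_vote_fraction(forest, X[:, :3])

    def test_vote_stability_under_forest_size(self, small_sim):
        # predictions must be stable when the ensemble grows 4x
        sim = small_sim
        pats = sim.cohort.patient_ids
        sel = sim.truth.prognostic_probe_ids
        Xtr = sim.t0.subset_probes(sel).values[pats].to_numpy().T
        Xte = sim.t2.subset_probes(sel).values[pats].to_numpy().T
        y = sim.cohort.outcome_vector()
        p500 = predict_vote_fraction(train_forest(Xtr, y, ForestConfig(500, seed=5)), Xte) >= 0.5
        p2000 = predict_vote_fraction(train_forest(Xtr, y, ForestConfig(2000, seed=5)), Xte) >= 0.5
        assert (p500 != p2000).mean() < 0.05


class TestLoocvConventions:
    def test_mean_sd_structure_31_of_34(self):
        # 31/34 correct folds: the binary-indicator convention reproduces
        # the characteristic 0.912 +/- 0.284 summary exactly
        ind = pd.DataFrame({"accuracy": [1] * 31 + [0] * 3})
        s = summarize_indicators(ind)
        assert s.loc["accuracy", "mean"] == pytest.approx(31 / 34, abs=5e-4)
        assert s.loc["accuracy", "sd"] == pytest.approx(math.sqrt((31 / 34) * (3 / 34)))
        assert s.loc["accuracy", "mean"] == pytest.approx(0.912, abs=5e-4)
        assert s.loc["accuracy", "sd"] == pytest.approx(0.284, abs=5e-4)

    def test_sd_is_binary_indicator_identity(self, rng):
        # for any 0/1 indicator vector, SD = sqrt(m(1-m)) exactly
        for _ in range(10):
            v = rng.integers(0, 2, size=rng.integers(3, 50))
            s = summarize_indicators(pd.DataFrame({"m": v}))
            m = v.mean()
            assert s.loc["m", "sd"] == pytest.approx(math.sqrt(m * (1 - m)), abs=1e-12)

    def test_recall_convention_counts_positives_only(self):
        # all 22 positives predicted positive, 12 true negatives contribute 0
        rows = [fold_indicators(1, 1)] * 22 + [fold_indicators(0, 0)] * 12
        s = summarize_indicators(pd.DataFrame(rows))
        assert s.loc["recall", "mean"] == pytest.approx(22 / 34)
        assert s.loc["recall", "sd"] == pytest.approx(0.478, abs=5e-4)
        assert s.loc["accuracy", "mean"] == 1.0

    def test_undefined_as_zero_for_negative_folds(self):
        assert fold_indicators(0, 0) == {"accuracy": 1, "precision": 0, "recall": 0, "f1": 0}
        assert fold_indicators(0, 1) == {"accuracy": 0, "precision": 0, "recall": 0, "f1": 0}
        assert fold_indicators(1, 0) == {"accuracy": 0, "precision": 0, "recall": 0, "f1": 0}
        assert fold_indicators(1, 1) == {"accuracy": 1, "precision": 1, "recall": 1, "f1": 1}

    def test_loocv_perfect_on_separated_data(self, rng):
        # every fold classified correctly: accuracy is 1 +/- 0, while the
        # positive-only indicators average to the positive-class fraction
        X, y = separated_clusters(rng, n=12)
        rep = loocv_evaluate(X, y, ForestConfig(n_trees=100, seed=4))
        assert rep.loocv_summary.loc["accuracy", "mean"] == 1.0
        assert rep.loocv_summary.loc["accuracy", "sd"] == 0.0
        assert rep.loocv_summary.loc["recall", "mean"] == pytest.approx(y.mean())
        assert rep.loocv_summary.loc["precision", "mean"] == pytest.approx(y.mean())

    def test_loocv_needs_three_samples(self, rng):
        with pytest.raises(ValueError, match="n >= 3"):
            loocv_evaluate(rng.normal(size=(2, 2)), np.array([0, 1]))


class TestTransferMetrics:
    @pytest.mark.parametrize(
        "tp,fp,tn,fn,acc,prec,rec",
        [
            (20, 6, 6, 2, 0.765, 0.769, 0.909),
            (22, 9, 3, 0, 0.735, 0.710, 1.0),
        ],
    )
    def test_confusion_arithmetic(self, tp, fp, tn, fn, acc, prec, rec):
        y_true = np.array([1] * tp + [0] * fp + [0] * tn + [1] * fn)
        y_pred = np.array([1] * tp + [1] * fp + [0] * tn + [0] * fn)
        m = pooled_metrics(y_true, y_pred)
        assert m["accuracy"] == pytest.approx(acc, abs=5e-4)
        assert m["precision"] == pytest.approx(prec, abs=5e-4)
        assert m["recall"] == pytest.approx(rec, abs=5e-4)
        assert m["f1"] == pytest.approx(
            2 * m["precision"] * m["recall"] / (m["precision"] + m["recall"])
        )

    def test_matches_sklearn_oracle(self, rng):
        from sklearn.metrics import accuracy_score, f1_score, precision_score, recall_score

        for _ in range(10):
            y_true = rng.integers(0, 2, size=30)
            y_pred = rng.integers(0, 2, size=30)
            m = pooled_metrics(y_true, y_pred)
            assert m["accuracy"] == pytest.approx(accuracy_score(y_true, y_pred))
            assert m["precision"] == pytest.approx(
                precision_score(y_true, y_pred, zero_division=0)
            )
            assert m["recall"] == pytest.approx(recall_score(y_true, y_pred, zero_division=0))
            assert m["f1"] == pytest.approx(f1_score(y_true, y_pred, zero_division=0))

    def test_all_correct_gives_ones(self, rng):
        X, y = separated_clusters(rng)
        forest = train_forest(X, y, ForestConfig(seed=6))
        rep = transfer_test(forest, X, y)
        assert rep.test_metrics["accuracy"] == 1.0
        assert rep.test_metrics["f1"] == 1.0
        assert ((rep.test_probabilities >= 0) & (rep.test_probabilities <= 1)).all()


class TestEpiSave:
    def test_appends_scaled_column(self, small_sim):
        sim = small_sim
        pats = sim.cohort.patient_ids
        X = sim.t0.values.iloc[:4][pats].to_numpy().T
        aug = episave_augment(X, sim.cohort, pats)
        assert aug.shape == (X.shape[0], X.shape[1] + 1)
        assert aug[:, -1].min() == 0.0 and aug[:, -1].max() == 1.0

    def test_constant_score_maps_to_half(self, small_sim):
        sim = small_sim
        data = sim.cohort.data.copy()
        data["save_score"] = 3.0
        cohort = CohortTable(data, covariates=sim.cohort.covariates)
        aug = episave_augment(np.zeros((len(data), 2)), cohort, list(data.index))
        assert (aug[:, -1] == 0.5).all()

    def test_missing_score_rejected(self, small_sim):
        sim = small_sim
        data = sim.cohort.data.copy()
        data.loc[data.index[0], "save_score"] = np.nan
        cohort = CohortTable(data, covariates=sim.cohort.covariates)
        with pytest.raises(ValueError, match="missing SAVE"):
            episave_augment(np.zeros((len(data), 2)), cohort, list(data.index))

    def test_informative_score_does_not_hurt_transfer(self):
        # weak methylation signal + informative SAVE score: fusing the score
        # must not reduce the average transfer AUC
        from episcope.simulate import SynthConfig, generate
        from episcope.survival import roc_auc

        deltas = []
        for seed in range(10):
            cfg = SynthConfig(
                n_probes=300, n_prognostic=6, n_responsive=20,
                prognostic_effect=0.5, score_signal=2.0, seed=seed,
            )
            sim = generate(cfg)
            pats = sim.cohort.patient_ids
            y = sim.cohort.outcome_vector()
            sel = sim.truth.prognostic_probe_ids
            Xtr = sim.t0.subset_probes(sel).values[pats].to_numpy().T
            Xte = sim.t2.subset_probes(sel).values[pats].to_numpy().T
            f = train_forest(Xtr, y, ForestConfig(seed=0))
            base = roc_auc(predict_vote_fraction(f, Xte), y).auc
            fe = train_forest(episave_augment(Xtr, sim.cohort, pats), y, ForestConfig(seed=0))
            fused = roc_auc(predict_vote_fraction(fe, episave_augment(Xte, sim.cohort, pats)), y).auc
            deltas.append(fused - base)
        assert np.mean(deltas) >= 0.0
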
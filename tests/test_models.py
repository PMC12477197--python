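"""Split arithmetic, SMOTE contract, registry behaviour, CV protocol and
metric computation."""

import numpy as np
import pytest

from ramanembryo.datatypes import GROUPS, RamanSpectrum, SampleRecord, dataset_to_matrix
from ramanembryo.models import (ALL_MODELS, apply_split, cross_validate,
                                evaluate, sample_level_folds, smote_oversample,
                                split_dataset, train_model)


def dummy_samples(sizes=(58, 25, 89), n_spec=2):
    wn = np.arange(300.0, 320.0)
    out = []
    for g, n in zip(GROUPS, sizes):
        for j in range(n):
            spectra = [RamanSpectrum(wn, np.full(len(wn), float(j + r)))
                       for r in range(n_spec)]
            out.append(SampleRecord(f"{g}{j:03d}", g, "I-II", spectra))
    return out


class TestSplit:
    def test_reference_cohort_gives_137_35(self):
        plan = split_dataset(dummy_samples(), 0.8, seed=0)
        assert len(plan.all_train) == 137
        assert len(plan.all_predict) == 35
        assert [len(plan.train_ids[g]) for g in GROUPS] == [46, 20, 71]

    @pytest.mark.parametrize("sizes,expected_train", [
        ((10, 10, 10), 24),
        ((5, 4, 3), 9),
    ])
    def test_floor_arithmetic(self, sizes, expected_train):
        plan = split_dataset(dummy_samples(sizes), 0.8, seed=1)
        assert len(plan.all_train) == expected_train
        assert len(plan.all_predict) == sum(sizes) - expected_train

    def test_partition_exhaustive_disjoint_no_leakage(self):
        samples = dummy_samples((12, 8, 15))
        plan = split_dataset(samples, 0.8, seed=2)
        train, predict = apply_split(samples, plan)
        train_ids = {r.sample_id for r in train}
        predict_ids = {r.sample_id for r in predict}
        assert train_ids.isdisjoint(predict_ids)
        assert train_ids | predict_ids == {r.sample_id for r in samples}
        # every spectrum follows its sample (structural: split is by sample)
        _, _, sids = dataset_to_matrix(train)
        assert set(sids) == train_ids

    def test_deterministic(self):
        samples = dummy_samples((10, 10, 10))
        a = split_dataset(samples, 0.8, seed=5)
        b = split_dataset(samples, 0.8, seed=5)
        assert a.train_ids == b.train_ids

    def test_degenerate_split_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            split_dataset(dummy_samples((1, 10, 10)), 0.8, seed=0)
        with pytest.raises(ValueError):
            split_dataset(dummy_samples(), 1.2, seed=0)


class TestSmote:
    def test_counts_equalized(self, rng):
        X = rng.standard_normal((200, 10))
        y = np.array(["A"] * 100 + ["B"] * 40 + ["C"] * 60)
        Xb, yb = smote_oversample(X, y, 5, seed=0)
        _, counts = np.unique(yb, return_counts=True)
        assert counts.tolist() == [100, 100, 100]

    def test_originals_preserved_verbatim(self, rng):
        X = rng.standard_normal((90, 5))
        y = np.array(["A"] * 50 + ["B"] * 40)
        Xb, yb = smote_oversample(X, y, 5, seed=0)
        assert np.array_equal(Xb[:90], X)
        assert np.array_equal(yb[:90], y)

    def test_balanced_input_unchanged(self, rng):
        X = rng.standard_normal((60, 5))
        y = np.repeat(["A", "B", "C"], 20)
        Xb, yb = smote_oversample(X, y, 5, seed=0)
        assert np.array_equal(Xb, X) and np.array_equal(yb, y)

    def test_synthetic_rows_between_two_parents(self, rng):
        """Brute-force parent search: every synthetic row must lie
        coordinate-wise between two original same-class rows."""
        X = rng.standard_normal((50, 4))
        y = np.array(["A"] * 35 + ["B"] * 15)
        Xb, yb = smote_oversample(X, y, k_neighbors=5, seed=0)
        originals = X[y == "B"]
        for row in Xb[50:]:
            found = False
            for i in range(len(originals)):
                for j in range(len(originals)):
                    if i == j:
                        continue
                    lo = np.minimum(originals[i], originals[j])
                    hi = np.maximum(originals[i], originals[j])
                    if np.all(row >= lo - 1e-9) and np.all(row <= hi + 1e-9):
                        # also collinear with the two parents
                        d = originals[j] - originals[i]
                        t = (row - originals[i]) @ d / (d @ d)
                        if np.allclose(originals[i] + t * d, row, atol=1e-8):
                            found = True
                            break
                if found:
                    break
            assert found

    def test_tiny_class_rejected(self, rng):
        X = rng.standard_normal((24, 3))
        y = np.array(["A"] * 20 + ["B"] * 4)
        with pytest.raises(ValueError, match="smaller k"):
            smote_oversample(X, y, k_neighbors=5)


class TestTrainModel:
    def test_unknown_name_lists_registry(self):
        with pytest.raises(ValueError, match="GRU"):
            train_model("XGB", np.ones((4, 2)), np.array(["A", "A", "B", "B"]))

    def test_lda_matches_fisher_direction(self, rng):
        """Two spherical Gaussians: the LDA boundary normal equals the
        class-mean difference (closed-form Fisher discriminant)."""
        n = 4000
        shift = np.zeros(6)
        shift[2] = 4.0
        X = rng.standard_normal((n, 6))
        y = np.array(["A"] * (n // 2) + ["B"] * (n // 2))
        X[y == "B"] += shift
        est = train_model("LDA", X, y)
        w = est.coef_.ravel()
        cos = abs(w[2]) / np.linalg.norm(w)
        assert cos > 0.99

    def test_nb_perfect_on_separated_single_feature(self):
        X = np.array([[0.0], [0.1], [5.0], [5.1]])
        y = np.array(["A", "A", "B", "B"])
        est = train_model("NB", X, y)
        assert np.mean(est.predict(X) == y) == 1.0

    @pytest.mark.parametrize("name", ALL_MODELS)
    def test_interpolation_regime_all_models(self, name, rng):
        """Three tight, far-apart classes (two points each): every family
        must classify its own training points correctly."""
        centers = np.array([[0.0, 0.0], [50.0, 0.0], [0.0, 50.0]])
        X = np.vstack([c + 0.5 * rng.standard_normal((2, 2)) for c in centers])
        y = np.repeat(["A", "B", "C"], 2)
        hp = {"KNN": {"n_neighbors": 1}, "RSVM": {"fraction": 1.0},
              "GRU": {"epochs": 200, "patch": 2, "hidden_size": 8},
              "GB": {"min_samples_leaf": 1},
              "MLP": {"early_stopping": False, "max_iter": 3000},
              "ANN": {"early_stopping": False, "max_iter": 3000}}.get(name)
        est = train_model(name, X, y, hp, seed=0)
        assert np.mean(est.predict(X) == y) == 1.0
        proba = est.predict_proba(X)
        assert np.allclose(proba.sum(axis=1), 1.0)


@pytest.mark.parametrize("name", ALL_MODELS)
def test_every_model_beats_chance_on_separable_data(name, ml_data):
    """High-separability cohort: each registry family must clear chance
    (1/3) by more than 3 binomial SE on its own training distribution."""
    X, y, sids = ml_data["X"], ml_data["y"], ml_data["sample_ids"]
    uniq = np.unique(sids)
    rng = np.random.default_rng(1)
    test_ids = set(rng.choice(uniq, size=len(uniq) // 5, replace=False))
    te = np.array([s in test_ids for s in sids])
    est = train_model(name, X[~te], y[~te], None, seed=0)
    acc = float(np.mean(est.predict(X[te]) == y[te]))
    se = np.sqrt((1 / 3) * (2 / 3) / int(te.sum()))
    assert acc > 1 / 3 + 3 * se, (name, acc)


class TestCrossValidate:
    def test_every_sample_in_exactly_one_validation_fold(self):
        samples = dummy_samples((20, 20, 20), n_spec=3)
        X, y, sids = dataset_to_matrix(samples)
        seen = []
        for _, va in sample_level_folds(sids, y, 5, seed=0):
            seen.extend(np.unique(sids[va]).tolist())
        assert sorted(seen) == sorted({r.sample_id for r in samples})

    def test_deep_models_rejected(self, rng):
        with pytest.raises(ValueError, match="deep"):
            cross_validate("GRU", rng.random((10, 3)),
                           np.repeat(["A", "B"], 5), np.arange(10), 2)

    def test_too_few_samples_per_class_rejected(self, rng):
        X = rng.random((6, 3))
        y = np.repeat(["A", "B", "C"], 2)
        with pytest.raises(ValueError, match="folds"):
            cross_validate("LDA", X, y, np.arange(6).astype(str), 5)

    def test_separable_lda_above_09(self, ml_data):
        cv = cross_validate("LDA", ml_data["X"], ml_data["y"],
                            ml_data["sample_ids"], 5, seed=0)
        assert cv["mean_score"] > 0.9
        assert len(cv["fold_scores"]) == 5


class TestEvaluate:
    def test_perfect_predictions(self, rng):
        X = np.vstack([np.zeros((5, 2)), np.ones((5, 2)) * 10,
                       np.ones((5, 2)) * -10]) + 0.1 * rng.standard_normal((15, 2))
        y = np.repeat(["A", "B", "C"], 5)
        est = train_model("LDA", X, y)
        rep = evaluate(est, X, y)
        assert rep.accuracy == rep.sensitivity == rep.specificity == 1.0
        assert all(v == 1.0 for v in rep.per_class_auc.values())

    def test_hand_computed_confusion_matrix(self):
        """Truth rows A,B,C with confusion [[8,2,0],[1,4,0],[1,1,18]]:
        accuracy 30/35, sensitivity_A 0.8 (hand arithmetic)."""
        y_true, y_pred = [], []
        conf = {("A", "A"): 8, ("A", "B"): 2, ("B", "A"): 1, ("B", "B"): 4,
                ("C", "A"): 1, ("C", "B"): 1, ("C", "C"): 18}
        for (t, p), n in conf.items():
            y_true += [t] * n
            y_pred += [p] * n

        class Fixed:
            def predict(self, X):
                return np.asarray(y_pred)

        rep = evaluate(Fixed(), np.zeros((35, 1)), np.asarray(y_true))
        assert rep.accuracy == pytest.approx(30 / 35)
        assert rep.per_class_sensitivity["A"] == pytest.approx(0.8)

    def test_always_predict_c(self):
        y_true = np.array(["A"] * 12 + ["B"] * 5 + ["C"] * 18)

        class AlwaysC:
            def predict(self, X):
                return np.full(len(X), "C")

        rep = evaluate(AlwaysC(), np.zeros((35, 1)), y_true)
        assert rep.accuracy == pytest.approx(18 / 35)
        assert rep.per_class_sensitivity["C"] == 1.0
        assert rep.per_class_specificity["C"] == 0.0

    def test_macro_consistency(self, ml_data):
        est = train_model("NB", ml_data["X"], ml_data["y"])
        rep = evaluate(est, ml_data["X"], ml_data["y"])
        assert rep.sensitivity == pytest.approx(
            np.mean(list(rep.per_class_sensitivity.values())))
        assert rep.specificity == pytest.approx(
            np.mean(list(rep.per_class_specificity.values())))
        for v in ([rep.accuracy, rep.sensitivity, rep.specificity]
                  + list(rep.per_class_auc.values())):
            assert 0.0 <= v <= 1.0
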
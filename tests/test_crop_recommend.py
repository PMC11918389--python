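"""Nearest-centroid recommendation, synthetic data and classifier scoring."""

import numpy as np
import pytest

from agriflow.crop_recommend import (
    REFERENCE_PROFILES,
    ClassReport,
    SoilSample,
    evaluate,
    generate_crop_dataset,
    nearest_centroid_predict,
    train_classifier,
)

# Field-validation samples with their published crop calls
VALIDATION_SAMPLES = [
    ("Barguna", SoilSample(22, 70, 37, 7.8, 190, 65, 197), "maize"),
    ("Tangail", SoilSample(22, 70, 52, 7.0, 125, 37, 132), "lentil"),
    ("Khulna", SoilSample(22, 70, 75, 7.4, 224, 189, 228), "jute"),
    ("Outdoor", SoilSample(31.8, 78, 62, 7.1, 147, 46, 154), "lentil"),
]


class TestNearestCentroid:
    @pytest.mark.parametrize("name,sample,expected", VALIDATION_SAMPLES,
                             ids=[v[0] for v in VALIDATION_SAMPLES])
    def test_reproduces_published_field_calls(self, name, sample, expected):
        assert nearest_centroid_predict(sample) == expected

    def test_sample_at_a_centroid_predicts_that_crop(self):
        maize = next(p for p in REFERENCE_PROFILES if p.crop == "maize")
        sample = SoilSample(temperature=maize.means["temperature"],
                            humidity=maize.means["humidity"], moisture=50.0,
                            ph=maize.means["ph"], n=maize.means["n"],
                            p=maize.means["p"], k=maize.means["k"])
        assert nearest_centroid_predict(sample) == "maize"

    def test_invalid_sample_rejected(self):
        with pytest.raises(ValueError):
            SoilSample(22, 70, 50, 15.2, 100, 50, 100)  # pH out of range

    def test_requires_two_profiles(self):
        with pytest.raises(ValueError):
            nearest_centroid_predict(VALIDATION_SAMPLES[0][1],
                                     profiles=REFERENCE_PROFILES[:1])


class TestSyntheticDataset:
    def test_balanced_and_seeded(self):
        df = generate_crop_dataset(n_per_class=30, seed=1)
        assert df["label"].value_counts().nunique() == 1
        assert len(df) == 30 * len(REFERENCE_PROFILES)
        df2 = generate_crop_dataset(n_per_class=30, seed=1)
        assert df.equals(df2)

    def test_values_respect_feature_ranges(self):
        df = generate_crop_dataset(n_per_class=200, seed=2, spread=0.3)
        assert df["ph"].between(0, 14).all()
        assert df["humidity"].between(0, 100).all()
        assert (df[["n", "p", "k"]] >= 0).all().all()

    def test_low_spread_samples_cluster_near_their_profile(self):
        df = generate_crop_dataset(n_per_class=50, seed=3, spread=0.01)
        for p in REFERENCE_PROFILES:
            sub = df[df["label"] == p.crop]
            assert sub["n"].mean() == pytest.approx(p.means["n"], rel=0.05)


class _FixedModel:
    """Stub classifier returning preset predictions (for metric oracles)."""

    def __init__(self, preds):
        self._preds = list(preds)
        self.feature_names_ = ("n", "p", "k")

    def predict(self, X):
        return np.asarray(self._preds[: len(X)])


def _frame(labels):
    import pandas as pd
    n = len(labels)
    return pd.DataFrame({"n": np.zeros(n), "p": np.zeros(n), "k": np.zeros(n),
                         "label": labels})


class TestEvaluation:
    def test_perfect_predictions(self):
        data = _frame(["a", "b", "c"])
        rep = evaluate(_FixedModel(["a", "b", "c"]), data)
        assert rep.accuracy == 1.0 and rep.f1_macro == 1.0

    def test_constant_predictor_on_balanced_classes(self):
        labels = [c for c in "abcde" for _ in range(4)]
        rep = evaluate(_FixedModel(["a"] * 20), _frame(labels))
        assert rep.accuracy == pytest.approx(0.2)

    def test_three_class_toy_matches_hand_tally(self):
        """Hand-computed confusion: A→(2 A, 1 B), B→(2 B), C→(1 C)."""
        truth = ["A", "A", "A", "B", "B", "C"]
        preds = ["A", "B", "A", "B", "B", "C"]
        rep = evaluate(_FixedModel(preds), _frame(truth))
        assert rep.accuracy == pytest.approx(5 / 6)
        assert rep.precision_macro == pytest.approx((1.0 + 2 / 3 + 1.0) / 3)
        assert rep.recall_macro == pytest.approx((2 / 3 + 1.0 + 1.0) / 3)
        assert rep.f1_macro == pytest.approx((0.8 + 0.8 + 1.0) / 3)
        assert rep.confusion.loc["A", "B"] == 1
        assert rep.confusion.loc["A"].sum() == 3  # row sums = class support

    def test_macro_f1_equals_harmonic_mean_formula(self, rng):
        classes = np.array(["x", "y", "z"])
        truth = classes[rng.integers(0, 3, 60)]
        preds = classes[rng.integers(0, 3, 60)]
        rep = evaluate(_FixedModel(preds), _frame(truth))
        f1s = []
        for c in classes:
            tp = np.sum((truth == c) & (preds == c))
            prec = tp / max(1, np.sum(preds == c))
            rec = tp / max(1, np.sum(truth == c))
            f1s.append(0.0 if prec + rec == 0 else 2 * prec * rec / (prec + rec))
        assert rep.f1_macro == pytest.approx(np.mean(f1s))

    def test_report_invariants_enforced(self):
        import pandas as pd
        with pytest.raises(ValueError):
            ClassReport(accuracy=0.9, precision_macro=0.5, recall_macro=0.5,
                        f1_macro=0.5,
                        confusion=pd.DataFrame([[1, 1], [1, 1]],
                                               index=list("ab"), columns=list("ab")))


class TestTrainedClassifier:
    def test_high_accuracy_on_low_spread_data(self):
        train = generate_crop_dataset(n_per_class=80, seed=0, spread=0.05)
        test = generate_crop_dataset(n_per_class=20, seed=99, spread=0.05)
        model = train_classifier(train, "tree_ensemble", seed=0)
        rep = evaluate(model, test)
        assert rep.accuracy >= 0.95

    @pytest.mark.parametrize("algorithm", ["nearest_centroid", "logistic"])
    def test_alternative_algorithms_learn_the_task(self, algorithm):
        train = generate_crop_dataset(n_per_class=60, seed=1, spread=0.03)
        test = generate_crop_dataset(n_per_class=15, seed=7, spread=0.03)
        model = train_classifier(train, algorithm, seed=1)
        assert evaluate(model, test).accuracy >= 0.9

    def test_unknown_algorithm_rejected(self):
        with pytest.raises(ValueError):
            train_classifier(generate_crop_dataset(n_per_class=5), "svm")
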
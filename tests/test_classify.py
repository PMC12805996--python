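"""Classifier training, evaluation protocols, and composition estimation."""

import numpy as np
import pandas as pd
import pytest

from ramanqa.classify import (
    ClassifierModel,
    RamanClassifier,
    estimate_composition,
    evaluate_batch_holdout,
    evaluate_split,
    predict_cells,
    sampling_depth_curve,
    train_classifier,
)
from ramanqa.simulate import make_species_cohort, simulate_cells
from ramanqa.spectra import Ramanome, SingleCellSpectrum, WavenumberAxis
from tests.conftest import combine


class TestTrain:
    def test_separable_species_perfect_training_accuracy(self, separable_pair):
        model = train_classifier(separable_pair, "LDA", seed=0)
        preds = predict_cells(model, separable_pair)
        truth = separable_pair.labels()
        assert (preds["label"].to_numpy() == np.asarray(truth)).all()
        assert set(model.manifest["n_per_class"].values()) == {200}

    def test_single_class_errors(self, separable_pair):
        idx = [i for i, lab in enumerate(separable_pair.labels()) if lab == "species1"]
        single = separable_pair.select_cells(idx)
        with pytest.raises(ValueError, match="2 classes"):
            train_classifier(single, "LDA")

    def test_unknown_algorithm_errors(self):
        with pytest.raises(ValueError, match="unknown algorithm"):
            RamanClassifier(algorithm="MLP").fit(np.zeros((4, 3)), ["a", "a", "b", "b"])

    @pytest.mark.parametrize("algorithm", ["RF", "SVM", "NBC", "KNN", "DT"])
    def test_all_algorithms_fit_and_predict(self, separable_pair, algorithm):
        model = train_classifier(
            separable_pair, algorithm, seed=1, rf_trees=50
        )
        preds = predict_cells(model, separable_pair)
        acc = np.mean(preds["label"].to_numpy() == np.asarray(separable_pair.labels()))
        assert acc > 0.9

    def test_model_round_trip(self, separable_pair, tmp_path):
        model = train_classifier(separable_pair, "LDA", seed=0)
        model.save(tmp_path / "model")
        loaded = ClassifierModel.load(tmp_path / "model")
        a = predict_cells(model, separable_pair)["label"]
        b = predict_cells(loaded, separable_pair)["label"]
        assert (a == b).all()
        assert loaded.manifest["algorithm"] == "LDA"


class TestEvaluateSplit:
    def test_per_repeat_length_and_confusion_sums(self, four_species_small):
        res = evaluate_split(four_species_small, "LDA", repeats=5, seed=2)
        assert len(res.per_repeat) == 5
        n_test = res.confusion.to_numpy().sum()
        # 30% of cells per repeat, 5 repeats, pooled
        assert n_test == 5 * round(0.3 * len(four_species_small))
        assert 0 <= res.accuracy_mean <= 100 and res.accuracy_sd >= 0

    def test_identical_spectra_two_classes_chance_level(self):
        axis = WavenumberAxis(np.arange(320.0, 4257.0, 8.0))
        rng = np.random.default_rng(0)
        template = np.exp(-0.5 * ((axis.values - 1000) / 30) ** 2)
        cells = tuple(
            SingleCellSpectrum(
                f"c{i}",
                template + rng.normal(0, 1e-9, axis.values.size),
                {"label": "A" if i < 100 else "B"},
            )
            for i in range(200)
        )
        res = evaluate_split(Ramanome(axis, cells), "KNN", repeats=5, seed=0)
        assert 35 <= res.accuracy_mean <= 65

    def test_permuted_labels_give_chance_accuracy(self, separable_pair):
        rng = np.random.default_rng(5)
        labels = rng.permutation(np.asarray(separable_pair.labels()))
        cells = tuple(
            SingleCellSpectrum(c.cell_id, c.intensities, {**c.meta, "label": lab})
            for c, lab in zip(separable_pair.cells, labels)
        )
        shuffled = Ramanome(separable_pair.axis, cells)
        res = evaluate_split(shuffled, "LDA", repeats=5, seed=0)
        # chance = 50% for 2 balanced classes; 99% binomial CI over pooled tests
        n_pooled = 5 * round(0.3 * len(shuffled))
        half_width = 100 * 2.58 * np.sqrt(0.25 / n_pooled)
        assert abs(res.accuracy_mean - 50.0) < half_width + 5

    def test_class_below_two_cells_errors(self, separable_pair):
        cells = separable_pair.cells[:1] + tuple(
            c for c in separable_pair.cells if c.meta["label"] == "species2"
        )
        r = Ramanome(separable_pair.axis, cells)
        with pytest.raises(ValueError):
            evaluate_split(r, "LDA")


class TestBatchHoldout:
    def test_no_batch_effect_matches_within_batch(self):
        cohort = make_species_cohort(2, seed=33)
        rams = []
        for b in range(2):
            for i, s in enumerate(cohort):
                rams.append(simulate_cells(s, 80, seed=70 + 10 * b + i, batch_id=f"b{b}"))
        r = combine(rams)
        from ramanqa.preprocess import preprocess_pipeline

        proc, _ = preprocess_pipeline(r, normalize=False)
        res = evaluate_batch_holdout(proc, "LDA", train_batches=1)
        within = evaluate_split(proc, "LDA", repeats=3, seed=0)
        assert abs(res.accuracy_mean - within.accuracy_mean) < 5

    def test_k_must_be_less_than_batches(self, four_species_small):
        with pytest.raises(ValueError):
            evaluate_batch_holdout(four_species_small, "LDA", train_batches=1)


class TestDepthCurve:
    def test_single_size_consistent_with_split(self, four_species_small):
        n_min = min(
            sum(1 for lab in four_species_small.labels() if lab == c)
            for c in set(four_species_small.labels())
        )
        curve = sampling_depth_curve(
            four_species_small, "LDA", sizes=[n_min], repeats=3, seed=0
        )
        assert len(curve) == 1 and curve[0][0] == n_min
        assert 0 <= curve[0][1] <= 100

    def test_oversized_request_errors(self, four_species_small):
        with pytest.raises(ValueError, match="needs >="):
            sampling_depth_curve(four_species_small, "LDA", sizes=[10**6])


class TestComposition:
    def test_equal_proportions_15_labels(self):
        preds = [f"strain{i}" for i in range(15) for _ in range(60)]
        comp = estimate_composition(preds)
        assert all(abs(p - 1 / 15) < 1e-12 for p in comp.proportions.values())
        assert sum(comp.counts.values()) == 900

    def test_single_label(self):
        comp = estimate_composition(["x"] * 10, labels=["x", "y"])
        assert comp.proportions == {"x": 1.0, "y": 0.0}

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            estimate_composition([])

    def test_recall_weighted_mixing_identity(self):
        """Composition after classification equals the confusion-matrix
        mixing of the true proportions, verified by brute-force counting."""
        rng = np.random.default_rng(11)
        labels = np.array(["A"] * 70 + ["B"] * 30)
        # imperfect classifier: flip A->B with p=.1, B->A with p=.2
        preds = labels.copy()
        flip_a = (labels == "A") & (rng.random(100) < 0.1)
        flip_b = (labels == "B") & (rng.random(100) < 0.2)
        preds[flip_a] = "B"
        preds[flip_b] = "A"
        comp = estimate_composition(preds, labels=["A", "B"])
        confusion = {
            (t, p): int(np.sum((labels == t) & (preds == p))) for t in "AB" for p in "AB"
        }
        expected_a = (confusion[("A", "A")] + confusion[("B", "A")]) / 100
        assert comp.proportions["A"] == pytest.approx(expected_a, abs=1e-12)


class TestClassifierOrdering:
    def test_lda_beats_naive_bayes_on_correlated_features(self):
        """Whole-cell intensity jitter correlates features; LDA models the
        shared covariance while NBC assumes independence, so LDA should win
        on most seeds."""
        wins = 0
        n_seeds = 20
        for seed in range(n_seeds):
            cohort = make_species_cohort(
                3, seed=400 + seed, separation="medium", noise_sd=0.08,
                cell_variability=0.35,
            )
            rams = [
                simulate_cells(s, 120, seed=500 + 10 * seed + i, include_baseline=False)
                for i, s in enumerate(cohort)
            ]
            r = combine(rams)
            lda = evaluate_split(r, "LDA", repeats=2, seed=seed)
            nbc = evaluate_split(r, "NBC", repeats=2, seed=seed)
            wins += lda.accuracy_mean >= nbc.accuracy_mean
        assert wins >= 16


class TestPredict:
    def test_empty_ramanome_empty_predictions(self, separable_pair):
        model = train_classifier(separable_pair, "LDA")
        empty = Ramanome(separable_pair.axis, ())
        assert predict_cells(model, empty).empty

    def test_incompatible_axis_errors(self, separable_pair):
        model = train_classifier(separable_pair, "LDA")
        coarse = WavenumberAxis(np.arange(320.0, 4257.0, 16.0))
        rng = np.random.default_rng(0)
        r = Ramanome(
            coarse,
            (SingleCellSpectrum("c", rng.uniform(0, 1, coarse.values.size)),),
        )
        with pytest.raises(ValueError, match="incompatible"):
            predict_cells(model, r)

    def test_unknown_species_gets_in_vocabulary_label(self, separable_pair):
        """Closed-world behavior: a species absent from the database is
        still assigned one of the trained labels."""
        model = train_classifier(separable_pair, "LDA")
        stranger_spec = make_species_cohort(3, seed=77)[2]
        stranger = simulate_cells(stranger_spec, 5, seed=1, include_baseline=False)
        preds = predict_cells(model, stranger)
        assert set(preds["label"]).issubset(set(model.labels))
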
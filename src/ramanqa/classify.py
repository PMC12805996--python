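"""Reference-database construction and per-cell species/strain identification.

Features are per-cell max-min-normalized intensities over the selected
wavenumber bands (fingerprint region by default).  Six classifier families
are supported: LDA (preceded by a PCA retaining 99% of variance, since LDA
on raw spectra is ill-posed when features approach sample count), RF, SVM,
NBC, KNN and DT.  Evaluation protocols: stratified 70/30 split repeated five
times, leave-batches-out cross-validation, and a sampling-depth curve.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedShuffleSplit
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from sklearn.utils.validation import check_is_fitted

from .preprocess import FINGERPRINT_BAND, BandDefinition, BandSelector, RowMinMaxScaler
from .spectra import Ramanome

__all__ = [
    "ALGORITHMS",
    "RamanClassifier",
    "ClassifierModel",
    "EvaluationResult",
    "CompositionEstimate",
    "train_classifier",
    "evaluate_split",
    "evaluate_batch_holdout",
    "sampling_depth_curve",
    "predict_cells",
    "estimate_composition",
]

ALGORITHMS = ("LDA", "RF", "SVM", "NBC", "KNN", "DT")


class RamanClassifier(BaseEstimator, ClassifierMixin):
    """Per-cell spectral classifier with a pluggable algorithm.

    Parameters follow scikit-learn conventions; defaults (KNN k=5, RF 500
    trees, RBF SVM, unlimited-depth DT, PCA to 99% variance before LDA) are
    config-exposed choices.  ``shrinkage_lda=True`` swaps the PCA+LDA route
    for shrinkage LDA with the Ledoit-Wolf estimator.
    """

    def __init__(
        self,
        algorithm: str = "LDA",
        pca_variance: float = 0.99,
        knn_k: int = 5,
        rf_trees: int = 500,
        shrinkage_lda: bool = False,
        random_state: int = 0,
    ):
        self.algorithm = algorithm
        self.pca_variance = pca_variance
        self.knn_k = knn_k
        self.rf_trees = rf_trees
        self.shrinkage_lda = shrinkage_lda
        self.random_state = random_state

    def _build(self) -> Pipeline:
        alg = self.algorithm.upper()
        if alg == "LDA":
            if self.shrinkage_lda:
                steps = [("lda", LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto"))]
            else:
                steps = [
                    ("pca", PCA(n_components=self.pca_variance, svd_solver="full",
                                random_state=self.random_state)),
                    ("lda", LinearDiscriminantAnalysis()),
                ]
        elif alg == "RF":
            steps = [("rf", RandomForestClassifier(n_estimators=self.rf_trees,
                                                   random_state=self.random_state))]
        elif alg == "SVM":
            steps = [("svm", SVC(kernel="rbf", random_state=self.random_state))]
        elif alg == "NBC":
            steps = [("nbc", GaussianNB())]
        elif alg == "KNN":
            steps = [("knn", KNeighborsClassifier(n_neighbors=self.knn_k))]
        elif alg == "DT":
            steps = [("dt", DecisionTreeClassifier(random_state=self.random_state))]
        else:
            raise ValueError(f"unknown algorithm {self.algorithm!r}; choose from {ALGORITHMS}")
        return Pipeline(steps)

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        classes, counts = np.unique(y, return_counts=True)
        if classes.size < 2:
            raise ValueError("need at least 2 classes")
        if counts.min() < 2:
            raise ValueError("every class needs at least 2 training cells")
        self.pipeline_ = self._build().fit(X, y)
        self.classes_ = self.pipeline_.classes_
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self, "pipeline_")
        X = np.asarray(X, dtype=float)
        if X.shape[0] == 0:
            return np.array([], dtype=self.classes_.dtype)
        return self.pipeline_.predict(X)

    def predict_score(self, X):
        """Confidence of the predicted label (posterior where available,
        otherwise the winning decision value)."""
        check_is_fitted(self, "pipeline_")
        X = np.asarray(X, dtype=float)
        if X.shape[0] == 0:
            return np.array([])
        clf = self.pipeline_
        if hasattr(clf, "predict_proba"):
            try:
                return clf.predict_proba(X).max(axis=1)
            except AttributeError:
                pass
        scores = clf.decision_function(X)
        return scores if scores.ndim == 1 else scores.max(axis=1)


@dataclass
class ClassifierModel:
    """Fitted per-cell label predictor plus its training manifest."""

    estimator: RamanClassifier
    labels: tuple
    feature_bands: tuple
    feature_wavenumbers: np.ndarray
    manifest: dict = field(default_factory=dict)

    def save(self, directory) -> Path:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        manifest = dict(self.manifest)
        manifest.update(
            {
                "format_version": 1,
                "labels": list(self.labels),
                "feature_bands": [(b.name, b.lo, b.hi) for b in self.feature_bands],
            }
        )
        (directory / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        np.savetxt(directory / "feature_wavenumbers.txt", self.feature_wavenumbers)
        joblib.dump(self.estimator, directory / "estimator.joblib")
        return directory

    @classmethod
    def load(cls, directory) -> "ClassifierModel":
        directory = Path(directory)
        manifest = json.loads((directory / "manifest.json").read_text())
        bands = tuple(BandDefinition(n, lo, hi) for n, lo, hi in manifest.pop("feature_bands"))
        labels = tuple(manifest.pop("labels"))
        manifest.pop("format_version", None)
        return cls(
            estimator=joblib.load(directory / "estimator.joblib"),
            labels=labels,
            feature_bands=bands,
            feature_wavenumbers=np.loadtxt(directory / "feature_wavenumbers.txt"),
            manifest=manifest,
        )


@dataclass
class EvaluationResult:
    """Accuracy mean/SD over repeats (in %) plus the pooled confusion matrix."""

    accuracy_mean: float
    accuracy_sd: float
    repeats: int
    confusion: pd.DataFrame
    per_repeat: list
    macro_accuracy_mean: float = float("nan")


@dataclass
class CompositionEstimate:
    """Predicted label counts and proportions from per-cell classification."""

    counts: dict
    proportions: dict

    def __post_init__(self) -> None:
        total = sum(self.counts.values())
        if total <= 0:
            raise ValueError("empty prediction set")
        assert abs(sum(self.proportions.values()) - 1.0) < 1e-12


def _features(ramanome: Ramanome, bands: Sequence[BandDefinition]):
    """Band-select then per-cell max-min normalize; returns (X, wavenumbers)."""
    selector = BandSelector(ramanome.axis.values, list(bands)).fit(None)
    X = selector.transform(ramanome.to_matrix())
    X = RowMinMaxScaler().fit(X).transform(X)
    return X, selector.selected_wavenumbers_


def _labels(ramanome: Ramanome) -> np.ndarray:
    y = np.asarray(ramanome.labels(), dtype=object)
    if any(v is None for v in y):
        raise ValueError("ramanome has unlabeled cells")
    return y.astype(str)


def train_classifier(
    ramanome: Ramanome,
    algorithm: str = "LDA",
    seed: int = 0,
    feature_bands: Sequence[BandDefinition] = (FINGERPRINT_BAND,),
    **estimator_params,
) -> ClassifierModel:
    """Fit a reference-database classifier on a labeled, preprocessed ramanome."""
    X, wavenumbers = _features(ramanome, feature_bands)
    y = _labels(ramanome)
    est = RamanClassifier(algorithm=algorithm, random_state=seed, **estimator_params).fit(X, y)
    classes, counts = np.unique(y, return_counts=True)
    manifest = {
        "algorithm": algorithm,
        "n_per_class": {c: int(n) for c, n in zip(classes, counts)},
        "batches_used": ramanome.batches(),
        "feature_bands": [(b.name, b.lo, b.hi) for b in feature_bands],
        "seed": int(seed),
        "split_fraction": None,
    }
    return ClassifierModel(est, tuple(classes), tuple(feature_bands), wavenumbers, manifest)


def _evaluate_arrays(X, y, algorithm, train_fraction, repeats, seed, **estimator_params):
    labels = np.unique(y)
    splitter = StratifiedShuffleSplit(
        n_splits=repeats, train_size=train_fraction, random_state=seed
    )
    accs, macro_accs = [], []
    confusion = pd.DataFrame(0, index=labels, columns=labels, dtype=int)
    for train_idx, test_idx in splitter.split(X, y):
        est = RamanClassifier(algorithm=algorithm, random_state=seed, **estimator_params)
        est.fit(X[train_idx], y[train_idx])
        pred = est.predict(X[test_idx])
        truth = y[test_idx]
        accs.append(100.0 * float(np.mean(pred == truth)))
        per_class = [100.0 * float(np.mean(pred[truth == c] == c)) for c in labels]
        macro_accs.append(float(np.mean(per_class)))
        for t, p in zip(truth, pred):
            confusion.loc[t, p] += 1
    return EvaluationResult(
        accuracy_mean=float(np.mean(accs)),
        accuracy_sd=float(np.std(accs, ddof=1)) if repeats > 1 else 0.0,
        repeats=repeats,
        confusion=confusion,
        per_repeat=accs,
        macro_accuracy_mean=float(np.mean(macro_accs)),
    )


def evaluate_split(
    ramanome: Ramanome,
    algorithm: str = "LDA",
    train_fraction: float = 0.7,
    repeats: int = 5,
    seed: int = 0,
    feature_bands: Sequence[BandDefinition] = (FINGERPRINT_BAND,),
    **estimator_params,
) -> EvaluationResult:
    """Stratified 70/30 split repeated ``repeats`` times; accuracy in %."""
    X, _ = _features(ramanome, feature_bands)
    y = _labels(ramanome)
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < 2:
        raise ValueError("every class needs at least 2 cells for a stratified split")
    return _evaluate_arrays(X, y, algorithm, train_fraction, repeats, seed, **estimator_params)


def evaluate_batch_holdout(
    ramanome: Ramanome,
    algorithm: str = "LDA",
    train_batches: int = 2,
    seed: int = 0,
    feature_bands: Sequence[BandDefinition] = (FINGERPRINT_BAND,),
    **estimator_params,
) -> EvaluationResult:
    """Train on every choice of k batches, test on each held-out batch."""
    batches = ramanome.batches()
    if len(batches) < 2:
        raise ValueError("need at least 2 batches")
    if train_batches >= len(batches):
        raise ValueError("train_batches must be < number of batches")
    X, _ = _features(ramanome, feature_bands)
    y = _labels(ramanome)
    batch_ids = np.asarray(ramanome.meta_values("batch_id"), dtype=object)
    labels = np.unique(y)
    accs = []
    confusion = pd.DataFrame(0, index=labels, columns=labels, dtype=int)
    for train_set in combinations(batches, train_batches):
        train_mask = np.isin(batch_ids, train_set)
        est = RamanClassifier(algorithm=algorithm, random_state=seed, **estimator_params)
        est.fit(X[train_mask], y[train_mask])
        for held_out in (b for b in batches if b not in train_set):
            test_mask = batch_ids == held_out
            pred = est.predict(X[test_mask])
            truth = y[test_mask]
            accs.append(100.0 * float(np.mean(pred == truth)))
            for t, p in zip(truth, pred):
                confusion.loc[t, p] += 1
    return EvaluationResult(
        accuracy_mean=float(np.mean(accs)),
        accuracy_sd=float(np.std(accs, ddof=1)) if len(accs) > 1 else 0.0,
        repeats=len(accs),
        confusion=confusion,
        per_repeat=accs,
    )


def sampling_depth_curve(
    ramanome: Ramanome,
    algorithm: str = "LDA",
    sizes: Sequence[int] = (500, 600, 1000, 1500, 3000),
    repeats: int = 5,
    seed: int = 0,
    feature_bands: Sequence[BandDefinition] = (FINGERPRINT_BAND,),
    **estimator_params,
) -> list:
    """Accuracy mean/SD per per-class subsample size.

    For each size, ``size`` cells are drawn per class (seeded) and the 70/30
    split evaluation is run on the subsample.
    """
    X, _ = _features(ramanome, feature_bands)
    y = _labels(ramanome)
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < max(sizes):
        raise ValueError(
            f"each class needs >= {max(sizes)} cells; smallest has {counts.min()}"
        )
    rng = np.random.default_rng(seed)
    curve = []
    for size in sizes:
        idx = np.concatenate(
            [rng.choice(np.where(y == c)[0], size=size, replace=False) for c in classes]
        )
        result = _evaluate_arrays(
            X[idx], y[idx], algorithm, 0.7, repeats, int(rng.integers(2**31)),
            **estimator_params,
        )
        curve.append((int(size), result.accuracy_mean, result.accuracy_sd))
    return curve


def predict_cells(model: ClassifierModel, ramanome: Ramanome) -> pd.DataFrame:
    """Per-cell label and score for a preprocessed ramanome.

    Prediction is closed-world: a cell from a species absent from the
    reference database is still assigned some in-vocabulary label.
    """
    if len(ramanome) == 0:
        return pd.DataFrame(columns=["cell_id", "label", "score"])
    X, wavenumbers = _features(ramanome, model.feature_bands)
    if wavenumbers.size != model.feature_wavenumbers.size or not np.allclose(
        wavenumbers, model.feature_wavenumbers
    ):
        raise ValueError("ramanome axis is incompatible with the model's features")
    return pd.DataFrame(
        {
            "cell_id": ramanome.cell_ids(),
            "label": model.estimator.predict(X),
            "score": model.estimator.predict_score(X),
        }
    )


def estimate_composition(predictions, labels: Sequence[str] | None = None) -> CompositionEstimate:
    """Label counts and proportions from per-cell predictions.

    ``predictions`` is a sequence of labels or a DataFrame with a ``label``
    column; ``labels`` optionally fixes the label vocabulary (zero-count
    labels included).
    """
    if isinstance(predictions, pd.DataFrame):
        pred = predictions["label"].to_numpy()
    else:
        pred = np.asarray(list(predictions), dtype=object)
    if pred.size == 0:
        raise ValueError("empty prediction set")
    vocab = list(labels) if labels is not None else sorted(set(map(str, pred)))
    counts = {lab: int(np.sum(pred == lab)) for lab in vocab}
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no prediction matches the given label vocabulary")
    proportions = {lab: counts[lab] / total for lab in vocab}
    return CompositionEstimate(counts, proportions)
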
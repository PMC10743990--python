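"""Classifier training, hyperparameter grids, evaluation metrics, and
y-randomization.

Four algorithm families (RF, SVM, KNN, MLP) are tuned over fixed default
grids by 5-fold cross-validated accuracy, then validated by repeated
stratified 70/30 Monte-Carlo splits.  Every trained model exposes a
probability score PS in [0, 1] for the active class; PS >= 0.5 is the
model's active call.  The SVM supports a Tanimoto kernel
K(x, y) = |x & y| / |x | y| on binary fingerprints, with probability
scores from internal cross-validated sigmoid calibration.

Splits are made on a canonical row order (sorted by structure key), so
grid search results are invariant to the row order of the input dataset.
"""

from __future__ import annotations

import datetime
import hashlib
import warnings
from dataclasses import dataclass, field
from itertools import product
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.exceptions import ConvergenceWarning
from sklearn.model_selection import StratifiedKFold, StratifiedShuffleSplit
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .curation import ACTIVE, LabeledDataset
from .representations import FeatureMatrix, featurize, tanimoto_matrix

ALGORITHMS = ("RF", "SVM", "KNN", "MLP")

MLP_MAX_ITER = 1000


class ModelingError(ValueError):
    pass


@dataclass
class HyperparameterGrid:
    algorithm: str
    grid: dict[str, list]

    def combinations(self) -> list[dict]:
        """All grid points in deterministic (insertion-order) enumeration."""
        names = list(self.grid)
        return [dict(zip(names, vals)) for vals in product(*(self.grid[n] for n in names))]


def default_grid(algorithm: str) -> HyperparameterGrid:
    """The default tuning grid for each algorithm family."""
    if algorithm == "RF":
        grid = {"max_features": ["sqrt", "log2", None], "n_estimators": [100, 500]}
    elif algorithm == "SVM":
        grid = {"C": [0.01, 0.1, 1, 10, 100], "kernel": ["linear", "tanimoto"]}
    elif algorithm == "KNN":
        grid = {"n_neighbors": list(range(1, 31)), "weight": ["uniform", "distance"]}
    elif algorithm == "MLP":
        grid = {
            "hidden_layer_size": [(50, 50, 50), (50, 100, 50), (100,)],
            "solver": ["lbfgs", "adam", "sgd"],
            "activation": ["identity", "logistic", "tanh", "relu"],
            "learning_rate_init": [0.01, 0.001, 0.0001, 0.00001],
        }
    else:
        raise ModelingError(f"unknown algorithm {algorithm!r}")
    return HyperparameterGrid(algorithm=algorithm, grid=grid)


@dataclass(frozen=True)
class ModelSpec:
    algorithm: str
    representation: str
    hyperparameters: tuple  # sorted (name, value) pairs for hashability
    seed: int = 0

    @classmethod
    def create(cls, algorithm, representation, hyperparameters: dict, seed: int = 0):
        hp = tuple(sorted(hyperparameters.items()))
        return cls(algorithm, representation, hp, seed)

    @property
    def params(self) -> dict:
        return dict(self.hyperparameters)

    @property
    def name(self) -> str:
        return f"{self.algorithm}-{self.representation}"


class TanimotoKernelSVC(BaseEstimator, ClassifierMixin):
    """SVC with a precomputed Tanimoto kernel over binary fingerprints.

    Probability scores come from sklearn's internal cross-validated sigmoid
    (Platt) calibration.  Kernel conventions: K = 1 for two all-zero vectors,
    0 between a zero and a nonzero vector.
    """

    def __init__(self, C: float = 1.0, random_state: int = 0):
        self.C = C
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X)
        if not np.isin(X, (0, 1)).all():
            raise ModelingError("Tanimoto kernel requires a binary representation")
        self.X_train_ = X
        K = tanimoto_matrix(X, X)
        self.svc_ = SVC(
            C=self.C, kernel="precomputed", probability=True,
            random_state=self.random_state,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", FutureWarning)
            self.svc_.fit(K, y)
        self.classes_ = self.svc_.classes_
        return self

    def predict_proba(self, X):
        K = tanimoto_matrix(np.asarray(X), self.X_train_)
        return self.svc_.predict_proba(K)

    def predict(self, X):
        p = self.predict_proba(X)[:, list(self.classes_).index(1)]
        return np.where(p >= 0.5, 1, 0)


def build_estimator(spec: ModelSpec):
    """Instantiate the sklearn estimator for a model spec (unfitted)."""
    p = spec.params
    seed = spec.seed
    if spec.algorithm == "RF":
        est = RandomForestClassifier(
            max_features=p.get("max_features", "sqrt"),
            n_estimators=p.get("n_estimators", 100),
            random_state=seed,
        )
    elif spec.algorithm == "SVM":
        kernel = p.get("kernel", "linear")
        if kernel == "tanimoto":
            if spec.representation == "descriptors":
                raise ModelingError(
                    "tanimoto kernel requires a binary representation"
                )
            est = TanimotoKernelSVC(C=p.get("C", 1.0), random_state=seed)
        else:
            est = SVC(
                C=p.get("C", 1.0), kernel=kernel, probability=True,
                random_state=seed,
            )
    elif spec.algorithm == "KNN":
        est = KNeighborsClassifier(
            n_neighbors=p.get("n_neighbors", 5),
            weights=p.get("weight", "uniform"),
            metric=p.get("metric", "euclidean"),
        )
    elif spec.algorithm == "MLP":
        est = MLPClassifier(
            hidden_layer_sizes=tuple(p.get("hidden_layer_size", (100,))),
            solver=p.get("solver", "adam"),
            activation=p.get("activation", "relu"),
            learning_rate_init=p.get("learning_rate_init", 0.001),
            max_iter=p.get("max_iter", MLP_MAX_ITER),
            random_state=seed,
        )
    else:
        raise ModelingError(f"unknown algorithm {spec.algorithm!r}")
    if spec.representation == "descriptors":
        if isinstance(est, TanimotoKernelSVC):  # pragma: no cover - guarded above
            raise ModelingError("tanimoto kernel requires a binary representation")
        est = Pipeline([("scale", StandardScaler()), ("clf", est)])
    return est


# --- labels and metrics ----------------------------------------------------


def _as_binary(labels: Sequence) -> np.ndarray:
    """Map labels to {1 = active/positive, 0 = inactive/negative}."""
    out = np.empty(len(labels), dtype=np.int64)
    for i, lab in enumerate(labels):
        if isinstance(lab, str):
            out[i] = 1 if lab == ACTIVE else 0
        else:
            out[i] = 1 if lab else 0
    return out


@dataclass(frozen=True)
class EvaluationReport:
    tp: int
    tn: int
    fp: int
    fn: int
    accuracy: float
    precision: float
    recall: float

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def evaluate(predicted_labels: Sequence, true_labels: Sequence) -> EvaluationReport:
    """Confusion-matrix metrics with active as the positive class.

    precision = TP/(TP+FP), recall = TP/(TP+FN),
    accuracy = (TP+TN)/(TP+TN+FP+FN); an empty denominator yields 0 with a
    warning.
    """
    if len(predicted_labels) != len(true_labels):
        raise ModelingError("predicted and true label lengths differ")
    pred = _as_binary(predicted_labels)
    true = _as_binary(true_labels)
    tp = int(np.sum((pred == 1) & (true == 1)))
    tn = int(np.sum((pred == 0) & (true == 0)))
    fp = int(np.sum((pred == 1) & (true == 0)))
    fn = int(np.sum((pred == 0) & (true == 1)))
    n = tp + tn + fp + fn
    accuracy = (tp + tn) / n if n else 0.0
    if tp + fp:
        precision = tp / (tp + fp)
    else:
        warnings.warn("no positive predictions; precision set to 0")
        precision = 0.0
    if tp + fn:
        recall = tp / (tp + fn)
    else:
        warnings.warn("no positive instances; recall set to 0")
        recall = 0.0
    return EvaluationReport(tp, tn, fp, fn, accuracy, precision, recall)


@dataclass
class CVResult:
    reports: list[EvaluationReport] = field(default_factory=list)

    @property
    def accuracies(self) -> np.ndarray:
        return np.array([r.accuracy for r in self.reports])

    @property
    def mean_accuracy(self) -> float:
        return float(self.accuracies.mean())

    @property
    def sd_accuracy(self) -> float:
        return float(self.accuracies.std(ddof=1)) if len(self.reports) > 1 else 0.0

    def mean(self, metric: str) -> float:
        return float(np.mean([getattr(r, metric) for r in self.reports]))


# --- dataset plumbing ------------------------------------------------------


def dataset_checksum(dataset: LabeledDataset) -> str:
    h = hashlib.sha256()
    for key, lab in sorted(
        (c.compound.structure_key, c.label) for c in dataset.compounds
    ):
        h.update(f"{key}:{lab};".encode())
    return h.hexdigest()


def _canonical_order(dataset: LabeledDataset) -> np.ndarray:
    keys = [c.compound.structure_key for c in dataset.compounds]
    return np.argsort(np.array(keys, dtype=object), kind="stable")


def features_for(dataset: LabeledDataset, kind: str) -> np.ndarray:
    return featurize(
        [c.compound for c in dataset.compounds], kind
    ).data.astype(np.float64)


def _resolve_features(dataset, kind, features) -> np.ndarray:
    if features is None:
        return features_for(dataset, kind)
    if isinstance(features, FeatureMatrix):
        features = features.data
    X = np.asarray(features, dtype=np.float64)
    if X.shape[0] != len(dataset):
        raise ModelingError("feature matrix rows do not match dataset size")
    return X


def _check_two_classes(y: np.ndarray) -> None:
    if len(np.unique(y)) < 2:
        raise ModelingError("dataset must contain both classes")


# --- trained model ---------------------------------------------------------


@dataclass
class TrainedClassifier:
    """A fitted (algorithm, representation, hyperparameters) model.

    ``predict_ps`` emits the probability score of the active class;
    ``predict_labels`` thresholds PS at 0.5 (the model's label output).
    """

    spec: ModelSpec
    estimator: object
    manifest: dict

    def predict_ps(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        proba = self.estimator.predict_proba(X)
        classes = list(
            self.estimator.classes_
            if not isinstance(self.estimator, Pipeline)
            else self.estimator[-1].classes_
        )
        ps = proba[:, classes.index(1)]
        return np.clip(ps, 0.0, 1.0)

    def predict_labels(self, X) -> np.ndarray:
        return (self.predict_ps(X) >= 0.5).astype(int)


def train(spec: ModelSpec, dataset: LabeledDataset, features=None) -> TrainedClassifier:
    """Fit a classifier on the full dataset."""
    X = _resolve_features(dataset, spec.representation, features)
    y = _as_binary(dataset.labels)
    _check_two_classes(y)
    est = build_estimator(spec)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", FutureWarning)
        est.fit(X, y)
    manifest = {
        "spec": {
            "algorithm": spec.algorithm,
            "representation": spec.representation,
            "hyperparameters": spec.params,
            "seed": spec.seed,
        },
        "dataset_checksum": dataset_checksum(dataset),
        "n_train": len(dataset),
        "date": datetime.date.today().isoformat(),
    }
    return TrainedClassifier(spec=spec, estimator=est, manifest=manifest)


# --- model selection -------------------------------------------------------


@dataclass
class GridSearchResult:
    best_params: dict
    table: "object"  # pandas.DataFrame ranked by mean accuracy


def grid_search(
    dataset: LabeledDataset,
    algorithm: str,
    kind: str,
    grid: HyperparameterGrid | None = None,
    seed: int = 0,
    features=None,
    n_folds: int = 5,
) -> GridSearchResult:
    """Select hyperparameters by stratified k-fold cross-validated accuracy.

    Every grid point is scored; the argmax wins, with ties broken by
    deterministic grid enumeration order (first wins).
    """
    import pandas as pd

    if grid is None:
        grid = default_grid(algorithm)
    combos = grid.combinations()
    if not combos:
        raise ModelingError("empty hyperparameter grid")
    X = _resolve_features(dataset, kind, features)
    y = _as_binary(dataset.labels)
    _check_two_classes(y)
    order = _canonical_order(dataset)
    X, y = X[order], y[order]

    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    splits = list(skf.split(X, y))
    rows = []
    best_params, best_acc = None, -np.inf
    for params in combos:
        spec = ModelSpec.create(algorithm, kind, params, seed=seed)
        accs = []
        for tr, te in splits:
            est = build_estimator(spec)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                warnings.simplefilter("ignore", FutureWarning)
                warnings.simplefilter("ignore", UserWarning)
                est.fit(X[tr], y[tr])
                pred = (np.asarray(est.predict_proba(X[te]))[:, 1] >= 0.5).astype(int)
                accs.append(evaluate(pred, y[te]).accuracy)
        mean_acc = float(np.mean(accs))
        rows.append({**{k: str(v) for k, v in params.items()},
                     "mean_accuracy": mean_acc, "sd_accuracy": float(np.std(accs))})
        if mean_acc > best_acc:
            best_acc, best_params = mean_acc, params
    table = pd.DataFrame(rows).sort_values(
        "mean_accuracy", ascending=False, kind="stable"
    ).reset_index(drop=True)
    return GridSearchResult(best_params=best_params, table=table)


def repeated_split_cv(
    spec: ModelSpec,
    dataset: LabeledDataset,
    n_repeats: int = 10,
    train_frac: float = 0.7,
    seed: int = 0,
    features=None,
) -> CVResult:
    """Monte-Carlo validation: n stratified random train/test splits.

    Each repeat fits on ``train_frac`` of the data and evaluates on the rest.
    """
    if n_repeats < 1:
        raise ModelingError("n_repeats must be >= 1")
    X = _resolve_features(dataset, spec.representation, features)
    y = _as_binary(dataset.labels)
    _check_two_classes(y)
    order = _canonical_order(dataset)
    X, y = X[order], y[order]
    sss = StratifiedShuffleSplit(
        n_splits=n_repeats, train_size=train_frac, random_state=seed
    )
    result = CVResult()
    for tr, te in sss.split(X, y):
        est = build_estimator(spec)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            warnings.simplefilter("ignore", FutureWarning)
            est.fit(X[tr], y[tr])
            pred = (np.asarray(est.predict_proba(X[te]))[:, 1] >= 0.5).astype(int)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            result.reports.append(evaluate(pred, y[te]))
    return result


def y_randomization(
    spec: ModelSpec,
    dataset: LabeledDataset,
    n_repeats: int = 10,
    seed: int = 0,
    features=None,
    train_frac: float = 0.7,
    n_splits_per_repeat: int = 1,
) -> list[float]:
    """Label-permutation control: refit under shuffled labels.

    Per repeat the labels are permuted with a seeded RNG, the model is refit
    with the spec's hyperparameters, and accuracy is measured on stratified
    held-out splits of the permuted data.  Informative models collapse to
    chance-level accuracy (~0.5 on balanced data).
    """
    if n_repeats < 1:
        raise ModelingError("n_repeats must be >= 1")
    X = _resolve_features(dataset, spec.representation, features)
    y = _as_binary(dataset.labels)
    _check_two_classes(y)
    order = _canonical_order(dataset)
    X, y = X[order], y[order]
    rng = np.random.default_rng(seed)
    accuracies = []
    for rep in range(n_repeats):
        y_perm = rng.permutation(y)
        split_seed = int(rng.integers(0, 2**31 - 1))
        sss = StratifiedShuffleSplit(
            n_splits=n_splits_per_repeat, train_size=train_frac,
            random_state=split_seed,
        )
        accs = []
        for tr, te in sss.split(X, y_perm):
            est = build_estimator(spec)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                warnings.simplefilter("ignore", FutureWarning)
                est.fit(X[tr], y_perm[tr])
                pred = (np.asarray(est.predict_proba(X[te]))[:, 1] >= 0.5).astype(int)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", UserWarning)
                accs.append(evaluate(pred, y_perm[te]).accuracy)
        accuracies.append(float(np.mean(accs)))
    return accuracies
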
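"""Classifier protocol: sample-level split, SMOTE, the 12-model registry,
sample-level cross-validation and spectrum-level evaluation.

The split is stratified by outcome group at the *sample* level (all
replicate spectra of one embryo's medium land on one side), so replicate
correlation can never leak between training and prediction. SMOTE then
balances the training *spectra*. Nine traditional families are tuned with
stratified sample-level 5-fold CV over deliberately small grids; the three
deep families (MLP, ANN, GRU) use a held-out validation split for early
stopping instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.discriminant_analysis import (LinearDiscriminantAnalysis,
                                           QuadraticDiscriminantAnalysis)
from sklearn.ensemble import HistGradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier, NearestNeighbors
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

from .datatypes import GROUPS, SampleRecord
from .gru import GRUClassifier

DEEP_MODELS = ("MLP", "ANN", "GRU")
TRADITIONAL_MODELS = ("GB", "KNN", "RF", "LSVM", "LDA", "LR", "QDA", "RSVM", "NB")
ALL_MODELS = DEEP_MODELS + TRADITIONAL_MODELS


# ------------------------------------------------------------------- split

@dataclass
class SplitPlan:
    """Per-group sample-level partition into training and prediction ids."""

    train_ids: dict[str, list[str]]
    predict_ids: dict[str, list[str]]
    fraction: float
    seed: int

    @property
    def all_train(self) -> list[str]:
        return [i for g in GROUPS for i in self.train_ids.get(g, [])]

    @property
    def all_predict(self) -> list[str]:
        return [i for g in GROUPS for i in self.predict_ids.get(g, [])]


def split_dataset(samples: list[SampleRecord], fraction: float = 0.8,
                  seed: int = 0) -> SplitPlan:
    """Per group, floor(fraction * n) samples to training, rest to prediction.

    With the reference cohort (58/25/89) at 0.8 this gives 137 training and
    35 prediction samples.
    """
    if not (0.0 < fraction < 1.0):
        raise ValueError("fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    by_group: dict[str, list[str]] = {g: [] for g in GROUPS}
    for rec in samples:
        by_group[rec.group].append(rec.sample_id)
    train_ids, predict_ids = {}, {}
    for g in GROUPS:
        ids = sorted(by_group[g])
        if not ids:
            raise ValueError(f"group {g} is empty")
        n_train = int(np.floor(fraction * len(ids)))
        if n_train == 0 or n_train == len(ids):
            raise ValueError(
                f"group {g}: split {fraction:g} of {len(ids)} samples leaves an "
                "empty training or prediction side"
            )
        perm = rng.permutation(len(ids))
        train_ids[g] = [ids[i] for i in sorted(perm[:n_train])]
        predict_ids[g] = [ids[i] for i in sorted(perm[n_train:])]
    return SplitPlan(train_ids, predict_ids, fraction, seed)


def apply_split(samples: list[SampleRecord], plan: SplitPlan
                ) -> tuple[list[SampleRecord], list[SampleRecord]]:
    train_set = set(plan.all_train)
    predict_set = set(plan.all_predict)
    train = [r for r in samples if r.sample_id in train_set]
    predict = [r for r in samples if r.sample_id in predict_set]
    return train, predict


# ------------------------------------------------------------------- SMOTE

def smote_oversample(X: np.ndarray, y: np.ndarray, k_neighbors: int = 5,
                     seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Synthetic minority oversampling to the majority class count.

    Each synthetic row is a convex combination of a minority row and one
    of its ``k_neighbors`` nearest same-class neighbours; original rows
    are preserved verbatim (and come first in the output).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    rng = np.random.default_rng(seed)
    classes, counts = np.unique(y, return_counts=True)
    n_max = counts.max()
    X_new, y_new = [X], [y]
    for c, n_c in zip(classes, counts):
        need = n_max - n_c
        if need == 0:
            continue
        if n_c <= k_neighbors:
            raise ValueError(
                f"class {c!r} has {n_c} members, not enough for k_neighbors="
                f"{k_neighbors}; use a smaller k"
            )
        Xc = X[y == c]
        nn = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(Xc)
        _, idx = nn.kneighbors(Xc)  # first neighbour is the point itself
        base = rng.integers(0, n_c, size=need)
        nbr_choice = rng.integers(1, k_neighbors + 1, size=need)
        gaps = rng.random(need)
        parents = idx[base, nbr_choice]
        synth = Xc[base] + gaps[:, None] * (Xc[parents] - Xc[base])
        X_new.append(synth)
        y_new.append(np.full(need, c, dtype=y.dtype))
    return np.vstack(X_new), np.concatenate(y_new)


# ---------------------------------------------------------------- registry

class ReducedSVC(BaseEstimator, ClassifierMixin):
    """RBF-kernel SVM trained on a random stratified subset of candidate
    support vectors (reduced-set SVM)."""

    def __init__(self, fraction: float = 0.1, C: float = 1.0,
                 gamma: str | float = "scale", random_state: int = 0):
        self.fraction = fraction
        self.C = C
        self.gamma = gamma
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X)
        y = np.asarray(y)
        rng = np.random.default_rng(self.random_state)
        keep = []
        for c in np.unique(y):
            idx = np.flatnonzero(y == c)
            n_keep = max(2, int(round(self.fraction * len(idx))))
            keep.extend(rng.choice(idx, size=min(n_keep, len(idx)), replace=False))
        keep = np.sort(np.asarray(keep))
        self.svc_ = SVC(kernel="rbf", C=self.C, gamma=self.gamma,
                        probability=True, random_state=self.random_state)
        self.svc_.fit(X[keep], y[keep])
        self.classes_ = self.svc_.classes_
        return self

    def predict(self, X):
        return self.svc_.predict(X)

    def predict_proba(self, X):
        return self.svc_.predict_proba(X)


def _registry(seed: int) -> dict:
    """Default estimator per family. MLP/ANN differ only in depth."""
    return {
        "MLP": MLPClassifier(hidden_layer_sizes=(128, 64), early_stopping=True,
                             validation_fraction=0.15, max_iter=400,
                             random_state=seed),
        "ANN": MLPClassifier(hidden_layer_sizes=(64,), early_stopping=True,
                             validation_fraction=0.15, max_iter=400,
                             random_state=seed),
        "GRU": GRUClassifier(random_state=seed),
        "GB": HistGradientBoostingClassifier(random_state=seed),
        "KNN": KNeighborsClassifier(n_neighbors=5),
        "RF": RandomForestClassifier(n_estimators=200, random_state=seed),
        "LSVM": SVC(kernel="linear", probability=True, random_state=seed),
        "LDA": LinearDiscriminantAnalysis(),
        "LR": LogisticRegression(max_iter=2000),
        # eigen solver + shrinkage: per-class covariances are rank-deficient
        # whenever features outnumber class spectra
        "QDA": QuadraticDiscriminantAnalysis(solver="eigen", shrinkage=0.5),
        "RSVM": ReducedSVC(random_state=seed),
        "NB": GaussianNB(),
    }


#: small hyperparameter grids for the traditional families (<= 12 configs)
DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "GB": {"learning_rate": [0.1, 0.3], "max_iter": [100]},
    "KNN": {"n_neighbors": [3, 5, 11]},
    "RF": {"max_features": ["sqrt", 0.1], "n_estimators": [200]},
    "LSVM": {"C": [0.1, 1.0, 10.0]},
    "LDA": {"solver": ["svd"]},
    "LR": {"C": [0.1, 1.0, 10.0]},
    "QDA": {"shrinkage": [0.1, 0.5, 0.9]},
    "RSVM": {"C": [1.0, 10.0], "fraction": [0.1]},
    "NB": {"var_smoothing": [1e-9, 1e-6]},
}


def train_model(name: str, X: np.ndarray, y: np.ndarray,
                hyperparams: dict | None = None, seed: int = 0):
    """Fit one registry family; returns an estimator with predict_proba."""
    registry = _registry(seed)
    if name not in registry:
        raise ValueError(
            f"unknown model {name!r}; registry: {sorted(registry)}"
        )
    est = registry[name]
    if hyperparams:
        est.set_params(**hyperparams)
    return est.fit(np.asarray(X, dtype=float), np.asarray(y))


# -------------------------------------------------------- cross-validation

def sample_level_folds(sample_ids: np.ndarray, y: np.ndarray, k_folds: int,
                       seed: int = 0):
    """Stratified k-fold at the sample level, expanded to spectrum indices.

    Every spectrum of one sample lands in the same fold. Yields
    (train_idx, val_idx) index arrays over spectra.
    """
    sample_ids = np.asarray(sample_ids)
    y = np.asarray(y)
    uniq, first = np.unique(sample_ids, return_index=True)
    sample_y = y[first]
    counts = {c: int((sample_y == c).sum()) for c in np.unique(sample_y)}
    too_small = [c for c, n in counts.items() if n < k_folds]
    if too_small:
        raise ValueError(
            f"classes {too_small} have fewer samples than {k_folds} folds"
        )
    skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
    for tr_s, va_s in skf.split(uniq, sample_y):
        tr_ids, va_ids = set(uniq[tr_s]), set(uniq[va_s])
        tr = np.flatnonzero([sid in tr_ids for sid in sample_ids])
        va = np.flatnonzero([sid in va_ids for sid in sample_ids])
        yield tr, va


def _param_grid(grid: dict[str, list]):
    import itertools
    keys = sorted(grid)
    for combo in itertools.product(*(grid[k] for k in keys)):
        yield dict(zip(keys, combo))


def cross_validate(name: str, X: np.ndarray, y: np.ndarray,
                   sample_ids: np.ndarray, k_folds: int = 5, seed: int = 0,
                   grid: dict[str, list] | None = None) -> dict:
    """Sample-level stratified CV with a small grid search.

    Traditional families only (the deep models use early-stopping
    validation instead). Returns {'best_params', 'fold_scores',
    'mean_score'} for the best configuration.
    """
    if name in DEEP_MODELS:
        raise ValueError(
            f"{name} is a deep model; cross_validate covers the traditional "
            f"families {TRADITIONAL_MODELS}"
        )
    if name not in TRADITIONAL_MODELS:
        raise ValueError(f"unknown model {name!r}; registry: {sorted(ALL_MODELS)}")
    if k_folds < 2:
        raise ValueError("k_folds must be >= 2")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    grid = grid if grid is not None else DEFAULT_GRIDS[name]
    folds = list(sample_level_folds(sample_ids, y, k_folds, seed))
    best = None
    for params in _param_grid(grid):
        scores = []
        for tr, va in folds:
            est = _registry(seed)[name]
            est.set_params(**params)
            est.fit(X[tr], y[tr])
            scores.append(float(np.mean(est.predict(X[va]) == y[va])))
        mean = float(np.mean(scores))
        if best is None or mean > best["mean_score"]:
            best = {"best_params": params, "fold_scores": scores,
                    "mean_score": mean}
    return best


# -------------------------------------------------------------- evaluation

@dataclass
class ModelReport:
    """Spectrum-level prediction metrics for one model."""

    name: str
    accuracy: float
    sensitivity: float              # macro average of per-class recalls
    specificity: float              # macro average of per-class TNRs
    per_class_sensitivity: dict[str, float] = field(default_factory=dict)
    per_class_specificity: dict[str, float] = field(default_factory=dict)
    per_class_auc: dict[str, float] = field(default_factory=dict)
    cv_scores: list[float] = field(default_factory=list)

    def to_row(self) -> dict:
        row = {"model": self.name, "accuracy": self.accuracy,
               "sensitivity": self.sensitivity, "specificity": self.specificity}
        for g, v in self.per_class_sensitivity.items():
            row[f"sens_{g}"] = v
        for g, v in self.per_class_specificity.items():
            row[f"spec_{g}"] = v
        for g, v in self.per_class_auc.items():
            row[f"auc_{g}"] = v
        return row


def evaluate(model, X_test: np.ndarray, y_test: np.ndarray,
             name: str | None = None) -> ModelReport:
    """One-vs-rest sensitivity/specificity per class, macro overall, and
    per-class ROC-AUC from predicted probabilities when available."""
    X_test = np.asarray(X_test, dtype=float)
    y_test = np.asarray(y_test)
    if len(y_test) == 0:
        raise ValueError("empty test set")
    y_pred = model.predict(X_test)
    classes = sorted(set(y_test) | set(y_pred))
    acc = float(np.mean(y_pred == y_test))
    sens, spec, aucs = {}, {}, {}
    proba = None
    if hasattr(model, "predict_proba"):
        try:
            proba = model.predict_proba(X_test)
        except Exception:
            proba = None
    for c in classes:
        pos = y_test == c
        if pos.any():
            sens[c] = float(np.mean(y_pred[pos] == c))
        if (~pos).any():
            spec[c] = float(np.mean(y_pred[~pos] != c))
        if proba is not None and pos.any() and (~pos).any():
            model_classes = list(getattr(model, "classes_", classes))
            if c in model_classes:
                j = model_classes.index(c)
                aucs[c] = float(roc_auc_score(pos.astype(int), proba[:, j]))
    return ModelReport(
        name=name or type(model).__name__,
        accuracy=acc,
        sensitivity=float(np.mean(list(sens.values()))),
        specificity=float(np.mean(list(spec.values()))),
        per_class_sensitivity=sens,
        per_class_specificity=spec,
        per_class_auc=aucs,
    )
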
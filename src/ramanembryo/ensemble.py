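"""Stacking of the top base models and per-sample mode aggregation.

Stacking follows the classic out-of-fold design: base models produce
class probabilities on training spectra they never saw (sample-level
5-fold), a multinomial logistic meta-learner is fitted on those
probability features, and the base models are then refitted on the full
training data for deployment.

A sample's final call is the mode of its replicate spectra's predicted
labels; ties break by highest mean predicted probability among the tied
labels, then by class prevalence, then alphabetically - fully
deterministic.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import LogisticRegression

from .datatypes import GROUPS
from .models import ModelReport, sample_level_folds, train_model


# ---------------------------------------------------------------- selection

def select_top_k(reports: list[ModelReport], k: int = 4) -> list[str]:
    """Names of the k highest-accuracy models; ties by sensitivity, then name."""
    if k <= 0:
        raise ValueError("k must be positive")
    if k > len(reports):
        raise ValueError(f"k={k} exceeds the {len(reports)} reports")
    ranked = sorted(reports, key=lambda r: (-r.accuracy, -r.sensitivity, r.name))
    return [r.name for r in ranked[:k]]


# ----------------------------------------------------------------- stacking

@dataclass
class StackingEnsemble:
    base_names: list[str]
    base_models: dict = field(default_factory=dict)
    meta: LogisticRegression | None = None
    classes_: np.ndarray | None = None

    def _features(self, X: np.ndarray) -> np.ndarray:
        return np.hstack([self.base_models[n].predict_proba(X)
                          for n in self.base_names])

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return self.meta.predict_proba(self._features(X))

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.meta.predict(self._features(X))


def fit_stack(base_names: list[str], X_train: np.ndarray, y_train: np.ndarray,
              sample_ids: np.ndarray | None = None, seed: int = 0,
              k_folds: int = 5,
              hyperparams: dict[str, dict] | None = None) -> StackingEnsemble:
    """Wolpert stacking with out-of-fold base probabilities.

    ``sample_ids`` (per training spectrum) keeps replicate spectra of one
    sample inside a single fold; if omitted, each spectrum is its own
    sample.
    """
    if not base_names:
        raise ValueError("base_names must be non-empty")
    X_train = np.asarray(X_train, dtype=float)
    y_train = np.asarray(y_train)
    if sample_ids is None:
        sample_ids = np.arange(len(y_train)).astype(str)
    hyperparams = hyperparams or {}

    from .models import _registry
    registry = _registry(seed)
    kept = []
    for name in base_names:
        if hasattr(registry[name], "predict_proba"):
            kept.append(name)
        else:
            warnings.warn(f"base model {name} has no probability output; excluded")
    if not kept:
        raise ValueError("no base model provides probability output")
    base_names = kept

    folds = list(sample_level_folds(sample_ids, y_train, k_folds, seed))
    classes = np.unique(y_train)
    n_classes = len(classes)
    oof = np.zeros((len(y_train), n_classes * len(base_names)))
    for tr, va in folds:
        for b, name in enumerate(base_names):
            est = train_model(name, X_train[tr], y_train[tr],
                              hyperparams.get(name), seed)
            proba = est.predict_proba(X_train[va])
            # align columns to the global class order
            aligned = np.zeros((len(va), n_classes))
            for j, c in enumerate(est.classes_):
                aligned[:, list(classes).index(c)] = proba[:, j]
            col = b * n_classes
            oof[np.ix_(va, range(col, col + n_classes))] = aligned

    meta = LogisticRegression(max_iter=2000, random_state=seed)
    meta.fit(oof, y_train)

    ens = StackingEnsemble(base_names=list(base_names), meta=meta,
                           classes_=classes)
    for name in base_names:
        ens.base_models[name] = train_model(name, X_train, y_train,
                                            hyperparams.get(name), seed)
    return ens


# ------------------------------------------------------------- aggregation

@dataclass
class SampleDecision:
    sample_id: str
    spectrum_labels: list[str]
    final_label: str
    fraction_correct: float | None = None
    truth: str | None = None

    @property
    def n_spectra(self) -> int:
        return len(self.spectrum_labels)


def aggregate_sample(labels: list[str],
                     probabilities: np.ndarray | None = None,
                     classes: list[str] | None = None,
                     truth: str | None = None,
                     sample_id: str = "",
                     prevalence: dict[str, float] | None = None) -> SampleDecision:
    """Mode over per-spectrum labels with deterministic tie-breaking.

    Ties break by (1) highest mean predicted probability among the tied
    labels (when ``probabilities`` with their ``classes`` column order are
    given), (2) higher training prevalence, (3) alphabetical order.
    """
    if not labels:
        raise ValueError("aggregate_sample needs at least one spectrum label")
    counts = Counter(labels)
    top = max(counts.values())
    tied = sorted(lbl for lbl, c in counts.items() if c == top)
    if len(tied) > 1:
        if probabilities is not None and classes is not None:
            mean_p = {lbl: float(np.mean(probabilities[:, classes.index(lbl)]))
                      for lbl in tied if lbl in classes}
            best = max(mean_p.values())
            tied = sorted(lbl for lbl, p in mean_p.items()
                          if abs(p - best) < 1e-12) or tied
        if len(tied) > 1 and prevalence:
            best = max(prevalence.get(lbl, 0.0) for lbl in tied)
            tied = sorted(lbl for lbl in tied
                          if prevalence.get(lbl, 0.0) == best)
    final = tied[0]
    frac = None
    if truth is not None:
        frac = float(np.mean([lbl == truth for lbl in labels]))
    return SampleDecision(sample_id, list(labels), final, frac, truth)


def sample_accuracy_distribution(decisions: list[SampleDecision]) -> dict:
    """Histogram of per-sample fraction-correct in ten 10% bins.

    Bins are [0, 0.1), ..., [0.9, 1.0]; also reports the share of samples
    with more than half their spectra predicted correctly.
    """
    fracs = [d.fraction_correct for d in decisions]
    if any(f is None for f in fracs):
        raise ValueError("all decisions need a known truth")
    fracs = np.asarray(fracs, dtype=float)
    edges = np.linspace(0.0, 1.0, 11)
    counts, _ = np.histogram(fracs, bins=edges)
    return {
        "bin_edges": edges.tolist(),
        "counts": counts.tolist(),
        "share_above_half": float(np.mean(fracs > 0.5)),
    }


def decide_samples(ens, samples, classes: list[str] | None = None
                   ) -> list[SampleDecision]:
    """Run a fitted classifier per sample and aggregate each one's spectra."""
    out = []
    classes = classes or list(getattr(ens, "classes_", GROUPS))
    classes = [str(c) for c in classes]
    for rec in samples:
        X = np.vstack([s.intensities for s in rec.spectra])
        labels = [str(v) for v in ens.predict(X)]
        proba = ens.predict_proba(X) if hasattr(ens, "predict_proba") else None
        out.append(aggregate_sample(labels, proba, classes,
                                    truth=rec.group, sample_id=rec.sample_id))
    return out
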
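"""Dimensionality-reduction views of preprocessed spectra.

Three views, mirroring common chemometric practice on spectral cohorts:

* t-SNE (unsupervised, library implementation),
* LDA topic model ("LaDA") on pseudo-count spectra -- note this is Latent
  Dirichlet Allocation, an *unsupervised* topic model; the "supervised"
  role is filled by colouring the embedding with the known labels,
* OPLS-DA, implemented from scratch with NIPALS: orthogonal (class-
  uncorrelated) variation is stripped from X before fitting the
  predictive PLS components against the one-hot class matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import LatentDirichletAllocation
from sklearn.manifold import TSNE


@dataclass
class EmbeddingResult:
    method: str
    coordinates: np.ndarray          # (n, 2)
    labels: np.ndarray
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.coordinates.shape[0] != len(self.labels):
            raise ValueError("one coordinate pair per input spectrum required")


# -------------------------------------------------------------------- t-SNE

def tsne_embed(X: np.ndarray, labels: np.ndarray, perplexity: float = 30.0,
               seed: int = 0) -> EmbeddingResult:
    """2-D t-SNE embedding; deterministic for a fixed seed."""
    n = X.shape[0]
    if n < 3 * perplexity:
        raise ValueError(
            f"t-SNE needs >= 3*perplexity rows; got {n} < {3 * perplexity:g}"
        )
    ts = TSNE(n_components=2, perplexity=perplexity, random_state=seed,
              init="pca")
    coords = ts.fit_transform(X)
    return EmbeddingResult("tsne", coords, np.asarray(labels),
                           {"kl_divergence": float(ts.kl_divergence_)})


# ------------------------------------------------------------------ OPLS-DA

def _one_hot(y: np.ndarray) -> tuple[np.ndarray, list]:
    classes = sorted(set(y))
    Y = np.zeros((len(y), len(classes)))
    for j, c in enumerate(classes):
        Y[np.asarray(y) == c, j] = 1.0
    return Y, classes


def _nipals_pls_component(X: np.ndarray, Y: np.ndarray, tol: float = 1e-10,
                          max_iter: int = 500):
    """One PLS2 component by NIPALS; returns (w, t, p, q)."""
    u = Y[:, np.argmax(np.var(Y, axis=0))].copy()
    w = None
    for _ in range(max_iter):
        w_new = X.T @ u
        w_new /= np.linalg.norm(w_new)
        t = X @ w_new
        q = Y.T @ t / (t @ t)
        u_new = Y @ q / (q @ q)
        if w is not None and np.linalg.norm(w_new - w) < tol:
            w = w_new
            u = u_new
            break
        w, u = w_new, u_new
    t = X @ w
    p = X.T @ t / (t @ t)
    q = Y.T @ t / (t @ t)
    return w, t, p, q


class OPLSDA:
    """Orthogonal PLS discriminant analysis (NIPALS).

    Removes ``n_orth`` components of X-variation orthogonal to the class
    structure, then fits ``n_pred`` predictive PLS components on the
    filtered matrix. Diagnostics: R2X (X variance modelled by predictive +
    orthogonal components) and R2Y (class-matrix variance explained).
    """

    def __init__(self, n_orth: int = 1, n_pred: int | None = None):
        if n_orth < 1:
            raise ValueError("n_orth must be >= 1")
        self.n_orth = n_orth
        self.n_pred = n_pred

    def fit(self, X: np.ndarray, y: np.ndarray) -> "OPLSDA":
        y = np.asarray(y)
        classes = sorted(set(y))
        if len(classes) < 2:
            raise ValueError("OPLS-DA needs at least two classes")
        n_pred = self.n_pred or (2 if len(classes) >= 3 else 1)

        self.x_mean_ = X.mean(axis=0)
        Xc = X - self.x_mean_
        keep = Xc.std(axis=0) > 0
        if not keep.all():
            import warnings
            warnings.warn(f"dropping {int((~keep).sum())} constant columns")
        self.keep_ = keep
        Xc = Xc[:, keep]
        Y, self.classes_ = _one_hot(y)
        Yc = Y - Y.mean(axis=0)

        ssx = np.sum(Xc ** 2)
        ssy = np.sum(Yc ** 2)
        Xf = Xc.copy()
        self.W_orth_, self.P_orth_, self.T_orth_ = [], [], []
        for _ in range(self.n_orth):
            w, t, p, q = _nipals_pls_component(Xf, Yc)
            w_orth = p - (w @ p) / (w @ w) * w
            norm = np.linalg.norm(w_orth)
            if norm < 1e-12:
                break
            w_orth /= norm
            t_orth = Xf @ w_orth
            p_orth = Xf.T @ t_orth / (t_orth @ t_orth)
            Xf = Xf - np.outer(t_orth, p_orth)
            self.W_orth_.append(w_orth)
            self.P_orth_.append(p_orth)
            self.T_orth_.append(t_orth)

        # predictive components on the filtered matrix
        self.W_, self.P_, self.Q_, self.T_ = [], [], [], []
        Xp = Xf.copy()
        Yres = Yc.copy()
        for _ in range(n_pred):
            w, t, p, q = _nipals_pls_component(Xp, Yres)
            self.W_.append(w)
            self.P_.append(p)
            self.Q_.append(q)
            self.T_.append(t)
            Xp = Xp - np.outer(t, p)
            Yres = Yres - np.outer(t, q)

        modelled = ssx - np.sum(Xp ** 2)
        self.r2x_ = float(modelled / ssx)
        self.r2y_ = float(1.0 - np.sum(Yres ** 2) / ssy)
        self.n_pred_ = n_pred
        return self

    def transform(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Returns (predictive scores, orthogonal scores) for new data."""
        Xc = (X - self.x_mean_)[:, self.keep_]
        t_orth = np.empty((X.shape[0], len(self.W_orth_)))
        for k, (w_o, p_o) in enumerate(zip(self.W_orth_, self.P_orth_)):
            t_orth[:, k] = Xc @ w_o
            Xc = Xc - np.outer(t_orth[:, k], p_o)
        t_pred = np.empty((X.shape[0], len(self.W_)))
        for k, (w, p) in enumerate(zip(self.W_, self.P_)):
            t_pred[:, k] = Xc @ w
            Xc = Xc - np.outer(t_pred[:, k], p)
        return t_pred, t_orth


def oplsda_fit(X: np.ndarray, y: np.ndarray, n_orth: int = 1
               ) -> tuple[OPLSDA, EmbeddingResult]:
    """Fit OPLS-DA and build the 2-D embedding.

    Three classes: first two predictive scores. Two classes: (predictive
    score 1, orthogonal score 1).
    """
    model = OPLSDA(n_orth=n_orth).fit(X, y)
    t_pred, t_orth = model.transform(X)
    if model.n_pred_ >= 2:
        coords = t_pred[:, :2]
    else:
        coords = np.column_stack([t_pred[:, 0], t_orth[:, 0]])
    return model, EmbeddingResult(
        "oplsda", coords, np.asarray(y),
        {"r2x": model.r2x_, "r2y": model.r2y_},
    )


# --------------------------------------------------------------------- LaDA

def lada_embed(X: np.ndarray, labels: np.ndarray, n_topics: int = 3,
               seed: int = 0, count_scale: float = 100.0) -> EmbeddingResult:
    """LDA topic embedding of spectra discretized to pseudo-counts.

    Intensities must be non-negative (guaranteed after area
    normalization); each spectrum becomes a "document" whose per-channel
    "word counts" are round(intensity * count_scale).
    """
    X = np.asarray(X, dtype=float)
    if np.any(X < 0):
        raise ValueError(
            "negative intensities: baseline-correct and normalize spectra first"
        )
    counts = np.rint(X * count_scale).astype(np.int64)
    lda = LatentDirichletAllocation(n_components=n_topics, random_state=seed)
    theta = lda.fit_transform(counts)
    if n_topics == 1:
        coords = np.zeros((X.shape[0], 2))
    else:
        coords = theta[:, :2]
    return EmbeddingResult(
        "lada", coords, np.asarray(labels),
        {"topic_word": lda.components_, "doc_topic": theta,
         "perplexity": float(lda.perplexity(counts))},
    )


def embeddings_to_frame(results: list[EmbeddingResult]):
    """Long-format frame (spectrum index, x, y, label, method) for export."""
    import pandas as pd
    frames = []
    for r in results:
        frames.append(pd.DataFrame({
            "spectrum": np.arange(len(r.labels)),
            "x": r.coordinates[:, 0], "y": r.coordinates[:, 1],
            "label": r.labels, "method": r.method,
        }))
    return pd.concat(frames, ignore_index=True)
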
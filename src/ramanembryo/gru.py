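"""A small GRU sequence classifier in pure numpy.

No deep-learning framework is assumed: the forward pass, backpropagation
through time and Adam updates are written out explicitly. A spectrum (one
long intensity vector) is chunked into consecutive patches (default 50
points, stride 50) and fed to a single unidirectional GRU; the softmax
head reads the final hidden state.

Analytic gradients are verified against central finite differences in the
test suite, which is the contract that matters for a hand-rolled BPTT.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -50, 50)))


def _softmax(z):
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class GRUClassifier(BaseEstimator, ClassifierMixin):
    """Single-layer GRU over patched spectra with a softmax head.

    Parameters
    ----------
    hidden_size : GRU state dimension.
    patch : points per input patch (the sequence element size); the
        spectrum is zero-padded to a multiple of ``patch``.
    epochs, lr, batch_size, l2 : Adam training schedule.
    val_fraction, patience : early stopping on a held-out fraction of the
        training spectra (skipped when the training set is too small to
        stratify a validation split).
    """

    def __init__(self, hidden_size: int = 32, patch: int = 50,
                 epochs: int = 60, lr: float = 0.01, batch_size: int = 32,
                 l2: float = 1e-4, val_fraction: float = 0.15,
                 patience: int = 8, random_state: int = 0):
        self.hidden_size = hidden_size
        self.patch = patch
        self.epochs = epochs
        self.lr = lr
        self.batch_size = batch_size
        self.l2 = l2
        self.val_fraction = val_fraction
        self.patience = patience
        self.random_state = random_state

    # ------------------------------------------------------------ plumbing

    def _init_params(self, p: int, h: int, k: int, rng) -> dict:
        def mat(a, b):
            return rng.standard_normal((a, b)) * np.sqrt(1.0 / a)
        params = {}
        for gate in ("z", "r", "h"):
            params[f"W{gate}"] = mat(p, h)
            params[f"U{gate}"] = mat(h, h)
            params[f"b{gate}"] = np.zeros(h)
        params["Wo"] = mat(h, k)
        params["bo"] = np.zeros(k)
        return params

    def _to_sequences(self, X: np.ndarray) -> np.ndarray:
        n, d = X.shape
        t = -(-d // self.patch)
        pad = t * self.patch - d
        if pad:
            X = np.hstack([X, np.zeros((n, pad))])
        return X.reshape(n, t, self.patch)

    # --------------------------------------------------- forward / backward

    def _forward(self, params: dict, Xs: np.ndarray):
        b, t, _ = Xs.shape
        h = np.zeros((b, self.hidden_size))
        cache = []
        for i in range(t):
            x = Xs[:, i, :]
            z = _sigmoid(x @ params["Wz"] + h @ params["Uz"] + params["bz"])
            r = _sigmoid(x @ params["Wr"] + h @ params["Ur"] + params["br"])
            c = np.tanh(x @ params["Wh"] + (r * h) @ params["Uh"] + params["bh"])
            h_new = (1.0 - z) * h + z * c
            cache.append((x, h, z, r, c))
            h = h_new
        logits = h @ params["Wo"] + params["bo"]
        return logits, h, cache

    def _loss_and_grads(self, params: dict, Xs: np.ndarray, Y: np.ndarray):
        """Mean cross-entropy + L2; gradients for every parameter."""
        b = Xs.shape[0]
        logits, h_last, cache = self._forward(params, Xs)
        probs = _softmax(logits)
        loss = -np.mean(np.sum(Y * np.log(probs + 1e-12), axis=1))

        grads = {k: np.zeros_like(v) for k, v in params.items()}
        dlogits = (probs - Y) / b
        grads["Wo"] = h_last.T @ dlogits
        grads["bo"] = dlogits.sum(axis=0)
        dh = dlogits @ params["Wo"].T

        for x, h_prev, z, r, c in reversed(cache):
            dz = dh * (c - h_prev)
            dc = dh * z
            dh_prev = dh * (1.0 - z)

            dc_pre = dc * (1.0 - c ** 2)
            grads["Wh"] += x.T @ dc_pre
            grads["Uh"] += (r * h_prev).T @ dc_pre
            grads["bh"] += dc_pre.sum(axis=0)
            drh = dc_pre @ params["Uh"].T
            dr = drh * h_prev
            dh_prev = dh_prev + drh * r

            dz_pre = dz * z * (1.0 - z)
            grads["Wz"] += x.T @ dz_pre
            grads["Uz"] += h_prev.T @ dz_pre
            grads["bz"] += dz_pre.sum(axis=0)
            dh_prev = dh_prev + dz_pre @ params["Uz"].T

            dr_pre = dr * r * (1.0 - r)
            grads["Wr"] += x.T @ dr_pre
            grads["Ur"] += h_prev.T @ dr_pre
            grads["br"] += dr_pre.sum(axis=0)
            dh_prev = dh_prev + dr_pre @ params["Ur"].T

            dh = dh_prev

        if self.l2 > 0:
            for k in params:
                if k.startswith(("W", "U")):
                    loss += 0.5 * self.l2 * np.sum(params[k] ** 2)
                    grads[k] += self.l2 * params[k]
        return loss, grads

    # -------------------------------------------------------------- fitting

    def fit(self, X: np.ndarray, y: np.ndarray) -> "GRUClassifier":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        k = len(self.classes_)
        rng = np.random.default_rng(self.random_state)

        self.x_mean_ = X.mean(axis=0)
        self.x_scale_ = X.std(axis=0)
        self.x_scale_[self.x_scale_ == 0] = 1.0
        Xs = self._to_sequences((X - self.x_mean_) / self.x_scale_)
        Y = np.eye(k)[y_idx]
        n = len(X)

        # validation split for early stopping (needs enough per class)
        counts = np.bincount(y_idx, minlength=k)
        n_val = int(round(self.val_fraction * n))
        use_val = n_val >= k and counts.min() >= 4
        if use_val:
            order = rng.permutation(n)
            val_idx, tr_idx = order[:n_val], order[n_val:]
            if len(np.unique(y_idx[tr_idx])) < k:
                use_val = False
        if not use_val:
            tr_idx = np.arange(n)
            val_idx = np.array([], dtype=int)

        params = self._init_params(self.patch, self.hidden_size, k, rng)
        m = {kk: np.zeros_like(v) for kk, v in params.items()}
        v = {kk: np.zeros_like(vv) for kk, vv in params.items()}
        b1, b2, eps = 0.9, 0.999, 1e-8
        step = 0
        best_val = np.inf
        best_params = {kk: vv.copy() for kk, vv in params.items()}
        bad_epochs = 0
        self.history_ = {"train_loss": [], "val_loss": []}

        for _epoch in range(self.epochs):
            perm = rng.permutation(len(tr_idx))
            ep_loss, nb = 0.0, 0
            for start in range(0, len(tr_idx), self.batch_size):
                batch = tr_idx[perm[start:start + self.batch_size]]
                loss, grads = self._loss_and_grads(params, Xs[batch], Y[batch])
                step += 1
                for kk in params:
                    m[kk] = b1 * m[kk] + (1 - b1) * grads[kk]
                    v[kk] = b2 * v[kk] + (1 - b2) * grads[kk] ** 2
                    mhat = m[kk] / (1 - b1 ** step)
                    vhat = v[kk] / (1 - b2 ** step)
                    params[kk] -= self.lr * mhat / (np.sqrt(vhat) + eps)
                ep_loss += loss
                nb += 1
            self.history_["train_loss"].append(ep_loss / max(nb, 1))

            if use_val:
                logits, _, _ = self._forward(params, Xs[val_idx])
                probs = _softmax(logits)
                vloss = -np.mean(np.sum(Y[val_idx] * np.log(probs + 1e-12), axis=1))
                self.history_["val_loss"].append(vloss)
                if vloss < best_val - 1e-5:
                    best_val = vloss
                    best_params = {kk: vv.copy() for kk, vv in params.items()}
                    bad_epochs = 0
                else:
                    bad_epochs += 1
                    if bad_epochs >= self.patience:
                        break

        self.params_ = best_params if use_val else params
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        Xs = self._to_sequences((X - self.x_mean_) / self.x_scale_)
        logits, _, _ = self._forward(self.params_, Xs)
        return _softmax(logits)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]
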
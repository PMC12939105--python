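"""A feature-tokenizer transformer for tabular inputs, in pure NumPy.

Each scalar feature j is embedded as a token ``x_j * W_j + b_j`` (W_j a
learned d-vector); a learned CLS token is appended.  Pre-norm transformer
blocks (multi-head self-attention + GELU feed-forward, residual both times)
process the token sequence; the classifier head reads the final
layer-normed CLS state and emits a sigmoid probability.  Training is
binary cross-entropy with Adam; gradients are computed analytically
(reverse-mode, hand-derived) and are validated against central differences
in the test suite.  Inference is deterministic; dropout is only active
during training and is driven by the configured seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import erf, expit

_EPS = 1e-5
_SQRT2 = np.sqrt(2.0)
_INV_SQRT_2PI = 1.0 / np.sqrt(2.0 * np.pi)


@dataclass(frozen=True)
class FTTransformerConfig:
    token_dim: int = 64
    n_layers: int = 3
    n_heads: int = 4
    ffn_multiplier: int = 4
    dropout: float = 0.1
    learning_rate: float = 1e-4
    batch_size: int = 32
    max_epochs: int = 200
    patience: int = 20
    val_fraction: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.token_dim % self.n_heads != 0:
            raise ValueError("token_dim must be divisible by n_heads")
        for name in ("token_dim", "n_layers", "n_heads", "ffn_multiplier",
                     "batch_size", "max_epochs"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


# ------------------------------------------------------------- primitives

def _gelu(x):
    return 0.5 * x * (1.0 + erf(x / _SQRT2))


def _gelu_grad(x):
    cdf = 0.5 * (1.0 + erf(x / _SQRT2))
    pdf = _INV_SQRT_2PI * np.exp(-0.5 * x * x)
    return cdf + x * pdf


def _ln_forward(x, g, b):
    mu = x.mean(-1, keepdims=True)
    var = x.var(-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + _EPS)
    xhat = (x - mu) * inv
    return g * xhat + b, (xhat, inv, g)


def _ln_backward(dy, cache):
    xhat, inv, g = cache
    dg = (dy * xhat).sum(tuple(range(dy.ndim - 1)))
    db = dy.sum(tuple(range(dy.ndim - 1)))
    dxhat = dy * g
    dx = inv * (dxhat - dxhat.mean(-1, keepdims=True)
                - xhat * (dxhat * xhat).mean(-1, keepdims=True))
    return dx, dg, db


def _linear_forward(x, w, b):
    return x @ w + b


def _linear_backward(x, w, dy):
    x2 = x.reshape(-1, x.shape[-1])
    dy2 = dy.reshape(-1, dy.shape[-1])
    return dy @ w.T, x2.T @ dy2, dy2.sum(0)


def _softmax(s):
    m = s.max(-1, keepdims=True)
    e = np.exp(s - m)
    return e / e.sum(-1, keepdims=True)


# ------------------------------------------------------------- the model

class FTTransformer:
    """Binary classifier over a fixed set of continuous features."""

    def __init__(self, n_features: int,
                 config: FTTransformerConfig = FTTransformerConfig()):
        if n_features < 1:
            raise ValueError("need at least one feature")
        self.n_features = int(n_features)
        self.config = config
        self.params = self._init_params(np.random.default_rng(config.seed))
        self.history_: list[dict] = []

    # -- parameters ----------------------------------------------------

    def _init_params(self, rng) -> dict[str, np.ndarray]:
        d = self.config.token_dim
        f = d * self.config.ffn_multiplier
        k = self.n_features

        def w(*shape, scale=None):
            scale = scale or 1.0 / np.sqrt(shape[0])
            return rng.normal(0.0, scale, size=shape)

        p: dict[str, np.ndarray] = {
            "tok_W": rng.normal(0.0, 1.0 / np.sqrt(d), size=(k, d)),
            "tok_b": np.zeros((k, d)),
            "cls": rng.normal(0.0, 1.0 / np.sqrt(d), size=d),
            "lnf_g": np.ones(d), "lnf_b": np.zeros(d),
            "head_w": w(d, 1).ravel(), "head_b": np.zeros(()),
        }
        for layer in range(self.config.n_layers):
            pre = f"L{layer}_"
            p[pre + "ln1_g"] = np.ones(d)
            p[pre + "ln1_b"] = np.zeros(d)
            p[pre + "ln2_g"] = np.ones(d)
            p[pre + "ln2_b"] = np.zeros(d)
            for nm in ("Wq", "Wk", "Wv", "Wo"):
                p[pre + nm] = w(d, d)
            for nm in ("bq", "bk", "bv", "bo"):
                p[pre + nm] = np.zeros(d)
            p[pre + "W1"] = w(d, f)
            p[pre + "b1"] = np.zeros(f)
            p[pre + "W2"] = w(f, d)
            p[pre + "b2"] = np.zeros(d)
        return p

    # -- forward / backward --------------------------------------------

    def _forward(self, X: np.ndarray, train: bool = False, rng=None):
        p = self.params
        cfg = self.config
        n, k = X.shape
        if k != self.n_features:
            raise ValueError(
                f"expected {self.n_features} features, got {k}")
        d = cfg.token_dim
        h = cfg.n_heads
        dh = d // h
        scale = 1.0 / np.sqrt(dh)

        cache: dict = {"X": X, "drop": {}}
        T = np.empty((n, k + 1, d))
        T[:, :k, :] = X[:, :, None] * p["tok_W"][None] + p["tok_b"][None]
        T[:, k, :] = p["cls"]
        cache["T0"] = T

        def dropout(a, tag):
            if not train or cfg.dropout <= 0:
                return a
            mask = (rng.random(a.shape) >= cfg.dropout) / (1 - cfg.dropout)
            cache["drop"][tag] = mask
            return a * mask

        layer_caches = []
        for layer in range(cfg.n_layers):
            pre = f"L{layer}_"
            lc: dict = {"T_in": T}
            A, lc["ln1"] = _ln_forward(T, p[pre + "ln1_g"], p[pre + "ln1_b"])
            lc["A"] = A
            Q = _linear_forward(A, p[pre + "Wq"], p[pre + "bq"])
            K = _linear_forward(A, p[pre + "Wk"], p[pre + "bk"])
            V = _linear_forward(A, p[pre + "Wv"], p[pre + "bv"])
            Qh = Q.reshape(n, k + 1, h, dh).transpose(0, 2, 1, 3)
            Kh = K.reshape(n, k + 1, h, dh).transpose(0, 2, 1, 3)
            Vh = V.reshape(n, k + 1, h, dh).transpose(0, 2, 1, 3)
            S = Qh @ Kh.swapaxes(-1, -2) * scale
            P = _softmax(S)
            Oh = P @ Vh
            O = Oh.transpose(0, 2, 1, 3).reshape(n, k + 1, d)
            M = _linear_forward(O, p[pre + "Wo"], p[pre + "bo"])
            M = dropout(M, f"{layer}_attn")
            lc.update(Qh=Qh, Kh=Kh, Vh=Vh, P=P, O=O)
            T = T + M

            lc["T_mid"] = T
            B, lc["ln2"] = _ln_forward(T, p[pre + "ln2_g"], p[pre + "ln2_b"])
            lc["B"] = B
            H = _linear_forward(B, p[pre + "W1"], p[pre + "b1"])
            G = _gelu(H)
            F = _linear_forward(G, p[pre + "W2"], p[pre + "b2"])
            F = dropout(F, f"{layer}_ffn")
            lc.update(H=H, G=G)
            T = T + F
            layer_caches.append(lc)

        Z, lnf_cache = _ln_forward(T, p["lnf_g"], p["lnf_b"])
        z = Z[:, k, :]
        logits = z @ p["head_w"] + p["head_b"]
        cache.update(layers=layer_caches, lnf=lnf_cache, z=z, T_out=T)
        return logits, cache

    def _backward(self, dlogits: np.ndarray, cache: dict) -> dict[str, np.ndarray]:
        p = self.params
        cfg = self.config
        X = cache["X"]
        n, k = X.shape
        d = cfg.token_dim
        h = cfg.n_heads
        dh = d // h
        scale = 1.0 / np.sqrt(dh)
        g: dict[str, np.ndarray] = {}

        z = cache["z"]
        g["head_w"] = z.T @ dlogits
        g["head_b"] = dlogits.sum()
        dZ = np.zeros((n, k + 1, d))
        dZ[:, k, :] = dlogits[:, None] * p["head_w"][None]
        dT, g["lnf_g"], g["lnf_b"] = _ln_backward(dZ, cache["lnf"])

        for layer in reversed(range(cfg.n_layers)):
            pre = f"L{layer}_"
            lc = cache["layers"][layer]
            dF = dT.copy()
            mask = cache["drop"].get(f"{layer}_ffn")
            if mask is not None:
                dF = dF * mask
            dG, g[pre + "W2"], g[pre + "b2"] = _linear_backward(
                lc["G"], p[pre + "W2"], dF)
            dH = dG * _gelu_grad(lc["H"])
            dB, g[pre + "W1"], g[pre + "b1"] = _linear_backward(
                lc["B"], p[pre + "W1"], dH)
            dT_mid, g[pre + "ln2_g"], g[pre + "ln2_b"] = _ln_backward(
                dB, lc["ln2"])
            dT = dT + dT_mid

            dM = dT.copy()
            mask = cache["drop"].get(f"{layer}_attn")
            if mask is not None:
                dM = dM * mask
            dO, g[pre + "Wo"], g[pre + "bo"] = _linear_backward(
                lc["O"], p[pre + "Wo"], dM)
            dOh = dO.reshape(n, k + 1, h, dh).transpose(0, 2, 1, 3)
            P, Qh, Kh, Vh = lc["P"], lc["Qh"], lc["Kh"], lc["Vh"]
            dP = dOh @ Vh.swapaxes(-1, -2)
            dVh = P.swapaxes(-1, -2) @ dOh
            dS = P * (dP - (dP * P).sum(-1, keepdims=True))
            dQh = dS @ Kh * scale
            dKh = dS.swapaxes(-1, -2) @ Qh * scale
            dQ = dQh.transpose(0, 2, 1, 3).reshape(n, k + 1, d)
            dK = dKh.transpose(0, 2, 1, 3).reshape(n, k + 1, d)
            dV = dVh.transpose(0, 2, 1, 3).reshape(n, k + 1, d)
            A = lc["A"]
            dA1, g[pre + "Wq"], g[pre + "bq"] = _linear_backward(
                A, p[pre + "Wq"], dQ)
            dA2, g[pre + "Wk"], g[pre + "bk"] = _linear_backward(
                A, p[pre + "Wk"], dK)
            dA3, g[pre + "Wv"], g[pre + "bv"] = _linear_backward(
                A, p[pre + "Wv"], dV)
            dT_in, g[pre + "ln1_g"], g[pre + "ln1_b"] = _ln_backward(
                dA1 + dA2 + dA3, lc["ln1"])
            dT = dT + dT_in

        dT0 = dT
        g["cls"] = dT0[:, k, :].sum(0)
        g["tok_W"] = np.einsum("nj,njd->jd", X, dT0[:, :k, :])
        g["tok_b"] = dT0[:, :k, :].sum(0)
        return g

    # -- loss ----------------------------------------------------------

    @staticmethod
    def _bce(logits, y, w=None):
        """Stable BCE; returns (mean loss, dlogits)."""
        if w is None:
            w = np.ones_like(logits)
        wsum = w.sum()
        loss = float((w * (np.logaddexp(0.0, logits) - y * logits)).sum() / wsum)
        dlogits = w * (expit(logits) - y) / wsum
        return loss, dlogits

    def loss_and_grads(self, X, y, sample_weight=None, train=True, rng=None):
        logits, cache = self._forward(X, train=train, rng=rng)
        loss, dlogits = self._bce(logits, np.asarray(y, dtype=np.float64),
                                  sample_weight)
        grads = self._backward(dlogits, cache)
        return loss, grads

    # -- training ------------------------------------------------------

    def fit(self, X, y, sample_weight=None, learning_rate=None,
            max_epochs=None, reset: bool = True):
        """Train by minibatch Adam with early stopping on validation loss.

        ``reset=False`` continues from the current weights (used for the
        self-training fine-tuning stage, typically with a reduced learning
        rate).  Raises ``RuntimeError`` on divergence (non-finite loss).
        """
        cfg = self.config
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=np.float64)
        n = X.shape[0]
        if sample_weight is None:
            sample_weight = np.ones(n)
        sample_weight = np.asarray(sample_weight, dtype=np.float64)
        lr = learning_rate if learning_rate is not None else cfg.learning_rate
        epochs = max_epochs if max_epochs is not None else cfg.max_epochs

        rng = np.random.default_rng(cfg.seed + 1)
        if reset:
            self.params = self._init_params(np.random.default_rng(cfg.seed))
            self.history_ = []

        # stratified validation split for early stopping
        val_idx = np.array([], dtype=int)
        if cfg.val_fraction > 0 and n >= 20:
            idx0 = np.flatnonzero(y == 0)
            idx1 = np.flatnonzero(y == 1)
            rng.shuffle(idx0)
            rng.shuffle(idx1)
            n0 = max(1, int(round(cfg.val_fraction * idx0.size)))
            n1 = max(1, int(round(cfg.val_fraction * idx1.size)))
            val_idx = np.concatenate([idx0[:n0], idx1[:n1]])
        train_idx = np.setdiff1d(np.arange(n), val_idx)

        m = {k: np.zeros_like(v) for k, v in self.params.items()}
        v = {k: np.zeros_like(v) for k, v in self.params.items()}
        b1, b2, eps = 0.9, 0.999, 1e-8
        step = 0
        best_loss = np.inf
        best_params = {k: p.copy() for k, p in self.params.items()}
        stale = 0

        for epoch in range(epochs):
            order = train_idx.copy()
            rng.shuffle(order)
            ep_loss = 0.0
            nb = 0
            for start in range(0, order.size, cfg.batch_size):
                batch = order[start:start + cfg.batch_size]
                loss, grads = self.loss_and_grads(
                    X[batch], y[batch], sample_weight[batch],
                    train=True, rng=rng)
                if not np.isfinite(loss):
                    raise RuntimeError(
                        f"training diverged at epoch {epoch} "
                        f"(loss={loss}); lower the learning rate")
                ep_loss += loss
                nb += 1
                step += 1
                for key, grad in grads.items():
                    m[key] = b1 * m[key] + (1 - b1) * grad
                    v[key] = b2 * v[key] + (1 - b2) * grad ** 2
                    mhat = m[key] / (1 - b1 ** step)
                    vhat = v[key] / (1 - b2 ** step)
                    self.params[key] = self.params[key] - lr * mhat / (
                        np.sqrt(vhat) + eps)

            if val_idx.size:
                logits, _ = self._forward(X[val_idx], train=False)
                mon_loss, _ = self._bce(logits, y[val_idx],
                                        sample_weight[val_idx])
            else:
                mon_loss = ep_loss / max(nb, 1)
            self.history_.append({"epoch": epoch, "train_loss":
                                  ep_loss / max(nb, 1), "monitor": mon_loss})
            if mon_loss < best_loss - 1e-6:
                best_loss = mon_loss
                best_params = {k: p.copy() for k, p in self.params.items()}
                stale = 0
            else:
                stale += 1
                if stale >= cfg.patience:
                    break
        self.params = best_params
        return self

    def predict_logits(self, X) -> np.ndarray:
        logits, _ = self._forward(np.asarray(X, dtype=np.float64),
                                  train=False)
        return logits

    def predict_proba(self, X) -> np.ndarray:
        """Probability of class 1 (deterministic; no dropout)."""
        return expit(self.predict_logits(X))
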
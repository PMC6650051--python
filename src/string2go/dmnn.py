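"""Deep maxout neural network for multi-label GO-term prediction.

The network maps a protein's network-embedding vector to sigmoid
probabilities over the term vocabulary through three hidden blocks, each
computing batch-norm -> k parallel affine maps -> elementwise max (maxout)
-> dropout.  Training minimizes binary cross-entropy with AdaGrad.  The
post-maxout activations of the third hidden block, taken in inference mode,
are the learned *functional representation*: features that encode both the
interaction neighborhood (through the embedding input) and term
co-occurrence structure (through the multi-label target).

Implemented directly on NumPy: explicit forward/backward passes, seeded
Glorot-uniform initialization, single-threaded and reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .embedding import EmbeddingMatrix
from .evaluation import confusion_metrics, ConfusionCounts

HIDDEN_DIM_CANDIDATES = (300, 500, 700, 1000)


class TrainingDivergenceError(RuntimeError):
    pass


@dataclass
class DMNNConfig:
    """Hyperparameters of the three-hidden-layer maxout network.

    Defaults follow the tuned protocol: AdaGrad, 3 maxout pieces, learning
    rate 0.05, batches of 100, 150 epochs, Glorot-uniform initialization.
    ``layer3_dim`` optionally widens/narrows only the third hidden layer
    (e.g. to match the input dimension); otherwise all three layers share
    ``hidden_dim``.
    """

    hidden_dim: int = 500
    maxout_pieces: int = 3
    dropout_rate: float = 0.5
    learning_rate: float = 0.05
    batch_size: int = 100
    epochs: int = 150
    seed: int = 0
    layer3_dim: int | None = None
    bn_momentum: float = 0.9
    bn_eps: float = 1e-5

    def validate(self) -> None:
        problems = []
        if self.hidden_dim <= 0:
            problems.append("hidden_dim must be > 0")
        if self.maxout_pieces < 1:
            problems.append("maxout_pieces must be >= 1")
        if not (0.0 <= self.dropout_rate < 1.0):
            problems.append("dropout_rate must lie in [0, 1)")
        if self.epochs < 1:
            problems.append("epochs must be >= 1")
        if self.learning_rate <= 0:
            problems.append("learning_rate must be > 0")
        if self.batch_size < 1:
            problems.append("batch_size must be >= 1")
        if self.layer3_dim is not None and self.layer3_dim <= 0:
            problems.append("layer3_dim must be > 0 when given")
        if problems:
            raise ValueError("invalid DMNN config: " + "; ".join(problems))


def _glorot_uniform(rng: np.random.Generator, fan_in: int, fan_out: int,
                    shape: tuple[int, ...]) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class _MaxoutBlock:
    """batch-norm -> k affine maps -> max -> dropout (training only)."""

    def __init__(self, rng: np.random.Generator, dim_in: int, dim_out: int,
                 pieces: int, cfg: DMNNConfig):
        self.cfg = cfg
        self.pieces = pieces
        self.gamma = np.ones(dim_in)
        self.beta = np.zeros(dim_in)
        self.run_mean = np.zeros(dim_in)
        self.run_var = np.ones(dim_in)
        self.W = _glorot_uniform(rng, dim_in, dim_out,
                                 (pieces, dim_in, dim_out))
        self.b = np.zeros((pieces, dim_out))

    def params(self):
        return [self.gamma, self.beta, self.W, self.b]

    def forward(self, h: np.ndarray, training: bool,
                rng: np.random.Generator | None = None) -> np.ndarray:
        eps = self.cfg.bn_eps
        if training:
            mu = h.mean(axis=0)
            var = h.var(axis=0)
            m = self.cfg.bn_momentum
            self.run_mean = m * self.run_mean + (1 - m) * mu
            self.run_var = m * self.run_var + (1 - m) * var
        else:
            mu, var = self.run_mean, self.run_var
        inv_std = 1.0 / np.sqrt(var + eps)
        xhat = (h - mu) * inv_std
        z = self.gamma * xhat + self.beta
        pre = np.einsum("bi,kio->bko", z, self.W) + self.b  # (b, k, out)
        self._argmax = pre.argmax(axis=1)
        a = pre.max(axis=1)
        if training and self.cfg.dropout_rate > 0:
            keep = 1.0 - self.cfg.dropout_rate
            mask = (rng.random(a.shape) < keep) / keep
            self._cache = (h, mu, inv_std, xhat, z, mask)
            return a * mask
        self._cache = (h, mu, inv_std, xhat, z, None)
        return a

    def backward(self, grad_out: np.ndarray):
        h, mu, inv_std, xhat, z, mask = self._cache
        if mask is not None:
            grad_out = grad_out * mask
        b_sz, k, out = grad_out.shape[0], self.pieces, self.W.shape[2]
        # route gradient to the winning piece
        grad_pre = np.zeros((b_sz, k, out))
        rows = np.arange(b_sz)[:, None]
        cols = np.arange(out)[None, :]
        grad_pre[rows, self._argmax, cols] = grad_out
        self.gW = np.einsum("bi,bko->kio", z, grad_pre)
        self.gb = grad_pre.sum(axis=0)
        grad_z = np.einsum("bko,kio->bi", grad_pre, self.W)
        # batch-norm backward
        self.ggamma = (grad_z * xhat).sum(axis=0)
        self.gbeta = grad_z.sum(axis=0)
        grad_xhat = grad_z * self.gamma
        n = h.shape[0]
        grad_h = (inv_std / n) * (
            n * grad_xhat
            - grad_xhat.sum(axis=0)
            - xhat * (grad_xhat * xhat).sum(axis=0)
        )
        return grad_h

    def grads(self):
        return [self.ggamma, self.gbeta, self.gW, self.gb]


class DeepMaxoutClassifier(BaseEstimator, TransformerMixin):
    """Three-hidden-layer maxout network, sklearn-style.

    ``fit(X, Y)`` trains on aligned protein rows; ``predict_proba`` returns
    sigmoid posteriors in (0, 1); ``transform`` returns the third hidden
    block's post-maxout activations in inference mode (dropout off,
    batch-norm on running statistics) — the functional representation.
    """

    def __init__(self, hidden_dim: int = 500, maxout_pieces: int = 3,
                 dropout_rate: float = 0.5, learning_rate: float = 0.05,
                 batch_size: int = 100, epochs: int = 150, seed: int = 0,
                 layer3_dim: int | None = None, bn_momentum: float = 0.9,
                 bn_eps: float = 1e-5):
        self.hidden_dim = hidden_dim
        self.maxout_pieces = maxout_pieces
        self.dropout_rate = dropout_rate
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.epochs = epochs
        self.seed = seed
        self.layer3_dim = layer3_dim
        self.bn_momentum = bn_momentum
        self.bn_eps = bn_eps

    def _config(self) -> DMNNConfig:
        return DMNNConfig(
            hidden_dim=self.hidden_dim, maxout_pieces=self.maxout_pieces,
            dropout_rate=self.dropout_rate, learning_rate=self.learning_rate,
            batch_size=self.batch_size, epochs=self.epochs, seed=self.seed,
            layer3_dim=self.layer3_dim, bn_momentum=self.bn_momentum,
            bn_eps=self.bn_eps,
        )

    # -- construction -------------------------------------------------
    def build(self, input_dim: int, vocab_size: int) -> "DeepMaxoutClassifier":
        """Initialize layers without training (Glorot uniform, seeded)."""
        if input_dim <= 0 or vocab_size <= 0:
            raise ValueError("input_dim and vocab_size must be positive")
        cfg = self._config()
        cfg.validate()
        rng = np.random.default_rng(cfg.seed)
        dims = [cfg.hidden_dim, cfg.hidden_dim,
                cfg.layer3_dim or cfg.hidden_dim]
        self.blocks_ = []
        prev = input_dim
        for dim_out in dims:
            self.blocks_.append(
                _MaxoutBlock(rng, prev, dim_out, cfg.maxout_pieces, cfg))
            prev = dim_out
        self.W_out_ = _glorot_uniform(rng, prev, vocab_size,
                                      (prev, vocab_size))
        self.b_out_ = np.zeros(vocab_size)
        self.input_dim_ = input_dim
        self.vocab_size_ = vocab_size
        self._rng = rng
        self.loss_curve_ = []
        return self

    # -- forward ------------------------------------------------------
    def _forward(self, X: np.ndarray, training: bool):
        h = X
        for blk in self.blocks_:
            h = blk.forward(h, training,
                            rng=self._rng if training else None)
        logits = h @ self.W_out_ + self.b_out_
        return h, logits

    @staticmethod
    def _sigmoid(z):
        return 1.0 / (1.0 + np.exp(-np.clip(z, -30, 30)))

    # -- training -----------------------------------------------------
    def fit(self, X, Y):
        X = np.asarray(X, dtype=float)
        Y = np.asarray(Y, dtype=float)
        if X.shape[0] != Y.shape[0]:
            raise ValueError(
                f"X has {X.shape[0]} rows but Y has {Y.shape[0]}")
        cfg = self._config()
        cfg.validate()
        self.build(X.shape[1], Y.shape[1])
        params = []
        for blk in self.blocks_:
            params.extend(blk.params())
        params.extend([self.W_out_, self.b_out_])
        accum = [np.zeros_like(p) for p in params]
        n = X.shape[0]
        rng = self._rng
        for epoch in range(cfg.epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            n_batches = 0
            for s in range(0, n, cfg.batch_size):
                idx = order[s:s + cfg.batch_size]
                xb, yb = X[idx], Y[idx]
                h3, logits = self._forward(xb, training=True)
                probs = self._sigmoid(logits)
                eps = 1e-12
                loss = -np.mean(np.sum(
                    yb * np.log(probs + eps)
                    + (1 - yb) * np.log(1 - probs + eps), axis=1))
                if not np.isfinite(loss):
                    raise TrainingDivergenceError(
                        f"NaN/Inf loss at epoch {epoch + 1}")
                epoch_loss += loss
                n_batches += 1
                grad_logits = (probs - yb) / len(idx)
                gW_out = h3.T @ grad_logits
                gb_out = grad_logits.sum(axis=0)
                grad_h = grad_logits @ self.W_out_.T
                grads_rev = []
                for blk in reversed(self.blocks_):
                    grad_h = blk.backward(grad_h)
                    grads_rev.append(blk.grads())
                grads = []
                for g in reversed(grads_rev):
                    grads.extend(g)
                grads.extend([gW_out, gb_out])
                # AdaGrad update
                for p, g, a in zip(params, grads, accum):
                    a += g * g
                    p -= cfg.learning_rate * g / (np.sqrt(a) + 1e-8)
            self.loss_curve_.append(epoch_loss / max(n_batches, 1))
        return self

    # -- inference ----------------------------------------------------
    def _check_input(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if not hasattr(self, "blocks_"):
            raise RuntimeError("model is not built/trained")
        if X.shape[1] != self.input_dim_:
            raise ValueError(
                f"input has {X.shape[1]} features, model expects "
                f"{self.input_dim_}")
        return X

    def predict_proba(self, X) -> np.ndarray:
        """Sigmoid posteriors, shape (n, vocab_size), values in (0, 1)."""
        X = self._check_input(X)
        _, logits = self._forward(X, training=False)
        return self._sigmoid(logits)

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X) >= 0.5).astype(int)

    def transform(self, X) -> np.ndarray:
        """Third hidden block's post-maxout activations (inference mode)."""
        X = self._check_input(X)
        h3, _ = self._forward(X, training=False)
        return h3


# ---------------------------------------------------------------------------
# spec-surface wrappers


def build_dmnn(input_dim: int, vocab_size: int,
               cfg: DMNNConfig | None = None) -> DeepMaxoutClassifier:
    cfg = cfg or DMNNConfig()
    model = DeepMaxoutClassifier(**_cfg_kwargs(cfg))
    return model.build(input_dim, vocab_size)


def _cfg_kwargs(cfg: DMNNConfig) -> dict:
    return dict(hidden_dim=cfg.hidden_dim, maxout_pieces=cfg.maxout_pieces,
                dropout_rate=cfg.dropout_rate,
                learning_rate=cfg.learning_rate, batch_size=cfg.batch_size,
                epochs=cfg.epochs, seed=cfg.seed, layer3_dim=cfg.layer3_dim,
                bn_momentum=cfg.bn_momentum, bn_eps=cfg.bn_eps)


def train_dmnn(model: DeepMaxoutClassifier, X: np.ndarray,
               Y: np.ndarray) -> DeepMaxoutClassifier:
    return model.fit(X, Y)


def extract_representation(model: DeepMaxoutClassifier,
                           X: EmbeddingMatrix) -> EmbeddingMatrix:
    """Functional representation: layer-3 activations with provenance."""
    vectors = model.transform(X.vectors)
    return EmbeddingMatrix(
        proteins=list(X.proteins), vectors=vectors, method="string2go",
        network=X.network,
        params={"source_method": X.method, "hidden_dim": vectors.shape[1]},
    )


def predict_sigmoid(model: DeepMaxoutClassifier, X: EmbeddingMatrix) -> np.ndarray:
    return model.predict_proba(X.vectors)


def _median_term_f1(Y_true: np.ndarray, Y_pred: np.ndarray) -> float:
    """Median over terms of F1 at the 0.5 decision threshold."""
    f1s = []
    for j in range(Y_true.shape[1]):
        t, p = Y_true[:, j], Y_pred[:, j]
        c = ConfusionCounts(
            tp=int(np.sum((t == 1) & (p == 1))),
            fp=int(np.sum((t == 0) & (p == 1))),
            fn=int(np.sum((t == 1) & (p == 0))),
            tn=int(np.sum((t == 0) & (p == 0))),
        )
        f1s.append(confusion_metrics(c)["f1"])
    f1s = sorted(f1s)
    return f1s[(len(f1s) - 1) // 2]  # lower median


def select_hidden_dim(candidates, X, Y, cfg: DMNNConfig | None = None,
                      folds: int = 10, seed: int = 0):
    """Choose the hidden width by cross-validated rounded median term F1.

    For each candidate width, k-fold CV (random split, seeded) produces
    out-of-fold sigmoid predictions; the median over terms of F1 at
    threshold 0.5 is rounded to two decimals.  The winner is the smallest
    candidate attaining the maximum rounded median.
    """
    from sklearn.model_selection import KFold

    candidates = sorted(set(candidates))
    if not candidates:
        raise ValueError("candidate set is empty")
    cfg = cfg or DMNNConfig()
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    report = {}
    for dim in candidates:
        kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
        oof = np.zeros_like(Y, dtype=float)
        for tr, va in kf.split(X):
            trial = DMNNConfig(**{**_cfg_kwargs(cfg), "hidden_dim": dim})
            model = DeepMaxoutClassifier(**_cfg_kwargs(trial))
            model.fit(X[tr], Y[tr])
            oof[va] = model.predict_proba(X[va])
        report[dim] = round(_median_term_f1(Y, (oof >= 0.5).astype(int)), 2)
    return pick_hidden_dim(report), report


def pick_hidden_dim(rounded_medians: dict[int, float]) -> int:
    """Smallest dimension among those attaining the maximum rounded median."""
    best = max(rounded_medians.values())
    return min(d for d, v in rounded_medians.items() if v == best)
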
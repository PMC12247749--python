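"""Attentive multilayer perceptron: cross-attention between patient-specific
features (query) and spectral feature blocks (keys/values).

The patient block (6 features) is encoded to a latent query; the harmonic
and ultra-harmonic 7-vectors are encoded to two tokens that serve as
keys/values.  Scaled dot-product attention produces a context vector which,
after a residual connection and layer normalization, feeds a sigmoid
classifier head.  Training uses weighted cross-entropy (positive-class
weight ``epsilon * N_total / N_pos``), first-order updates with adaptive
per-parameter step sizes (Adam), dropout, and L2 regularization; model
selection uses stratified K-fold cross-validation on the natural-ratio
training split.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .predict import (
    FEATURE_NAMES_20,
    ConfusionMetrics,
    Dataset,
    confusion_metrics,
)

__all__ = [
    "AMPConfig",
    "AMPModel",
    "AMPCVResult",
    "cross_attention",
    "weighted_ce",
    "positive_class_weight",
    "stratified_folds",
    "train_amp",
    "train_amp_cv",
]

_LN_EPS = 1e-5

# Column blocks within the 20-feature design matrix.
_UH_COLS = tuple(range(0, 7))
_H_COLS = tuple(range(7, 14))
_PATIENT_COLS = tuple(range(14, 20))


@dataclass(frozen=True)
class AMPConfig:
    d_model: int = 32
    patient_dim: int = 6
    frequency_dims: tuple[int, int] = (7, 7)
    epsilon: float = 2.0
    dropout: float = 0.1
    l2: float = 1e-4
    folds: int = 10
    epochs: int = 40
    batch_size: int = 256
    learning_rate: float = 0.01
    n_heads: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if self.n_heads != 1:
            raise NotImplementedError("only a single attention head is implemented")
        if not (0.0 <= self.dropout < 1.0):
            raise ValueError("dropout must be in [0, 1)")


def cross_attention(
    Q: np.ndarray, K: np.ndarray, V: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Scaled dot-product attention for a single query.

    Returns ``(context, weights)`` where ``context = softmax(Q K^T / sqrt(d)) V``.
    ``Q`` is (d,) or (1, d); ``K`` and ``V`` are (T, d).
    """
    q = np.asarray(Q, dtype=float).reshape(-1)
    K = np.atleast_2d(np.asarray(K, dtype=float))
    V = np.atleast_2d(np.asarray(V, dtype=float))
    d = q.size
    if K.shape[1] != d or V.shape[1] != d:
        raise ValueError(
            f"width mismatch: Q has d={d}, K is {K.shape}, V is {V.shape}"
        )
    if K.shape[0] != V.shape[0] or K.shape[0] < 1:
        raise ValueError("K and V must have the same (>=1) number of rows")
    scores = K @ q / math.sqrt(d)
    scores = scores - scores.max()
    w = np.exp(scores)
    w /= w.sum()
    return w @ V, w


def weighted_ce(p: float, y: int, w_pos: float) -> float:
    """Weighted cross-entropy ``-[w_pos * y * log p + (1-y) * log(1-p)]``."""
    if w_pos <= 0:
        raise ValueError("w_pos must be > 0")
    if y not in (0, 1):
        raise ValueError("y must be 0 or 1")
    if not (0.0 < p < 1.0):
        warnings.warn("probability outside (0,1); clamping at 1e-12", RuntimeWarning)
        p = min(max(p, 1e-12), 1.0 - 1e-12)
    return -(w_pos * y * math.log(p) + (1 - y) * math.log(1.0 - p))


def positive_class_weight(n_total: int, n_pos: int, epsilon: float = 2.0) -> float:
    """Default positive-class weight ``epsilon * N_total / N_pos``."""
    if n_pos <= 0:
        raise ValueError("n_pos must be > 0")
    return epsilon * n_total / n_pos


def _init_params(config: AMPConfig, rng: np.random.Generator) -> dict[str, np.ndarray]:
    d = config.d_model
    d1 = config.patient_dim
    dh, du = config.frequency_dims

    def glorot(shape):
        s = math.sqrt(6.0 / sum(shape))
        return rng.uniform(-s, s, size=shape)

    return {
        "Wp": glorot((d1, d)), "bp": np.zeros(d),
        "Wh": glorot((dh, d)), "bh": np.zeros(d),
        "Wu": glorot((du, d)), "bu": np.zeros(d),
        "Wq": glorot((d, d)), "Wk": glorot((d, d)), "Wv": glorot((d, d)),
        "gamma": np.ones(d), "beta": np.zeros(d),
        "wc": glorot((d,)), "bc": np.zeros(1),
    }


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    e = np.exp(z[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def _forward(
    params: dict[str, np.ndarray],
    P: np.ndarray,
    H: np.ndarray,
    U: np.ndarray,
    dropout: float = 0.0,
    rng: Optional[np.random.Generator] = None,
) -> tuple[np.ndarray, dict]:
    """Batched forward pass; returns probabilities and a cache for backprop."""
    d = params["Wq"].shape[0]
    q0 = np.tanh(P @ params["Wp"] + params["bp"])  # (N, d)
    th = np.tanh(H @ params["Wh"] + params["bh"])  # (N, d)
    tu = np.tanh(U @ params["Wu"] + params["bu"])  # (N, d)
    K0 = np.stack([th, tu], axis=1)  # (N, 2, d)
    Q = q0 @ params["Wq"]  # (N, d)
    Kr = K0 @ params["Wk"]  # (N, 2, d)
    Vr = K0 @ params["Wv"]  # (N, 2, d)
    scores = np.einsum("ntd,nd->nt", Kr, Q) / math.sqrt(d)  # (N, 2)
    scores = scores - scores.max(axis=1, keepdims=True)
    attn = np.exp(scores)
    attn /= attn.sum(axis=1, keepdims=True)
    ctx = np.einsum("nt,ntd->nd", attn, Vr)  # (N, d)
    z = q0 + ctx
    mu = z.mean(axis=1, keepdims=True)
    var = z.var(axis=1, keepdims=True)
    std = np.sqrt(var + _LN_EPS)
    zhat = (z - mu) / std
    ln = params["gamma"] * zhat + params["beta"]
    if dropout > 0.0:
        if rng is None:
            raise ValueError("dropout requires an rng")
        mask = (rng.random(ln.shape) >= dropout) / (1.0 - dropout)
    else:
        mask = np.ones_like(ln)
    ln_d = ln * mask
    logit = ln_d @ params["wc"] + params["bc"][0]
    prob = _sigmoid(logit)
    cache = dict(
        P=P, H=H, U=U, q0=q0, th=th, tu=tu, K0=K0, Q=Q, Kr=Kr, Vr=Vr,
        attn=attn, ctx=ctx, zhat=zhat, std=std, ln=ln, mask=mask,
        ln_d=ln_d, prob=prob, d=d,
    )
    return prob, cache


def _backward(
    params: dict[str, np.ndarray], cache: dict, dlogit: np.ndarray
) -> dict[str, np.ndarray]:
    """Gradients of the loss wrt all parameters given dL/dlogit (N,)."""
    d = cache["d"]
    grads: dict[str, np.ndarray] = {}
    grads["wc"] = cache["ln_d"].T @ dlogit
    grads["bc"] = np.array([dlogit.sum()])
    dln = (dlogit[:, None] * params["wc"]) * cache["mask"]
    grads["gamma"] = (dln * cache["zhat"]).sum(axis=0)
    grads["beta"] = dln.sum(axis=0)
    dzhat = dln * params["gamma"]
    m1 = dzhat.mean(axis=1, keepdims=True)
    m2 = (dzhat * cache["zhat"]).mean(axis=1, keepdims=True)
    dz = (dzhat - m1 - cache["zhat"] * m2) / cache["std"]
    dq0 = dz.copy()
    dctx = dz
    attn, Vr, Kr, Q = cache["attn"], cache["Vr"], cache["Kr"], cache["Q"]
    dattn = np.einsum("nd,ntd->nt", dctx, Vr)
    dVr = attn[:, :, None] * dctx[:, None, :]
    dscores = attn * (dattn - (dattn * attn).sum(axis=1, keepdims=True))
    dKr = dscores[:, :, None] * Q[:, None, :] / math.sqrt(d)
    dQ = np.einsum("nt,ntd->nd", dscores, Kr) / math.sqrt(d)
    grads["Wq"] = cache["q0"].T @ dQ
    dq0 += dQ @ params["Wq"].T
    K0 = cache["K0"]
    n = K0.shape[0]
    grads["Wk"] = K0.reshape(2 * n, d).T @ dKr.reshape(2 * n, d)
    grads["Wv"] = K0.reshape(2 * n, d).T @ dVr.reshape(2 * n, d)
    dK0 = dKr @ params["Wk"].T + dVr @ params["Wv"].T
    dth = dK0[:, 0, :] * (1.0 - cache["th"] ** 2)
    dtu = dK0[:, 1, :] * (1.0 - cache["tu"] ** 2)
    dq0pre = dq0 * (1.0 - cache["q0"] ** 2)
    grads["Wh"] = cache["H"].T @ dth
    grads["bh"] = dth.sum(axis=0)
    grads["Wu"] = cache["U"].T @ dtu
    grads["bu"] = dtu.sum(axis=0)
    grads["Wp"] = cache["P"].T @ dq0pre
    grads["bp"] = dq0pre.sum(axis=0)
    return grads


def _loss_and_dlogit(
    prob: np.ndarray, y: np.ndarray, w_pos: float
) -> tuple[float, np.ndarray]:
    p = np.clip(prob, 1e-12, 1.0 - 1e-12)
    n = y.size
    loss = float(
        -(w_pos * y * np.log(p) + (1.0 - y) * np.log(1.0 - p)).mean()
    )
    dlogit = (w_pos * y * (p - 1.0) + (1.0 - y) * p) / n
    return loss, dlogit


_L2_KEYS = ("Wp", "Wh", "Wu", "Wq", "Wk", "Wv", "wc")


@dataclass
class AMPModel:
    """Trained attention classifier with its feature scaler."""

    params: dict[str, np.ndarray]
    config: AMPConfig
    x_mean: np.ndarray
    x_sd: np.ndarray
    feature_names: tuple[str, ...] = FEATURE_NAMES_20
    threshold: float = 0.5

    def _blocks(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        Xs = (np.atleast_2d(np.asarray(X, dtype=float)) - self.x_mean) / self.x_sd
        return Xs[:, _PATIENT_COLS], Xs[:, _H_COLS], Xs[:, _UH_COLS]

    def forward(self, X: np.ndarray) -> np.ndarray:
        P, H, U = self._blocks(X)
        prob, _ = _forward(self.params, P, H, U, dropout=0.0)
        return prob

    def classify(self, X: np.ndarray) -> np.ndarray:
        return self.forward(X) >= self.threshold

    def attention_weights(self, X: np.ndarray) -> np.ndarray:
        P, H, U = self._blocks(X)
        _, cache = _forward(self.params, P, H, U, dropout=0.0)
        return cache["attn"]


def stratified_folds(
    y: np.ndarray, n_folds: int, seed: int = 0
) -> list[np.ndarray]:
    """Fold index arrays with per-class counts within +-1 of proportional."""
    y = np.asarray(y)
    rng = np.random.default_rng(seed)
    folds: list[list[int]] = [[] for _ in range(n_folds)]
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        if len(idx) < n_folds:
            raise ValueError(
                f"class {cls} has {len(idx)} samples < {n_folds} folds"
            )
        rng.shuffle(idx)
        for i, j in enumerate(idx):
            folds[i % n_folds].append(j)
    return [np.sort(np.array(f)) for f in folds]


def train_amp(
    X: np.ndarray,
    y: np.ndarray,
    config: AMPConfig,
    w_pos: Optional[float] = None,
    seed: Optional[int] = None,
) -> AMPModel:
    """Train one AMP on a 20-feature matrix with weighted cross-entropy."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.shape[1] != 20:
        raise ValueError("AMP expects the 20-feature design matrix")
    if w_pos is None:
        n_pos = int(y.sum())
        w_pos = positive_class_weight(y.size, max(n_pos, 1), config.epsilon)
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    params = _init_params(config, rng)
    x_mean = X.mean(axis=0)
    x_sd = X.std(axis=0, ddof=0)
    x_sd[x_sd < 1e-12] = 1.0
    Xs = (X - x_mean) / x_sd
    P, H, U = Xs[:, _PATIENT_COLS], Xs[:, _H_COLS], Xs[:, _UH_COLS]

    # Adam state
    m = {k: np.zeros_like(v) for k, v in params.items()}
    v = {k: np.zeros_like(vv) for k, vv in params.items()}
    b1, b2, eps = 0.9, 0.999, 1e-8
    step = 0
    n = y.size
    for _ in range(config.epochs):
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            sel = order[start : start + config.batch_size]
            prob, cache = _forward(
                params, P[sel], H[sel], U[sel],
                dropout=config.dropout, rng=rng,
            )
            _, dlogit = _loss_and_dlogit(prob, y[sel], w_pos)
            grads = _backward(params, cache, dlogit)
            step += 1
            for key in params:
                g = grads[key]
                if key in _L2_KEYS and config.l2 > 0:
                    g = g + config.l2 * params[key]
                m[key] = b1 * m[key] + (1 - b1) * g
                v[key] = b2 * v[key] + (1 - b2) * g * g
                mh = m[key] / (1 - b1**step)
                vh = v[key] / (1 - b2**step)
                params[key] = params[key] - config.learning_rate * mh / (
                    np.sqrt(vh) + eps
                )
    return AMPModel(
        params=params, config=config, x_mean=x_mean, x_sd=x_sd,
    )


@dataclass
class AMPCVResult:
    model: AMPModel
    fold_metrics: list[ConfusionMetrics] = field(default_factory=list)
    test_metrics: Optional[ConfusionMetrics] = None
    best_fold: int = -1


def train_amp_cv(dataset: Dataset, config: AMPConfig) -> AMPCVResult:
    """Stratified K-fold cross-validation on the natural-ratio data.

    The data are split 80/20 preserving the class ratio; each fold model is
    trained on the other folds of the 80% and scored on its own fold; the
    best model by (sensitivity, precision) is evaluated on the untouched
    20% test split.
    """
    from .predict import train_test_split  # local to avoid cycles at import

    if dataset.X.shape[1] != 20:
        raise ValueError("train_amp_cv expects the 20-feature dataset")
    train, test = train_test_split(dataset, 0.2, seed=config.seed)
    if train.n_positive == 0 or train.n_positive < config.folds:
        raise ValueError("too few positives to stratify across folds")
    w_pos = positive_class_weight(train.n, train.n_positive, config.epsilon)
    folds = stratified_folds(train.y, config.folds, seed=config.seed)
    models: list[AMPModel] = []
    metrics: list[ConfusionMetrics] = []
    for i, fold_idx in enumerate(folds):
        mask = np.ones(train.n, dtype=bool)
        mask[fold_idx] = False
        model = train_amp(
            train.X[mask], train.y[mask], config, w_pos=w_pos,
            seed=config.seed + 1000 + i,
        )
        metrics.append(
            confusion_metrics(model.classify(train.X[fold_idx]), train.y[fold_idx])
        )
        models.append(model)

    def score(m: ConfusionMetrics) -> tuple[float, float]:
        sens = m.sensitivity if math.isfinite(m.sensitivity) else -1.0
        prec = m.precision if math.isfinite(m.precision) else -1.0
        return (sens, prec)

    best = max(range(len(models)), key=lambda i: score(metrics[i]))
    best_model = models[best]
    test_metrics = confusion_metrics(best_model.classify(test.X), test.y)
    return AMPCVResult(
        model=best_model, fold_metrics=metrics,
        test_metrics=test_metrics, best_fold=best,
    )
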
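"""Broadband-emission safety predictor.

Dataset assembly pairs the features of pulse ``t`` with the event flag of
pulse ``t+1``.  The predictor is a 12-10-1 sigmoid multilayer perceptron
(141 trainable parameters) trained by Levenberg-Marquardt on mean squared
error after 1:1 under-sampling of the majority class inside the training
split.  Attribution uses a permutation-sampling Shapley estimator with
marginal replacement from a background sample.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence, Union

import numpy as np

from .simulate import SonicationRecord, SubjectModel
from .spectral import AEFrame

__all__ = [
    "FEATURE_NAMES_12",
    "FEATURE_NAMES_20",
    "PATIENT_FEATURES",
    "HARMONIC_FEATURES",
    "ULTRAHARMONIC_FEATURES",
    "Dataset",
    "MLPModel",
    "TrainConfig",
    "ConfusionMetrics",
    "ShapResult",
    "TrainingDivergedError",
    "mb_kinetics_trace",
    "features_from_frame",
    "build_dataset",
    "train_test_split",
    "undersample",
    "oversample",
    "train_mlp",
    "fit_predictor",
    "confusion_metrics",
    "shap_attributions",
    "mean_abs_shap",
    "top_k_features",
]

ULTRAHARMONIC_FEATURES = tuple(f"uh{k}" for k in range(1, 8))
HARMONIC_FEATURES = tuple(f"h{n}" for n in range(2, 9))
#: Patient-specific block (query side of the attention variant).
PATIENT_FEATURES = (
    "pressure",
    "target_x",
    "target_y",
    "mb_kinetics",
    "tumor",
    "pulse_number",
)

#: The 12-feature predictor input.
FEATURE_NAMES_12 = ULTRAHARMONIC_FEATURES + (
    "pressure",
    "target_x",
    "target_y",
    "mb_kinetics",
    "tumor",
)

#: The 20-feature design matrix used for attribution analysis.
FEATURE_NAMES_20 = (
    ULTRAHARMONIC_FEATURES
    + HARMONIC_FEATURES
    + ("pressure", "target_x", "target_y", "mb_kinetics", "tumor", "pulse_number")
)


class TrainingDivergedError(RuntimeError):
    pass


@dataclass
class Dataset:
    """Design matrix with next-pulse event labels."""

    X: np.ndarray
    y: np.ndarray
    feature_names: tuple[str, ...]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=np.int8)
        if self.X.ndim != 2 or self.y.ndim != 1 or len(self.X) != len(self.y):
            raise ValueError("X must be N x D and y length N")
        if self.X.shape[1] != len(self.feature_names):
            raise ValueError("feature_names must match X columns")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("features must be finite")

    @property
    def n(self) -> int:
        return len(self.y)

    @property
    def n_positive(self) -> int:
        return int(self.y.sum())

    def subset(self, idx: np.ndarray) -> "Dataset":
        return Dataset(self.X[idx], self.y[idx], self.feature_names, dict(self.provenance))


def mb_kinetics_trace(record: SonicationRecord) -> np.ndarray:
    """Online-computable microbubble-kinetics proxy per pulse.

    The tracking H4 level normalized by its running maximum, clipped to
    [0, 1] — the same quantity a controller can form in real time.
    """
    out = np.zeros(record.n_pulses)
    running_max = 0.0
    for i, frame in enumerate(record.frames):
        v = max(0.0, frame.h4_db)
        running_max = max(running_max, v)
        out[i] = min(1.0, v / running_max) if running_max > 1e-9 else 0.0
    return out


def features_from_frame(
    frame: AEFrame,
    mb_kinetics: float,
    subject: SubjectModel,
    feature_set: int = 12,
    pulse_number: Optional[int] = None,
) -> np.ndarray:
    """Feature vector for one pulse, in dataset column order."""
    base = list(frame.ultraharmonic_db)
    if feature_set == 12:
        tail = [
            frame.pressure_mpa,
            subject.target_x_mm,
            subject.target_y_mm,
            mb_kinetics,
            1.0 if subject.tumor else 0.0,
        ]
        return np.array(base + tail, dtype=float)
    if feature_set == 20:
        tail = list(frame.harmonic_db) + [
            frame.pressure_mpa,
            subject.target_x_mm,
            subject.target_y_mm,
            mb_kinetics,
            1.0 if subject.tumor else 0.0,
            float(pulse_number if pulse_number is not None else frame.pulse_index),
        ]
        return np.array(base + tail, dtype=float)
    raise ValueError(f"feature_set must be 12 or 20, got {feature_set}")


def build_dataset(
    records: Sequence[SonicationRecord], feature_set: int = 12
) -> Dataset:
    """Assemble the N x D matrix: row ``t`` carries pulse ``t``'s features
    and the label is pulse ``t+1``'s event flag (last pulse dropped)."""
    if len(records) == 0:
        raise ValueError("records must be non-empty")
    names = FEATURE_NAMES_12 if feature_set == 12 else FEATURE_NAMES_20
    if feature_set not in (12, 20):
        raise ValueError(f"feature_set must be 12 or 20, got {feature_set}")
    rows, labels = [], []
    for rec in records:
        if rec.n_pulses < 2:
            raise ValueError("each record needs at least 2 pulses")
        kin = mb_kinetics_trace(rec)
        frames = rec.frames
        for t in range(rec.n_pulses - 1):
            rows.append(
                features_from_frame(
                    frames[t],
                    kin[t],
                    rec.subject,
                    feature_set=feature_set,
                    pulse_number=t + 1,
                )
            )
            labels.append(1 if frames[t + 1].is_event else 0)
    prov = {
        "n_records": len(records),
        "seeds": [rec.seed for rec in records],
        "feature_set": feature_set,
    }
    return Dataset(np.array(rows), np.array(labels), names, prov)


def train_test_split(
    dataset: Dataset, test_fraction: float = 0.2, seed: int = 0
) -> tuple[Dataset, Dataset]:
    """Stratified random split preserving the class ratio in both parts."""
    if not (0.0 < test_fraction < 1.0):
        raise ValueError("test_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    test_idx = []
    for cls in (0, 1):
        idx = np.flatnonzero(dataset.y == cls)
        rng.shuffle(idx)
        n_test = int(round(test_fraction * len(idx)))
        test_idx.append(idx[:n_test])
    test_mask = np.zeros(dataset.n, dtype=bool)
    test_mask[np.concatenate(test_idx)] = True
    return dataset.subset(~test_mask), dataset.subset(test_mask)


def undersample(dataset: Dataset, rng: np.random.Generator) -> Dataset:
    """Balance 1:1 by keeping all positives and sampling an equal number of
    negatives without replacement (apply to the training split only)."""
    pos = np.flatnonzero(dataset.y == 1)
    neg = np.flatnonzero(dataset.y == 0)
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be present to under-sample")
    if len(neg) < len(pos):
        raise ValueError("fewer negatives than positives; nothing to under-sample")
    chosen = rng.choice(neg, size=len(pos), replace=False)
    idx = np.concatenate([pos, chosen])
    rng.shuffle(idx)
    return dataset.subset(idx)


def oversample(dataset: Dataset, rng: np.random.Generator) -> Dataset:
    """Alternative balancing: duplicate positives (with replacement) up to
    the negative count.  Same interface as :func:`undersample`."""
    pos = np.flatnonzero(dataset.y == 1)
    neg = np.flatnonzero(dataset.y == 0)
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be present to over-sample")
    extra = rng.choice(pos, size=max(0, len(neg) - len(pos)), replace=True)
    idx = np.concatenate([pos, extra, neg])
    rng.shuffle(idx)
    return dataset.subset(idx)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    e = np.exp(z[~pos])
    out[~pos] = e / (1.0 + e)
    return out


@dataclass
class MLPModel:
    """12-10-1 sigmoid network with stored feature scaler and threshold."""

    W1: np.ndarray  # (hidden, in)
    b1: np.ndarray  # (hidden,)
    w2: np.ndarray  # (hidden,)
    b2: float
    x_mean: np.ndarray
    x_sd: np.ndarray
    feature_names: tuple[str, ...]
    threshold: float = 0.5

    @property
    def n_params(self) -> int:
        return self.W1.size + self.b1.size + self.w2.size + 1

    def forward(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.W1.shape[1]:
            raise ValueError(
                f"expected {self.W1.shape[1]} features, got {X.shape[1]}"
            )
        Z = (X - self.x_mean) / self.x_sd
        H = _sigmoid(Z @ self.W1.T + self.b1)
        return _sigmoid(H @ self.w2 + self.b2)

    def predict(self, x: np.ndarray) -> tuple[float, bool]:
        """Probability and the thresholded call (>= threshold is positive)."""
        x = np.asarray(x, dtype=float)
        if x.ndim != 1:
            raise ValueError("predict takes a single feature vector")
        if not np.all(np.isfinite(x)):
            raise ValueError("features must be finite")
        p = float(self.forward(x[None, :])[0])
        return p, p >= self.threshold

    def classify(self, X: np.ndarray) -> np.ndarray:
        return self.forward(X) >= self.threshold


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 1000
    learning_rate: float = 0.01  # initial LM damping
    test_fraction: float = 0.2
    sampling: str = "under"  # under | over
    seed: int = 0
    grad_tol: float = 1e-7
    max_damping: float = 1e10
    validation_fraction: float = 0.2  # early-stopping split inside the train set
    max_fail: int = 6  # consecutive validation failures before stopping
    n_restarts: int = 3  # weight re-initializations; best validation SSE wins

    def __post_init__(self) -> None:
        if not (0 < self.epochs <= 1000):
            raise ValueError("epochs must be in 1..1000")
        if self.sampling not in ("under", "over"):
            raise ValueError("sampling must be 'under' or 'over'")


def _forward_parts(
    theta: np.ndarray, Xs: np.ndarray, hidden: int
) -> tuple[np.ndarray, np.ndarray]:
    d = Xs.shape[1]
    W1 = theta[: hidden * d].reshape(hidden, d)
    b1 = theta[hidden * d : hidden * d + hidden]
    w2 = theta[hidden * d + hidden : hidden * d + 2 * hidden]
    b2 = theta[-1]
    H = _sigmoid(Xs @ W1.T + b1)
    f = _sigmoid(H @ w2 + b2)
    return H, f


def _jacobian(
    theta: np.ndarray, Xs: np.ndarray, hidden: int
) -> tuple[np.ndarray, np.ndarray]:
    """Exact Jacobian of the network output wrt all parameters."""
    n, d = Xs.shape
    w2 = theta[hidden * d + hidden : hidden * d + 2 * hidden]
    H, f = _forward_parts(theta, Xs, hidden)
    df = f * (1.0 - f)  # (n,)
    dH = H * (1.0 - H)  # (n, hidden)
    # d f / d z1_j = df * w2_j * dH_j
    g1 = df[:, None] * dH * w2[None, :]  # (n, hidden)
    J_W1 = g1[:, :, None] * Xs[:, None, :]  # (n, hidden, d)
    J = np.concatenate(
        [
            J_W1.reshape(n, hidden * d),
            g1,  # b1
            df[:, None] * H,  # w2
            df[:, None],  # b2
        ],
        axis=1,
    )
    return J, f


def train_mlp(
    train: Dataset, config: TrainConfig, hidden: int = 10
) -> tuple[MLPModel, dict]:
    """Train with ``config.n_restarts`` re-initializations.

    The safety predictor must above all not miss events, so the restart
    with the best validation sensitivity wins (ties broken by validation
    SSE); without a validation split the lowest training SSE wins.
    """
    best: Optional[tuple[tuple[float, float], MLPModel, dict]] = None
    for restart in range(max(1, config.n_restarts)):
        cfg = dataclasses.replace(config, seed=config.seed + 7717 * restart)
        model, history = _train_mlp_once(train, cfg, hidden)
        if "val_sensitivity" in history:
            score = (-history["val_sensitivity"], history["best_val_sse"])
        else:
            score = (0.0, history["sse"][-1])
        if best is None or score < best[0]:
            best = (score, model, history)
    assert best is not None
    return best[1], best[2]


def _train_mlp_once(
    train: Dataset, config: TrainConfig, hidden: int = 10
) -> tuple[MLPModel, dict]:
    """Levenberg-Marquardt on the full exact Jacobian, minimizing MSE.

    Multiplicative damping starts at ``config.learning_rate``; an accepted
    step divides it by 10, a rejected step multiplies it by 10.  Stops at
    the epoch cap, on a small gradient, on damping overflow, or — when
    ``config.validation_fraction > 0`` — after ``config.max_fail``
    consecutive validation-error increases (the best-validation weights
    are restored).
    """
    X, y = train.X, train.y.astype(float)
    x_mean = X.mean(axis=0)
    x_sd = X.std(axis=0, ddof=0)
    x_sd[x_sd < 1e-12] = 1.0
    Xall = (X - x_mean) / x_sd

    rng = np.random.default_rng(config.seed)
    n_all = len(Xall)
    if config.validation_fraction > 0 and n_all >= 10:
        n_val = max(1, int(round(config.validation_fraction * n_all)))
        order = rng.permutation(n_all)
        val_idx, fit_idx = order[:n_val], order[n_val:]
        Xs, ys = Xall[fit_idx], y[fit_idx]
        Xv, yv = Xall[val_idx], y[val_idx]
    else:
        Xs, ys = Xall, y
        Xv = yv = None
    n, d = Xs.shape

    n_theta = hidden * d + 2 * hidden + 1
    theta = rng.uniform(-0.5, 0.5, size=n_theta)

    mu = config.learning_rate
    _, f = _forward_parts(theta, Xs, hidden)
    sse = float(np.sum((ys - f) ** 2))
    history = {"sse": [sse], "mu": [mu], "val_sse": [], "stop": "epoch_cap"}
    eye = np.eye(n_theta)
    best_theta, best_val, fails = theta.copy(), math.inf, 0

    for epoch in range(config.epochs):
        J, f = _jacobian(theta, Xs, hidden)
        r = ys - f
        g = J.T @ r
        if not math.isfinite(sse):
            raise TrainingDivergedError(f"non-finite loss at epoch {epoch}")
        if np.max(np.abs(g)) < config.grad_tol:
            history["stop"] = "gradient"
            break
        JtJ = J.T @ J
        accepted = False
        while mu <= config.max_damping:
            try:
                delta = np.linalg.solve(JtJ + mu * eye, g)
            except np.linalg.LinAlgError:
                mu *= 10.0
                continue
            theta_new = theta + delta
            _, f_new = _forward_parts(theta_new, Xs, hidden)
            sse_new = float(np.sum((ys - f_new) ** 2))
            if math.isfinite(sse_new) and sse_new < sse:
                theta, sse = theta_new, sse_new
                mu = max(mu * 0.1, 1e-12)
                accepted = True
                break
            mu *= 10.0
        history["sse"].append(sse)
        history["mu"].append(mu)
        if not accepted:
            history["stop"] = "damping_overflow"
            break
        if Xv is not None:
            _, fv = _forward_parts(theta, Xv, hidden)
            val_sse = float(np.sum((yv - fv) ** 2))
            history["val_sse"].append(val_sse)
            if val_sse < best_val:
                best_val, fails = val_sse, 0
                best_theta = theta.copy()
            else:
                fails += 1
                if fails >= config.max_fail:
                    history["stop"] = "validation"
                    break
    if Xv is not None and math.isfinite(best_val):
        theta = best_theta
        history["best_val_sse"] = best_val / len(Xv)
        _, fv = _forward_parts(theta, Xv, hidden)
        pos = yv > 0.5
        if pos.any():
            history["val_sensitivity"] = float(np.mean(fv[pos] >= 0.5))

    W1 = theta[: hidden * d].reshape(hidden, d)
    b1 = theta[hidden * d : hidden * d + hidden]
    w2 = theta[hidden * d + hidden : hidden * d + 2 * hidden]
    b2 = float(theta[-1])
    model = MLPModel(
        W1=W1,
        b1=b1,
        w2=w2,
        b2=b2,
        x_mean=x_mean,
        x_sd=x_sd,
        feature_names=train.feature_names,
    )
    return model, history


def fit_predictor(
    dataset: Dataset, config: TrainConfig
) -> tuple[MLPModel, "ConfusionMetrics", "ConfusionMetrics", Dataset, Dataset]:
    """80/20 split, balance the training split, train, evaluate.

    Returns (model, balanced-train metrics, natural-ratio test metrics,
    balanced train set, test set).
    """
    train, test = train_test_split(dataset, config.test_fraction, seed=config.seed)
    rng = np.random.default_rng(config.seed + 1)
    balanced = (undersample if config.sampling == "under" else oversample)(train, rng)
    model, _ = train_mlp(balanced, config)
    m_train = confusion_metrics(model.classify(balanced.X), balanced.y)
    m_test = confusion_metrics(model.classify(test.X), test.y)
    return model, m_train, m_test, balanced, test


@dataclass(frozen=True)
class ConfusionMetrics:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def _ratio(self, num: int, den: int, name: str) -> float:
        if den == 0:
            warnings.warn(f"{name} undefined (zero denominator)", RuntimeWarning)
            return float("nan")
        return num / den

    @property
    def accuracy(self) -> float:
        return self._ratio(self.tp + self.tn, self.n, "accuracy")

    @property
    def sensitivity(self) -> float:
        return self._ratio(self.tp, self.tp + self.fn, "sensitivity")

    @property
    def precision(self) -> float:
        return self._ratio(self.tp, self.tp + self.fp, "precision")

    @property
    def specificity(self) -> float:
        return self._ratio(self.tn, self.tn + self.fp, "specificity")


def confusion_metrics(
    predictions: Sequence[Union[bool, int]], labels: Sequence[Union[bool, int]]
) -> ConfusionMetrics:
    """Confusion counts and derived rates from binary sequences."""
    p = np.asarray(predictions).astype(bool)
    t = np.asarray(labels).astype(bool)
    if p.size == 0:
        raise ValueError("empty input")
    if p.shape != t.shape:
        raise ValueError("predictions and labels must have equal length")
    return ConfusionMetrics(
        tp=int(np.sum(p & t)),
        fp=int(np.sum(p & ~t)),
        tn=int(np.sum(~p & ~t)),
        fn=int(np.sum(~p & t)),
    )


@dataclass
class ShapResult:
    """Per-feature attributions for one input (model-output units)."""

    phi: np.ndarray
    base_value: float
    feature_names: Optional[tuple[str, ...]] = None

    def local_accuracy_residual(self, fx: float) -> float:
        return float(abs(fx - self.base_value - self.phi.sum()))


ModelLike = Union[MLPModel, Callable[[np.ndarray], np.ndarray]]


def _as_callable(model: ModelLike) -> Callable[[np.ndarray], np.ndarray]:
    if isinstance(model, MLPModel):
        return model.forward
    return model


def shap_attributions(
    model: ModelLike,
    x: np.ndarray,
    background: Union[np.ndarray, Dataset],
    n_samples: int = 2000,
    seed: int = 0,
) -> ShapResult:
    """Permutation-sampling Shapley values with marginal replacement.

    Each sample draws a feature permutation and a background row, then
    walks the permutation switching features from background to ``x``,
    crediting each feature with the model-output change.  The telescoping
    sums make local accuracy exact for the sampled base value.
    """
    f = _as_callable(model)
    x = np.asarray(x, dtype=float).ravel()
    B = background.X if isinstance(background, Dataset) else np.asarray(background)
    names = background.feature_names if isinstance(background, Dataset) else None
    if B.ndim != 2 or len(B) == 0:
        raise ValueError("background must be a non-empty 2-D array")
    d = x.size
    if B.shape[1] != d:
        raise ValueError("background width must match x")
    if n_samples < 2 * d:
        raise ValueError(f"n_samples must be >= 2*D = {2 * d}, got {n_samples}")
    rng = np.random.default_rng(seed)

    # One chain of d+1 evaluation points per sampled permutation: start at
    # the background row, switch features to x in permutation order.
    perms = np.argsort(rng.random((n_samples, d)), axis=1)
    ranks = np.argsort(perms, axis=1)  # rank[s, f] = position of f in perm s
    Z = B[rng.integers(len(B), size=n_samples)].astype(float)
    steps = np.arange(d + 1)
    rows = np.where(
        ranks[:, None, :] < steps[None, :, None], x[None, None, :], Z[:, None, :]
    )
    vals = np.asarray(f(rows.reshape(-1, d)), dtype=float).reshape(n_samples, d + 1)
    diffs = np.diff(vals, axis=1)  # (n_samples, d) in permutation order
    phi = np.bincount(perms.ravel(), weights=diffs.ravel(), minlength=d) / n_samples
    base = float(vals[:, 0].mean())
    return ShapResult(phi=phi, base_value=base, feature_names=names)


def mean_abs_shap(results: Sequence[ShapResult]) -> np.ndarray:
    """Global importance: mean |phi| per feature over many explanations."""
    if len(results) == 0:
        raise ValueError("no shap results")
    return np.mean([np.abs(r.phi) for r in results], axis=0)


def top_k_features(
    results: Sequence[ShapResult], k: int = 7
) -> list[tuple[int, str, float]]:
    """Top-k features by mean |phi|, descending; ties break by index.

    Returns (feature index, name, importance) triples.
    """
    imp = mean_abs_shap(results)
    if k > imp.size:
        raise ValueError(f"k={k} exceeds feature count {imp.size}")
    names = results[0].feature_names or tuple(
        f"f{i}" for i in range(imp.size)
    )
    order = sorted(range(imp.size), key=lambda i: (-imp[i], i))[:k]
    return [(i, names[i], float(imp[i])) for i in order]
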
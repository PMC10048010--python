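"""Feed-forward sigmoidal classifier with weight decay, trained by SGD.

A single hidden layer of logistic units feeding one logistic output unit;
the loss is binary cross-entropy plus an L2 weight-decay penalty, minimized
by seeded stochastic gradient descent over shuffled minibatches.  The
learning rate is halved (and the epoch reverted) whenever the full-data loss
increases, so the recorded loss history is non-increasing.  Hyperparameters
(hidden size, decay) are tuned by stratified k-fold cross-validation; the
set-aside split holds out a test partition with exact per-class counts.

The positive class is "female" throughout, matching the confusion-matrix
conventions of the evaluation module.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .errors import DegenerateTrainingError, InvalidInputError, SchemaError

POSITIVE_CLASS = "F"


def _as_matrix(x) -> Tuple[np.ndarray, Optional[List[str]]]:
    if hasattr(x, "table"):  # PredictorTable
        return x.table.to_numpy(dtype=float), list(x.table.columns)
    if isinstance(x, pd.DataFrame):
        return x.to_numpy(dtype=float), list(x.columns)
    arr = np.atleast_2d(np.asarray(x, dtype=float))
    return arr, None


def _as_binary(y, positive: str = POSITIVE_CLASS) -> np.ndarray:
    arr = np.asarray(y)
    if arr.dtype.kind in "ifb":
        out = arr.astype(float)
        if not np.all(np.isin(out, (0.0, 1.0))):
            raise InvalidInputError("numeric labels must be 0/1")
        return out
    return (arr.astype(str) == positive).astype(float)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


@dataclass
class AnnModel:
    """A trained network: sizes, weights, and the training metadata needed
    to reproduce the fit."""

    hidden: int
    decay: float
    w1: np.ndarray
    b1: np.ndarray
    w2: np.ndarray
    b2: np.ndarray
    feature_names: Optional[List[str]]
    learning_rate: float
    epochs: int
    batch_size: int
    seed: int
    loss_history: np.ndarray
    training_accuracy: float
    positive_class: str = POSITIVE_CLASS

    @property
    def n_features(self) -> int:
        return self.w1.shape[0]

    def forward(self, x: np.ndarray) -> np.ndarray:
        h = _sigmoid(x @ self.w1 + self.b1)
        p = _sigmoid(h @ self.w2 + self.b2)
        return np.clip(p[:, 0], 1e-12, 1.0 - 1e-12)


def _loss(model_w, x, y, decay):
    """Total objective: summed cross-entropy + decay * sum of squared weights
    (the nnet/caret convention, under which decay=0.1 is a mild penalty)."""
    w1, b1, w2, b2 = model_w
    h = _sigmoid(x @ w1 + b1)
    p = np.clip(_sigmoid(h @ w2 + b2)[:, 0], 1e-12, 1.0 - 1e-12)
    bce = -np.sum(y * np.log(p) + (1 - y) * np.log(1 - p))
    return bce + decay * (np.sum(w1**2) + np.sum(w2**2))


def train_ann(
    x,
    y,
    hidden: int = 3,
    decay: float = 0.1,
    learning_rate: float = 0.05,
    epochs: int = 500,
    batch_size: int = 8,
    seed: int = 0,
    positive: str = POSITIVE_CLASS,
) -> AnnModel:
    """Train the sigmoidal network by seeded minibatch SGD.

    Deterministic: the same seed and data give bitwise-identical weights.
    Raises :class:`DegenerateTrainingError` if only one class is present.
    """
    xm, names = _as_matrix(x)
    yb = _as_binary(y, positive)
    if xm.shape[0] != yb.shape[0]:
        raise InvalidInputError("X and y lengths differ")
    if not np.all(np.isfinite(xm)):
        raise InvalidInputError("missing or non-finite values in predictors")
    if len(np.unique(yb)) < 2:
        raise DegenerateTrainingError("training labels contain a single class")
    if hidden < 1 or decay < 0 or learning_rate <= 0 or epochs < 1 or batch_size < 1:
        raise InvalidInputError("invalid training hyperparameters")

    n, p = xm.shape
    rng = np.random.default_rng(seed)
    w1 = rng.uniform(-0.7, 0.7, size=(p, hidden)) / np.sqrt(p)
    b1 = rng.uniform(-0.7, 0.7, size=hidden)
    w2 = rng.uniform(-0.7, 0.7, size=(hidden, 1)) / np.sqrt(hidden)
    b2 = rng.uniform(-0.7, 0.7, size=1)

    lr = learning_rate
    prev = _loss((w1, b1, w2, b2), xm, yb, decay)
    history = [prev]
    for _ in range(epochs):
        snap = (w1.copy(), b1.copy(), w2.copy(), b2.copy())
        order = rng.permutation(n)
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            xb, tb = xm[idx], yb[idx]
            h = _sigmoid(xb @ w1 + b1)
            pr = _sigmoid(h @ w2 + b2)
            dz2 = (pr - tb[:, None]) / len(idx)
            dw2 = h.T @ dz2 + (2 * decay / n) * w2
            db2 = dz2.sum(axis=0)
            dh = dz2 @ w2.T
            dz1 = dh * h * (1 - h)
            dw1 = xb.T @ dz1 + (2 * decay / n) * w1
            db1 = dz1.sum(axis=0)
            w1 -= lr * dw1
            b1 -= lr * db1
            w2 -= lr * dw2
            b2 -= lr * db2
        loss = _loss((w1, b1, w2, b2), xm, yb, decay)
        if loss > prev:
            w1, b1, w2, b2 = snap  # revert and halve the learning rate
            lr *= 0.5
            history.append(prev)
            if lr < 1e-12:
                break
        else:
            prev = loss
            history.append(loss)

    model = AnnModel(
        hidden=hidden,
        decay=decay,
        w1=w1,
        b1=b1,
        w2=w2,
        b2=b2,
        feature_names=names,
        learning_rate=learning_rate,
        epochs=epochs,
        batch_size=batch_size,
        seed=seed,
        loss_history=np.asarray(history),
        training_accuracy=0.0,
        positive_class=positive,
    )
    proba = model.forward(xm)
    model.training_accuracy = float(np.mean((proba >= 0.5) == (yb == 1.0)))
    return model


def predict_sex(model: AnnModel, x) -> Tuple[np.ndarray, np.ndarray]:
    """Probability of the positive class ("female") and the 0.5-threshold
    label per specimen.  A probability of exactly 0.5 classifies positive."""
    xm, names = _as_matrix(x)
    if names is not None and model.feature_names is not None:
        if names != model.feature_names:
            raise SchemaError("predictor columns do not match the training layout")
    if xm.shape[1] != model.n_features:
        raise SchemaError(
            f"model expects {model.n_features} predictors, got {xm.shape[1]}"
        )
    proba = model.forward(xm)
    negative = "M" if model.positive_class == "F" else "other"
    labels = np.where(proba >= 0.5, model.positive_class, negative)
    return proba, labels


@dataclass
class CvResult:
    """Cross-validation grid results and the selected candidate."""

    candidates: List[Dict]
    mean_accuracy: np.ndarray
    sd_accuracy: np.ndarray
    fold_accuracy: np.ndarray
    selected_index: int

    @property
    def selected(self) -> Dict:
        return self.candidates[self.selected_index]


def cross_validate(
    x,
    y,
    grid: Sequence,
    k: int = 10,
    seed: int = 0,
    positive: str = POSITIVE_CLASS,
    **train_kwargs,
) -> CvResult:
    """Stratified k-fold accuracy for each (hidden, decay) candidate.

    Selects the candidate with maximal mean held-out accuracy; ties break
    toward the smallest hidden size, then the smallest decay.
    """
    xm, _ = _as_matrix(x)
    yb = _as_binary(y, positive)
    n = xm.shape[0]
    if k < 2:
        raise InvalidInputError("k must be >= 2")
    if k > n:
        raise InvalidInputError(f"k={k} exceeds the number of specimens ({n})")
    candidates = []
    for cand in grid:
        if isinstance(cand, Mapping):
            candidates.append({"hidden": int(cand["hidden"]), "decay": float(cand["decay"])})
        else:
            h, d = cand
            candidates.append({"hidden": int(h), "decay": float(d)})
    if not candidates:
        raise InvalidInputError("empty candidate grid")

    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed % 2**32)
    folds = list(skf.split(xm, yb))
    acc = np.zeros((len(candidates), k))
    for ci, cand in enumerate(candidates):
        for fi, (tr, va) in enumerate(folds):
            model = train_ann(
                xm[tr],
                yb[tr],
                hidden=cand["hidden"],
                decay=cand["decay"],
                seed=(seed * 100003 + fi * 101 + ci * 13) % 2**31,
                positive=positive,
                **train_kwargs,
            )
            proba = model.forward(xm[va])
            acc[ci, fi] = np.mean((proba >= 0.5) == (yb[va] == 1.0))
    mean = acc.mean(axis=1)
    sd = acc.std(axis=1, ddof=1) if k > 1 else np.zeros(len(candidates))
    order = sorted(
        range(len(candidates)),
        key=lambda i: (-mean[i], candidates[i]["hidden"], candidates[i]["decay"]),
    )
    return CvResult(
        candidates=candidates,
        mean_accuracy=mean,
        sd_accuracy=sd,
        fold_accuracy=acc,
        selected_index=order[0],
    )


@dataclass
class SplitPlan:
    """A set-aside partition with exact per-class counts."""

    train_ids: List[str]
    test_ids: List[str]
    train_counts: Dict[str, int]
    test_counts: Dict[str, int]
    seed: int


def set_aside_split(
    labels: Mapping[str, str], train_counts: Mapping[str, int], seed: int
) -> SplitPlan:
    """Randomly draw a training partition honoring exact per-class counts.

    ``labels`` maps specimen id -> class; the complement of the training draw
    is the test partition.  Reproducible under ``seed``.
    """
    if isinstance(labels, pd.Series):
        labels = labels.to_dict()
    ids = list(labels)
    rng = np.random.default_rng(seed)
    train: List[str] = []
    for cls in sorted(train_counts):
        pool = [s for s in ids if labels[s] == cls]
        want = int(train_counts[cls])
        if want < 0 or want > len(pool):
            raise InvalidInputError(
                f"requested {want} training specimens of class {cls!r}, "
                f"only {len(pool)} available"
            )
        chosen = rng.choice(len(pool), size=want, replace=False)
        train.extend(pool[i] for i in sorted(chosen))
    train_set = set(train)
    test = [s for s in ids if s not in train_set]
    train = [s for s in ids if s in train_set]

    def counts(group):
        out: Dict[str, int] = {}
        for s in group:
            out[labels[s]] = out.get(labels[s], 0) + 1
        return out

    return SplitPlan(
        train_ids=train,
        test_ids=test,
        train_counts=counts(train),
        test_counts=counts(test),
        seed=seed,
    )


def predictor_importance(model: AnnModel, names: Optional[Sequence[str]] = None) -> pd.Series:
    """Garson connection-weight importance, rescaled so the maximum is 100.

    For each hidden unit the absolute input weights are normalized to
    fractions and weighted by the absolute hidden-to-output weight; summing
    over hidden units gives a nonnegative score per predictor.
    """
    if names is None:
        names = model.feature_names or [f"x{i + 1}" for i in range(model.n_features)]
    if len(names) != model.n_features:
        raise InvalidInputError("names length does not match the predictor count")
    aw1 = np.abs(model.w1)  # (p, h)
    denom = aw1.sum(axis=0)
    frac = np.divide(aw1, denom, out=np.zeros_like(aw1), where=denom > 0)
    raw = frac @ np.abs(model.w2[:, 0])
    top = raw.max()
    scaled = raw * (100.0 / top) if top > 0 else raw
    return pd.Series(scaled, index=list(names)).sort_values(ascending=False)
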
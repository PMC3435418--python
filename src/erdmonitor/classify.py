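"""Quadratically-regularized linear logistic regression (rLLR) and the
evaluation protocols built on it.

The classifier minimizes the penalized negative log-likelihood

    NLL(w, b) = Σ_i log(1 + exp(−y_i (w·x_i + b))) + (λ/2)‖w‖²

(y ∈ {−1, +1}; the offset b is not penalized), a strictly convex problem
solved by Newton iterations with step halving.  The class probability is
P(movement | x) = 1 / (1 + exp(−(w·x + b))).  Features are z-scored with
statistics estimated on the training set only, so cross-validation and
block-calibration evaluation are leakage-free.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.stats

from .containers import FeatureMatrix, MOVEMENT

__all__ = [
    "RLLRModel",
    "EvalResult",
    "train_rllr",
    "predict_proba",
    "predict",
    "crossvalidate",
    "block_calibration_eval",
    "chance_threshold",
    "select_lambda",
    "penalized_nll_grad",
]


@dataclass
class RLLRModel:
    """Fitted rLLR: weights, offset and the training standardization."""

    w: np.ndarray
    b: float
    lam: float
    mean: np.ndarray
    scale: np.ndarray
    feature_index: list | None = None
    n_iter: int = 0
    trained: bool = False

    def to_dict(self) -> dict:
        return {
            "w": self.w.tolist(),
            "b": self.b,
            "lambda": self.lam,
            "mean": self.mean.tolist(),
            "scale": self.scale.tolist(),
            "feature_index": [
                [ch, list(band), period] for ch, band, period in (self.feature_index or [])
            ],
            "n_iter": self.n_iter,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RLLRModel":
        idx = [(ch, tuple(band), period) for ch, band, period in d.get("feature_index") or []]
        return cls(
            np.asarray(d["w"], dtype=float), float(d["b"]), float(d["lambda"]),
            np.asarray(d["mean"], dtype=float), np.asarray(d["scale"], dtype=float),
            idx or None, int(d.get("n_iter", 0)), True,
        )


@dataclass
class EvalResult:
    """Classification outcome of one evaluation protocol."""

    rate: float
    per_split: dict
    n_test: int
    confusion: np.ndarray  # rows: true (no-movement, movement); cols: predicted

    @property
    def se(self) -> float:
        """Binomial standard error of the pooled rate."""
        return float(np.sqrt(self.rate * (1 - self.rate) / max(self.n_test, 1)))


def _as_xy(features, labels=None):
    if isinstance(features, FeatureMatrix):
        X = features.values
        y = (features.labels == MOVEMENT).astype(int)
    else:
        X = np.asarray(features, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        y = np.asarray(labels)
        if y.dtype.kind in "US":
            y = (y == MOVEMENT).astype(int)
        y = y.astype(int)
    return X, y


def penalized_nll_grad(wb: np.ndarray, X: np.ndarray, y: np.ndarray, lam: float):
    """Penalized NLL and its gradient at ``wb = [w, b]`` (y ∈ {0,1}).

    Exposed so the analytic gradient can be checked against finite
    differences.
    """
    w, b = wb[:-1], wb[-1]
    f = X @ w + b
    # log(1+exp(-s*f)) with s = ±1, stable via logaddexp
    s = 2.0 * y - 1.0
    nll = np.logaddexp(0.0, -s * f).sum() + 0.5 * lam * w @ w
    p = scipy.stats.logistic.cdf(f)
    r = p - y
    grad = np.concatenate([X.T @ r + lam * w, [r.sum()]])
    return nll, grad


def _standardize_fit(X: np.ndarray):
    mean = X.mean(axis=0)
    scale = X.std(axis=0, ddof=0)
    scale = np.where(scale > 0, scale, 1.0)
    return mean, scale


def train_rllr(
    features,
    labels=None,
    lam: float = 1.0,
    tol: float = 1e-8,
    max_iter: int = 1000,
    standardize: bool = True,
    feature_index=None,
    init: np.ndarray | None = None,
) -> RLLRModel:
    """Fit the rLLR by Newton iterations with step halving.

    Convergence: relative change of the penalized NLL below *tol* (or a
    vanishing Newton decrement).  The problem is convex, so the optimum is
    unique and independent of the start (``init``, default zeros, is the
    starting point ``[w, b]`` in standardized coordinates).
    """
    X, y = _as_xy(features, labels)
    if not np.all(np.isfinite(X)):
        raise ValueError("features contain non-finite values")
    if len(np.unique(y)) < 2:
        raise ValueError("need at least one trial of each class")
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    if isinstance(features, FeatureMatrix) and feature_index is None:
        feature_index = features.index

    if standardize:
        mean, scale = _standardize_fit(X)
    else:
        mean = np.zeros(X.shape[1])
        scale = np.ones(X.shape[1])
    Z = (X - mean) / scale

    n, d = Z.shape
    wb = np.zeros(d + 1) if init is None else np.asarray(init, dtype=float).copy()
    if wb.shape != (d + 1,):
        raise ValueError(f"init must have shape ({d + 1},)")
    nll, grad = penalized_nll_grad(wb, Z, y, lam)
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        p = scipy.stats.logistic.cdf(Z @ wb[:-1] + wb[-1])
        W = np.clip(p * (1 - p), 1e-12, None)
        Za = np.column_stack([Z, np.ones(n)])
        Hess = (Za * W[:, None]).T @ Za
        Hess[:d, :d] += lam * np.eye(d)
        try:
            step = np.linalg.solve(Hess, grad)
        except np.linalg.LinAlgError as err:
            raise RuntimeError(f"rLLR Newton system singular: {err}") from err
        decrement = grad @ step  # Newton decrement at the current point
        # step halving on the penalized NLL
        t = 1.0
        for _ in range(50):
            new = wb - t * step
            new_nll, new_grad = penalized_nll_grad(new, Z, y, lam)
            if new_nll <= nll:
                break
            t /= 2.0
        else:
            raise RuntimeError("rLLR line search failed (no descent step found)")
        rel = abs(nll - new_nll) / max(abs(nll), 1.0)
        wb, nll, grad = new, new_nll, new_grad
        if decrement < tol or rel < tol:
            break
    else:
        raise RuntimeError(
            f"rLLR did not converge in {max_iter} iterations "
            f"(last relative NLL change {rel:.3e}, |grad| {np.linalg.norm(grad):.3e})"
        )
    return RLLRModel(wb[:-1], float(wb[-1]), lam, mean, scale, feature_index, n_iter, True)


def decision_value(model: RLLRModel, X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != model.w.size:
        raise ValueError(f"expected {model.w.size} features, got {X.shape[1]}")
    Z = (X - model.mean) / model.scale
    return Z @ model.w + model.b


def predict_proba(model: RLLRModel, X) -> np.ndarray:
    """P(movement | x) = 1/(1+exp(−f(x))) with f the decision value."""
    if not model.trained:
        raise ValueError("model is not trained")
    return scipy.stats.logistic.cdf(decision_value(model, X))


def predict(model: RLLRModel, X) -> np.ndarray:
    """1 for movement (P > 0.5), else 0."""
    return (predict_proba(model, X) > 0.5).astype(int)


def _grouped_stratified_folds(y, groups, k, rng):
    """Assign groups to k folds, dealing the groups of each class round-robin
    after shuffling, so folds are near-stratified and group-disjoint."""
    folds = [[] for _ in range(k)]
    order = rng.permutation(k)
    fold_cycle = 0
    for cls in np.unique(y):
        cls_groups = np.unique(groups[y == cls])
        rng.shuffle(cls_groups)
        for g in cls_groups:
            folds[order[fold_cycle % k]].extend(np.nonzero(groups == g)[0])
            fold_cycle += 1
    return [np.sort(np.array(f, dtype=int)) for f in folds]


def _confusion(y_true, y_pred):
    c = np.zeros((2, 2), dtype=int)
    for t, p in zip(y_true, y_pred):
        c[t, p] += 1
    return c


def crossvalidate(
    features,
    labels=None,
    k: int = 10,
    seed: int = 0,
    lam: float = 1.0,
    unit: str = "sequence",
    sequences=None,
) -> EvalResult:
    """k-fold cross-validated classification rate.

    Folds are non-overlapping and exhaustive.  With ``unit='sequence'``
    (default) all trials of an experimental sequence share a fold, so
    within-sequence dependence cannot leak between training and test;
    ``unit='trial'`` assigns individual trials.  Standardization and
    training are redone inside every fold.
    """
    X, y = _as_xy(features, labels)
    n = len(y)
    if k > n:
        raise ValueError(f"k={k} exceeds the {n} available trials")
    for cls in (0, 1):
        if (y == cls).sum() < k and unit == "trial":
            raise ValueError("need at least k trials per class")
    if unit == "sequence":
        if sequences is None:
            if not isinstance(features, FeatureMatrix):
                raise ValueError("unit='sequence' needs sequence indices")
            sequences = features.sequence
        groups = np.asarray(sequences)
    elif unit == "trial":
        groups = np.arange(n)
    else:
        raise ValueError("unit must be 'sequence' or 'trial'")

    rng = np.random.default_rng(seed)
    folds = _grouped_stratified_folds(y, groups, k, rng)
    assert sorted(np.concatenate(folds).tolist()) == list(range(n))

    correct = 0
    per_fold = {}
    conf = np.zeros((2, 2), dtype=int)
    for i, test_idx in enumerate(folds):
        if len(test_idx) == 0:
            per_fold[i] = float("nan")
            continue
        train_mask = np.ones(n, bool)
        train_mask[test_idx] = False
        model = train_rllr(X[train_mask], y[train_mask], lam=lam)
        y_hat = predict(model, X[test_idx])
        correct += int((y_hat == y[test_idx]).sum())
        per_fold[i] = float((y_hat == y[test_idx]).mean())
        conf += _confusion(y[test_idx], y_hat)
    return EvalResult(correct / n, per_fold, n, conf)


def block_calibration_eval(
    features,
    labels=None,
    blocks=None,
    train_block: int = 1,
    lam: float = 1.0,
) -> EvalResult:
    """Train on one experimental block ("calibration"), test on the rest
    ("operating time"); rates reported pooled and per block."""
    X, y = _as_xy(features, labels)
    if blocks is None:
        if not isinstance(features, FeatureMatrix):
            raise ValueError("block_calibration_eval needs block indices")
        blocks = features.block
    blocks = np.asarray(blocks, dtype=int)
    uniq = np.unique(blocks)
    if train_block not in uniq:
        raise ValueError(f"train_block {train_block} not present (blocks: {uniq.tolist()})")
    if uniq.size < 2:
        raise ValueError("need at least 2 blocks for calibration evaluation")
    train = blocks == train_block
    if len(np.unique(y[train])) < 2:
        raise ValueError(f"block {train_block} does not contain both classes")
    model = train_rllr(X[train], y[train], lam=lam)
    test = ~train
    y_hat = predict(model, X[test])
    per_block = {
        int(b): float((y_hat[blocks[test] == b] == y[test][blocks[test] == b]).mean())
        for b in uniq
        if b != train_block
    }
    return EvalResult(
        float((y_hat == y[test]).mean()), per_block, int(test.sum()),
        _confusion(y[test], y_hat),
    )


def chance_threshold(n_trials: int, p0: float = 0.5, alpha: float = 0.01) -> float:
    """Smallest rate c/n whose one-sided binomial tail P(X ≥ c | n, p0) is
    ≤ alpha; rates above it are significantly better than chance.

    Returns ``nan`` when no attainable count is significant (tiny n).
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    c = int(scipy.stats.binom.isf(alpha, n_trials, p0)) + 1
    if c > n_trials:
        return float("nan")
    # isf guarantees sf(c-1) <= alpha; step back while the tail still fits
    while c > 0 and scipy.stats.binom.sf(c - 2, n_trials, p0) <= alpha:
        c -= 1
    return c / n_trials


def select_lambda(
    features,
    labels=None,
    grid=(0.01, 0.1, 1.0, 10.0, 100.0),
    k: int = 5,
    seed: int = 0,
    unit: str = "sequence",
    sequences=None,
) -> float:
    """Pick λ by nested k-fold cross-validation over *grid* (ties → smaller λ)."""
    best = (-np.inf, None)
    for lam in sorted(grid):
        res = crossvalidate(
            features, labels, k=k, seed=seed, lam=lam, unit=unit, sequences=sequences
        )
        if res.rate > best[0]:
            best = (res.rate, lam)
    return best[1]
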
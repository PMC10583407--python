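"""Log-linearized Gaussian mixture network (LLGMN).

A discriminative Gaussian mixture classifier written as a single-layer network:
each input vector ``x`` (dimension D) is expanded into

    X = (1, x_1..x_D, x_i x_j for i <= j)          H = 1 + D + D(D+1)/2

and each of the C*M component units applies a linear score ``X @ w_k``.  A
softmax over all units followed by summation within each class yields class
posterior probabilities.  Because the log of a Gaussian mixture component
density is exactly a quadratic in ``x``, this network family contains every
Gaussian mixture Bayes classifier (see :func:`log_linearize_gmm`), while
training by cross-entropy makes it discriminative.

The last unit (class C, component M) is the identifiability anchor: its weight
column is pinned to zero, removing the softmax's shift invariance.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .feature_table import AnalysisConfig, FeatureTable

POSTERIOR_CLIP = 1e-12


def expansion_size(d: int) -> int:
    return 1 + d + d * (d + 1) // 2


@lru_cache(maxsize=64)
def _pair_indices(d: int) -> tuple[np.ndarray, np.ndarray]:
    # upper-triangular (i <= j) pairs in row-major order
    return np.triu_indices(d)


@lru_cache(maxsize=64)
def _pair_matrix(d: int) -> np.ndarray:
    """Symmetric (d, d) lookup from (i, j) to the flat pair position."""
    iu, ju = _pair_indices(d)
    mat = np.empty((d, d), dtype=int)
    k = np.arange(iu.size)
    mat[iu, ju] = k
    mat[ju, iu] = k
    return mat


def expand_input(x: np.ndarray) -> np.ndarray:
    """Expand one input vector; see module docstring for the ordering."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 1:
        raise ValueError("input must be a 1-D vector with D >= 1")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite input")
    return expand_batch(x[None, :])[0]


def expand_batch(x: np.ndarray) -> np.ndarray:
    """Vectorized expansion of an (N, D) batch into (N, H)."""
    x = np.asarray(x, dtype=float)
    n, d = x.shape
    iu, ju = _pair_indices(d)
    out = np.empty((n, expansion_size(d)))
    out[:, 0] = 1.0
    out[:, 1 : d + 1] = x
    out[:, d + 1 :] = x[:, iu] * x[:, ju]
    return out


@dataclass
class LLGMNModel:
    """Weights of the network: ``(H, C*M)`` with the final column all zero.

    Unit k corresponds to class ``k // M`` and component ``k % M``
    (0-based); class posteriors are sums of unit softmax outputs per class.
    """

    n_classes: int
    n_components: int
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        c, m = self.n_classes, self.n_components
        if self.weights.ndim != 2 or self.weights.shape[1] != c * m:
            raise ValueError("weights must be (H, C*M)")
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("non-finite weights")
        if np.any(self.weights[:, -1] != 0):
            raise ValueError("anchor (last) column must be identically zero")

    @property
    def input_size(self) -> int:
        return self.weights.shape[0]

    @classmethod
    def zeros(cls, d: int, n_classes: int = 2, n_components: int = 1) -> "LLGMNModel":
        h = expansion_size(d)
        return cls(n_classes, n_components, np.zeros((h, n_classes * n_components)))

    def to_dict(self) -> dict:
        return {
            "n_classes": self.n_classes,
            "n_components": self.n_components,
            "weights": self.weights.ravel().tolist(),
            "input_size": self.input_size,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "LLGMNModel":
        w = np.asarray(data["weights"], float).reshape(
            data["input_size"], data["n_classes"] * data["n_components"]
        )
        return cls(data["n_classes"], data["n_components"], w)


def llgmn_forward(
    model: LLGMNModel, expanded: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Class posteriors and per-unit softmax outputs for expanded inputs.

    Accepts a single length-H vector or an (N, H) batch; returns matching
    shapes ``(.., C)`` and ``(.., C*M)``.  Softmax uses max-subtraction for
    overflow safety; posteriors sum to 1 by construction.
    """
    single = expanded.ndim == 1
    x = np.atleast_2d(np.asarray(expanded, dtype=float))
    if x.shape[1] != model.input_size:
        raise ValueError(
            f"expanded input size {x.shape[1]} != model H {model.input_size}"
        )
    act = x @ model.weights
    act -= act.max(axis=1, keepdims=True)
    y = np.exp(act)
    y /= y.sum(axis=1, keepdims=True)
    post = y.reshape(x.shape[0], model.n_classes, model.n_components).sum(axis=2)
    if single:
        return post[0], y[0]
    return post, y


def log_linearize_gmm(
    priors: np.ndarray, means: np.ndarray, covariances: np.ndarray
) -> LLGMNModel:
    """Build the LLGMN whose posteriors equal those of a given Gaussian mixture.

    ``priors`` is (C, M) with total sum 1 (joint class-and-component weights);
    ``means`` is (C, M, D); ``covariances`` is (C, M, D, D), each SPD.  The
    log of ``pi_cm * N(x; mu, Sigma)`` is a quadratic form in x, whose
    coefficients are placed into the expanded-input weight layout; the anchor
    column is subtracted out (softmax shift invariance keeps posteriors
    unchanged).
    """
    priors = np.asarray(priors, float)
    means = np.asarray(means, float)
    covariances = np.asarray(covariances, float)
    c, m = priors.shape
    d = means.shape[2]
    if not np.isclose(priors.sum(), 1.0):
        raise ValueError("priors must sum to 1")
    iu, ju = _pair_indices(d)
    h = expansion_size(d)
    w = np.empty((h, c * m))
    for ci in range(c):
        for mi in range(m):
            cov = covariances[ci, mi]
            sign, logdet = np.linalg.slogdet(cov)
            if sign <= 0:
                raise np.linalg.LinAlgError("covariance not positive definite")
            prec = np.linalg.inv(cov)
            mu = means[ci, mi]
            col = np.empty(h)
            col[0] = (
                np.log(priors[ci, mi])
                - 0.5 * (d * np.log(2 * np.pi) + logdet)
                - 0.5 * mu @ prec @ mu
            )
            col[1 : d + 1] = prec @ mu
            quad = -prec[iu, ju]  # off-diagonal pairs appear once => full -A_ij
            quad[iu == ju] = -0.5 * np.diag(prec)
            col[d + 1 :] = quad
            w[:, ci * m + mi] = col
    w -= w[:, -1:]
    return LLGMNModel(c, m, w)


def cross_entropy(
    model: LLGMNModel, expanded: np.ndarray, targets: np.ndarray
) -> float:
    """Summed cross-entropy error  -sum_n sum_c t_nc ln p(c|x_n).

    Posteriors are clipped below at 1e-12 before the log.
    """
    post, _ = llgmn_forward(model, expanded)
    post = np.atleast_2d(post)
    targets = np.atleast_2d(targets)
    return float(-(targets * np.log(np.clip(post, POSTERIOR_CLIP, None))).sum())


def llgmn_gradient(
    model: LLGMNModel, expanded: np.ndarray, targets: np.ndarray
) -> np.ndarray:
    """Analytic gradient of :func:`cross_entropy` w.r.t. the weight matrix.

    The anchored column's gradient is forced to zero.
    """
    grad, _ = _gradient_pieces(model, expanded, targets)
    return grad


def _gradient_pieces(
    model: LLGMNModel, expanded: np.ndarray, targets: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Weight gradient and per-unit activation deltas (used by the sparse net)."""
    x = np.atleast_2d(expanded)
    t = np.atleast_2d(targets)
    post, y = llgmn_forward(model, x)
    m = model.n_components
    # dE/da_k = Y_k * (1 - t_c(k) / p_c(k))   for unit k in class c(k)
    ratio = t / np.clip(post, POSTERIOR_CLIP, None)
    delta = y * (1.0 - np.repeat(ratio, m, axis=1))
    grad = x.T @ delta
    grad[:, -1] = 0.0
    return grad, delta


def train_llgmn(
    table: FeatureTable, config: AnalysisConfig, n_classes: int = 2
) -> LLGMNModel:
    """Train an LLGMN by mini-batch SGD on a standardized table.

    Weights start at zero (uniform posteriors).  Batches are reshuffled each
    epoch with a seeded RNG; after each epoch the full-data loss is evaluated
    and training stops early when it fails to improve by more than
    ``early_stop_min_delta`` for more than ``early_stop_patience`` consecutive
    epochs.  The best-loss weights are returned.
    """
    if not table.standardized:
        raise ValueError("train_llgmn requires a standardized table")
    if len(np.unique(table.labels)) < 2:
        raise ValueError("training data must contain both classes")
    expanded = expand_batch(table.values)
    targets = table.onehot_targets()
    model = LLGMNModel.zeros(table.n_indices, n_classes, config.n_components)
    rng = np.random.default_rng(config.seed)
    n = table.n_samples

    best_loss = cross_entropy(model, expanded, targets)
    best_w = model.weights.copy()
    stall = 0
    for _ in range(config.max_epochs):
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            grad = llgmn_gradient(model, expanded[idx], targets[idx])
            model.weights -= config.learning_rate * grad
        loss = cross_entropy(model, expanded, targets)
        if loss < best_loss - config.early_stop_min_delta:
            best_loss = loss
            best_w = model.weights.copy()
            stall = 0
        else:
            if loss < best_loss:
                best_loss = loss
                best_w = model.weights.copy()
            stall += 1
            if stall > config.early_stop_patience:
                break
    model.weights = best_w
    return model
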
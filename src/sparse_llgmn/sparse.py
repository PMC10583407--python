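"""The proposed sparse network: gating layer + LLGMN, trained end-to-end.

An elementwise "dimensionality reduction" layer

    y_i = w_i * x_i        (i = 1..P)

feeds the LLGMN.  Training minimizes the energy

    E = cross-entropy(posteriors, targets) + lambda * sum_i |w_i|

by joint mini-batch SGD; the L1 term is handled with a proximal
(soft-thresholding) step on ``w`` after every gradient update, which is what
makes some gate weights exactly zero at the end of training.  An index whose
gate is zero is multiplicatively removed from the model, so selection happens
during the fit itself.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .feature_table import AnalysisConfig, FeatureTable
from .llgmn import (
    LLGMNModel,
    POSTERIOR_CLIP,
    _pair_indices,
    _pair_matrix,
    expand_batch,
    llgmn_forward,
)


@dataclass
class SparseLLGMNModel:
    """Gate weights ``w`` (length P), the downstream LLGMN, and lambda."""

    reduction_weights: np.ndarray
    llgmn: LLGMNModel
    lam: float

    def __post_init__(self) -> None:
        self.reduction_weights = np.asarray(self.reduction_weights, float)
        if not np.all(np.isfinite(self.reduction_weights)):
            raise ValueError("non-finite reduction weights")

    @property
    def n_indices(self) -> int:
        return self.reduction_weights.size

    def support(self) -> np.ndarray:
        """Boolean mask of indices with exactly non-zero gate weight."""
        return self.reduction_weights != 0

    def posteriors(self, x: np.ndarray) -> np.ndarray:
        """Class posterior probabilities for raw (standardized) inputs (N, P)."""
        x = np.atleast_2d(np.asarray(x, float))
        reduced = x * self.reduction_weights
        post, _ = llgmn_forward(self.llgmn, expand_batch(reduced))
        return post

    def to_dict(self) -> dict:
        return {
            "reduction_weights": self.reduction_weights.tolist(),
            "llgmn": self.llgmn.to_dict(),
            "lambda": self.lam,
        }

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_dict(cls, data: dict) -> "SparseLLGMNModel":
        return cls(
            np.asarray(data["reduction_weights"], float),
            LLGMNModel.from_dict(data["llgmn"]),
            float(data["lambda"]),
        )

    @classmethod
    def load(cls, path: str | Path) -> "SparseLLGMNModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def reduce_inputs(w: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Gating layer output y_i = w_i * x_i (elementwise)."""
    w = np.asarray(w, float)
    x = np.asarray(x, float)
    if w.shape[-1] != x.shape[-1]:
        raise ValueError("w and x must have equal length")
    return w * x


def energy(model: SparseLLGMNModel, table: FeatureTable) -> float:
    """Energy E = summed cross-entropy + lambda * sum |w_i|."""
    post = model.posteriors(table.values)
    t = table.onehot_targets()
    ce = float(-(t * np.log(np.clip(post, POSTERIOR_CLIP, None))).sum())
    return ce + model.lam * float(np.abs(model.reduction_weights).sum())


def prox_l1(v: np.ndarray, t: float) -> np.ndarray:
    """Soft-thresholding: sign(v) * max(|v| - t, 0), with exact zeros."""
    if t < 0:
        raise ValueError("threshold must be >= 0")
    v = np.asarray(v, float)
    out = np.sign(v) * np.maximum(np.abs(v) - t, 0.0)
    # entries at or below the threshold compare equal to 0, not just small
    out[np.abs(v) <= t] = 0.0
    return out


def _gate_expansion(w: np.ndarray) -> np.ndarray:
    """Expansion-pattern of the gate vector: (1, w_i, w_i w_j for i <= j).

    Because every expanded entry is a monomial, expand(w * x) equals
    expand(x) * _gate_expansion(w) elementwise, which lets training expand the
    data once instead of at every mini-batch step.
    """
    iu, ju = _pair_indices(w.size)
    return np.concatenate(([1.0], w, w[iu] * w[ju]))


def _sparse_gradients(
    model: SparseLLGMNModel, x: np.ndarray, targets: np.ndarray,
    expanded_x: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Gradients of the cross-entropy term w.r.t. LLGMN weights and gates.

    Backpropagation chains through the quadratic expansion: the gradient on
    the gate-expansion entries is folded back onto w via the pair table (the
    diagonal pair contributes twice).
    """
    w = model.reduction_weights
    p = w.size
    if expanded_x is None:
        expanded_x = expand_batch(x)
    wexp = _gate_expansion(w)
    expanded = expanded_x * wexp

    post, y = llgmn_forward(model.llgmn, expanded)
    m = model.llgmn.n_components
    ratio = targets / np.clip(post, POSTERIOR_CLIP, None)
    delta = y * (1.0 - np.repeat(ratio, m, axis=1))
    grad_w_llgmn = expanded.T @ delta
    grad_w_llgmn[:, -1] = 0.0

    # gradient on the gate-expansion vector, then fold back onto w
    d_wexp = ((delta @ model.llgmn.weights.T) * expanded_x).sum(axis=0)
    d_lin = d_wexp[1 : p + 1]
    d_quad = d_wexp[p + 1 :]
    pairmat = _pair_matrix(p)
    g = d_quad[pairmat]  # symmetric (P, P)
    diag = np.arange(p)
    grad_gate = d_lin + g @ w + d_quad[pairmat[diag, diag]] * w
    return grad_w_llgmn, grad_gate


def train_sparse_llgmn(
    table: FeatureTable,
    config: AnalysisConfig,
    w_init: np.ndarray | None = None,
) -> SparseLLGMNModel:
    """Train the sparse network end-to-end with proximal SGD.

    Gate weights start at 1 (identity layer), LLGMN weights at zero.  After
    every mini-batch gradient step the gates receive the L1 proximal update
    with threshold ``learning_rate * lambda``, producing exact zeros.  Early
    stopping monitors the full-data energy E after each epoch, with the same
    rule as :func:`~sparse_llgmn.llgmn.train_llgmn`; best-energy parameters
    are returned.
    """
    if not table.standardized:
        raise ValueError("train_sparse_llgmn requires a standardized table")
    if len(np.unique(table.labels)) < 2:
        raise ValueError("training data must contain both classes")
    if isinstance(config.lam, str):
        raise ValueError("lambda must be resolved to a number before training")
    lam = float(config.lam)

    p = table.n_indices
    llgmn = LLGMNModel.zeros(p, 2, config.n_components)
    w = np.ones(p) if w_init is None else np.asarray(w_init, float).copy()
    model = SparseLLGMNModel(w, llgmn, lam)
    targets = table.onehot_targets()
    x = table.values
    n = table.n_samples
    rng = np.random.default_rng(config.seed)
    expanded_x = expand_batch(x)  # data expanded once; gates folded in per step

    def full_energy() -> float:
        post, _ = llgmn_forward(
            llgmn, expanded_x * _gate_expansion(model.reduction_weights)
        )
        ce = float(-(targets * np.log(np.clip(post, POSTERIOR_CLIP, None))).sum())
        return ce + lam * float(np.abs(model.reduction_weights).sum())

    best_e = full_energy()
    best = (model.reduction_weights.copy(), llgmn.weights.copy())
    stall = 0
    for _ in range(config.max_epochs):
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            g_llgmn, g_gate = _sparse_gradients(
                model, x[idx], targets[idx], expanded_x=expanded_x[idx]
            )
            llgmn.weights -= config.learning_rate * g_llgmn
            llgmn.weights[:, -1] = 0.0
            stepped = model.reduction_weights - config.learning_rate * g_gate
            model.reduction_weights = prox_l1(stepped, config.learning_rate * lam)
        e = full_energy()
        if e < best_e - config.early_stop_min_delta:
            best_e = e
            best = (model.reduction_weights.copy(), llgmn.weights.copy())
            stall = 0
        else:
            if e < best_e:
                best_e = e
                best = (model.reduction_weights.copy(), llgmn.weights.copy())
            stall += 1
            if stall > config.early_stop_patience:
                break
    model.reduction_weights, llgmn.weights = best
    return model
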
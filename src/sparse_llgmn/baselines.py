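"""Comparison methods: stepwise partial-KLI elimination and Lasso regression.

Partial KL information (KLI) is used here as a per-input contribution measure
for a trained LLGMN, operationalized as the increase in validation
cross-entropy when an input column is replaced by its training-fold mean
(zero after standardization).  Backward elimination removes the
least-contributing index each round, retraining by cross-validation, and
keeps the set with the best out-of-fold AUC along the trace.

The Lasso baseline is penalized *linear* regression of the 0/1 class label on
standardized predictors (not logistic), solved by cyclic coordinate descent;
coefficient magnitudes on standardized predictors are the standardized
partial regression coefficients used for ranking.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .feature_table import (
    AnalysisConfig,
    FeatureTable,
    apply_standardization,
    standardize,
)
from .llgmn import LLGMNModel, cross_entropy, expand_batch, train_llgmn
from .selection import make_folds
from .stats import auc_mann_whitney


def partial_kli(model: LLGMNModel, table: FeatureTable, i: int) -> float:
    """Contribution of index i: cross-entropy with column i mean-substituted
    (0 after standardization) minus the intact cross-entropy.

    Can legitimately be negative (removing a column may reduce the error on a
    small validation set).
    """
    if not table.standardized:
        raise ValueError("partial_kli requires a standardized table")
    if not 0 <= i < table.n_indices:
        raise IndexError(f"index {i} out of range")
    targets = table.onehot_targets()
    base = cross_entropy(model, expand_batch(table.values), targets)
    ablated = table.values.copy()
    ablated[:, i] = 0.0
    return cross_entropy(model, expand_batch(ablated), targets) - base


def _llgmn_cv(
    table: FeatureTable, config: AnalysisConfig, folds: np.ndarray
) -> tuple[float, np.ndarray, list[LLGMNModel], list]:
    """Out-of-fold AUC of a plain LLGMN over given fold assignments."""
    n = table.n_samples
    oof = np.full(n, np.nan)
    models, fold_tables = [], []
    for fold in range(1, int(folds.max()) + 1):
        val_mask = folds == fold
        train = standardize(table.subset_rows(~val_mask), on_constant="zero")
        held = apply_standardization(
            table.subset_rows(val_mask), train.standardization_params
        )
        model = train_llgmn(train, config)
        from .llgmn import llgmn_forward

        post, _ = llgmn_forward(model, expand_batch(held.values))
        oof[val_mask] = post[:, 0]
        models.append(model)
        fold_tables.append(held)
    auc = auc_mann_whitney(oof, table.labels == 1)
    return auc, oof, models, fold_tables


@dataclass
class StepwiseTrace:
    """Backward-elimination trace: removal order, AUC per evaluated set, and
    the retained set maximizing out-of-fold AUC."""

    removal_order: list[str]
    auc_at_step: list[float]  # AUC of the sets of sizes P, P-1, ..., 1
    selected: set[str]
    oof_scores: np.ndarray  # out-of-fold posteriors for the selected set
    survivor: str | None = None

    @property
    def ranking(self) -> list[str]:
        """Importance ranking: the later an index was removed, the more it
        contributed; the surviving index ranks first."""
        head = [self.survivor] if self.survivor is not None else []
        return head + list(reversed(self.removal_order))


def stepwise_kli_selection(
    table: FeatureTable,
    config: AnalysisConfig,
    fold_assignments: np.ndarray | None = None,
) -> StepwiseTrace:
    """Backward elimination driven by partial KLI, scored by out-of-fold AUC.

    Each round: cross-validate a plain LLGMN on the remaining indices, record
    the pooled out-of-fold AUC, average the per-fold partial KLI of every
    remaining index over the validation folds, and drop the minimum.  Stops
    when one index remains; ``selected`` is the set with the highest AUC along
    the trace (ties resolved toward the smaller set).
    """
    if table.n_indices < 2:
        raise ValueError("stepwise elimination needs at least 2 indices")
    if fold_assignments is None:
        fold_assignments = make_folds(
            table.n_samples, config.n_folds, table.labels, config.seed
        )
    remaining = list(table.index_names)
    removal_order: list[str] = []
    aucs: list[float] = []
    best_auc, best_set, best_oof = -np.inf, list(remaining), None
    while True:
        sub = table.subset_columns(remaining)
        auc, oof, models, fold_tables = _llgmn_cv(sub, config, fold_assignments)
        aucs.append(auc)
        # smaller set wins ties, so >= replaces the incumbent
        if auc >= best_auc:
            best_auc, best_set, best_oof = auc, list(remaining), oof
        if len(remaining) == 1:
            break
        kli = np.zeros(len(remaining))
        for model, held in zip(models, fold_tables):
            for j in range(len(remaining)):
                kli[j] += partial_kli(model, held, j)
        kli /= len(models)
        drop = int(np.argmin(kli))
        removal_order.append(remaining.pop(drop))
    return StepwiseTrace(removal_order, aucs, set(best_set), best_oof, remaining[0])


def auc_drop_importance(
    table: FeatureTable,
    config: AnalysisConfig,
    fold_assignments: np.ndarray | None = None,
) -> list[tuple[str, float, float]]:
    """Leave-one-index-out AUC reduction for a selected set.

    Returns (name, auc_without, reduction_percent) sorted by descending
    reduction, where reduction% = (AUC_full - AUC_without) / AUC_full * 100.
    Negative reductions are legal (deleting an index can raise the AUC).
    """
    if table.n_indices < 2:
        raise ValueError("need at least 2 indices to delete one")
    if fold_assignments is None:
        fold_assignments = make_folds(
            table.n_samples, config.n_folds, table.labels, config.seed
        )
    auc_full, _, _, _ = _llgmn_cv(table, config, fold_assignments)
    rows = []
    for name in table.index_names:
        keep = [n for n in table.index_names if n != name]
        auc_without, _, _, _ = _llgmn_cv(
            table.subset_columns(keep), config, fold_assignments
        )
        rows.append((name, auc_without, (auc_full - auc_without) / auc_full * 100.0))
    rows.sort(key=lambda r: -r[2])
    return rows


@dataclass
class LassoFit:
    """Lasso solution on standardized predictors (coefficients are the
    standardized partial regression coefficients)."""

    coefficients: np.ndarray
    intercept: float
    lam: float
    index_names: list[str]

    def predict(self, values: np.ndarray) -> np.ndarray:
        return self.intercept + np.asarray(values, float) @ self.coefficients


def lasso_fit(
    table: FeatureTable, lam: float, tol: float = 1e-8, max_iter: int = 100000
) -> LassoFit:
    """Cyclic coordinate descent for
    (1/2N) ||y - b0 - X b||^2 + lam * sum |b_i|,  y in {0, 1}.

    Labels are coded y = 1 for the positive class (label 1).  Converged when
    no coefficient moves by more than ``tol`` in a full cycle.
    """
    if not table.standardized:
        raise ValueError("lasso_fit requires standardized predictors")
    x = table.values
    y = (table.labels == 1).astype(float)
    n, p = x.shape
    b0 = y.mean()
    beta = np.zeros(p)
    col_sq = (x**2).sum(axis=0) / n
    resid = y - b0 - x @ beta
    for _ in range(max_iter):
        max_delta = 0.0
        for j in range(p):
            old = beta[j]
            rho = (x[:, j] @ resid) / n + col_sq[j] * old
            new = np.sign(rho) * max(abs(rho) - lam, 0.0) / col_sq[j]
            if new != old:
                resid -= x[:, j] * (new - old)
                beta[j] = new
                max_delta = max(max_delta, abs(new - old))
        # intercept update (free of penalty)
        shift = resid.mean()
        if abs(shift) > 0:
            b0 += shift
            resid -= shift
            max_delta = max(max_delta, abs(shift))
        if max_delta <= tol:
            break
    return LassoFit(beta, float(b0), float(lam), list(table.index_names))


def lasso_lambda_max(table: FeatureTable) -> float:
    """Smallest lambda at which all coefficients are zero."""
    y = (table.labels == 1).astype(float)
    return float(np.abs(table.values.T @ (y - y.mean())).max() / table.n_samples)


def lasso_select(
    table: FeatureTable,
    config: AnalysisConfig,
    fold_assignments: np.ndarray | None = None,
    n_lambdas: int = 30,
    inner_folds: int = 5,
) -> tuple[LassoFit, list[str], np.ndarray | None]:
    """Pick lambda by inner CV (minimum mean squared error), fit on the full
    table, and rank indices by |standardized coefficient| descending.

    ``table`` is an unstandardized feature table; standardization happens per
    training split.  When ``fold_assignments`` is given, out-of-fold linear
    predictors for ROC analysis are computed over those folds at the chosen
    lambda (per-fold refits); otherwise the third return value is None.
    """
    full_std = standardize(table, on_constant="zero")
    lam_max = lasso_lambda_max(full_std)
    lambdas = np.geomspace(lam_max, max(lam_max * 1e-3, 1e-12), n_lambdas)
    inner = make_folds(table.n_samples, inner_folds, table.labels, config.seed)
    cv_mse = np.zeros(n_lambdas)
    for fold in range(1, inner_folds + 1):
        val_mask = inner == fold
        train = standardize(table.subset_rows(~val_mask), on_constant="zero")
        held = apply_standardization(
            table.subset_rows(val_mask), train.standardization_params
        )
        y_val = (held.labels == 1).astype(float)
        for li, lam in enumerate(lambdas):
            fit = lasso_fit(train, lam)
            cv_mse[li] += ((y_val - fit.predict(held.values)) ** 2).sum()
    best_lam = float(lambdas[int(np.argmin(cv_mse))])
    fit = lasso_fit(full_std, best_lam)
    order = np.argsort(-np.abs(fit.coefficients), kind="stable")
    ranking = [table.index_names[j] for j in order]

    oof = None
    if fold_assignments is not None:
        oof = np.full(table.n_samples, np.nan)
        for fold in range(1, int(fold_assignments.max()) + 1):
            val_mask = fold_assignments == fold
            train = standardize(table.subset_rows(~val_mask), on_constant="zero")
            held = apply_standardization(
                table.subset_rows(val_mask), train.standardization_params
            )
            oof[val_mask] = lasso_fit(train, best_lam).predict(held.values)
    return fit, ranking, oof
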
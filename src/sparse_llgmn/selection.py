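"""Cross-validation, the non-zero-at-least-once selection rule, and
permutation importance.

Selection is union-of-support: an index counts as effective when its gate
weight is non-zero in at least one cross-validation fold.  Importance is
measured two ways — by the gate weights themselves (mean |w_i| across folds)
and by permutation importance, the increase in validation cross-entropy after
shuffling one index column of the validation data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .feature_table import (
    AnalysisConfig,
    FeatureTable,
    apply_standardization,
    standardize,
)
from .llgmn import POSTERIOR_CLIP
from .sparse import SparseLLGMNModel, train_sparse_llgmn


def make_folds(n: int, k: int, labels: np.ndarray, seed: int) -> np.ndarray:
    """Stratified fold assignment: length-n array of fold ids 1..k.

    Per-class counts per fold differ by at most 1; leftover members are dealt
    to the folds with the smallest running totals, which also balances fold
    sizes (55 samples over 11 folds gives 11 folds of exactly 5).  The shuffle
    is seeded and deterministic.
    """
    labels = np.asarray(labels)
    if k > n:
        raise ValueError("more folds than samples")
    rng = np.random.default_rng(seed)
    assignment = np.zeros(n, dtype=int)
    totals = np.zeros(k, dtype=int)
    classes = sorted(np.unique(labels), key=lambda c: -(labels == c).sum())
    for cls in classes:
        members = np.where(labels == cls)[0]
        if members.size < k:
            warnings.warn(
                f"class {cls} has fewer members ({members.size}) than folds ({k})",
                stacklevel=2,
            )
        rng.shuffle(members)
        base, rem = divmod(members.size, k)
        counts = np.full(k, base)
        # give the +1 remainders to the currently smallest folds (ties: low id)
        order = np.lexsort((np.arange(k), totals))
        counts[order[:rem]] += 1
        pos = 0
        for fold in range(k):
            assignment[members[pos : pos + counts[fold]]] = fold + 1
            pos += counts[fold]
        totals += counts
    return assignment


@dataclass
class CVResult:
    """Artifacts of one K-fold cross-validated sparse-network run."""

    fold_assignments: np.ndarray
    models: list[SparseLLGMNModel]
    oof_posteriors: np.ndarray  # positive-class (label 1) probability per sample
    fold_weights: np.ndarray  # (K, P) gate weights
    fold_params: list[tuple[np.ndarray, np.ndarray]]
    index_names: list[str]
    fold_lambdas: list[float] = field(default_factory=list)

    @property
    def n_folds(self) -> int:
        return len(self.models)


def cross_validate(
    table: FeatureTable,
    config: AnalysisConfig,
    fold_assignments: np.ndarray | None = None,
) -> CVResult:
    """K-fold CV of the sparse network with leakage-free standardization.

    Each fold standardizes on its training rows, trains the sparse network,
    and scores the held-out rows; out-of-fold positive-class posteriors are
    assembled over all folds.  With ``config.lam == "tpe"`` the L1 coefficient
    is tuned per fold on that fold's training rows.
    """
    from .tuning import tune_lambda_tpe

    n = table.n_samples
    if fold_assignments is None:
        fold_assignments = make_folds(n, config.n_folds, table.labels, config.seed)
    k = int(fold_assignments.max())
    oof = np.full(n, np.nan)
    models: list[SparseLLGMNModel] = []
    weights = np.zeros((k, table.n_indices))
    params: list[tuple[np.ndarray, np.ndarray]] = []
    lambdas: list[float] = []
    for fold in range(1, k + 1):
        val_mask = fold_assignments == fold
        try:
            train = standardize(table.subset_rows(~val_mask), on_constant="zero")
            held = apply_standardization(
                table.subset_rows(val_mask), train.standardization_params
            )
            if isinstance(config.lam, str):
                lam = tune_lambda_tpe(train, config.replace(lam=0.0))
            else:
                lam = float(config.lam)
            model = train_sparse_llgmn(train, config.replace(lam=lam))
        except Exception as exc:
            raise RuntimeError(f"cross-validation failed in fold {fold}: {exc}") from exc
        post = model.posteriors(held.values)
        oof[val_mask] = post[:, 0]
        models.append(model)
        weights[fold - 1] = model.reduction_weights
        params.append(train.standardization_params)
        lambdas.append(lam)
    return CVResult(
        fold_assignments, models, oof, weights, params, list(table.index_names), lambdas
    )


@dataclass
class SelectionResult:
    """Indices judged effective: gate weight non-zero in at least one fold."""

    selected: set[str]
    mean_weights: np.ndarray
    mean_abs_weights: np.ndarray
    n_folds_nonzero: np.ndarray
    ranking: list[str]
    index_names: list[str]


def select_indices(cv: CVResult) -> SelectionResult:
    """Apply the non-zero-at-least-once rule and rank by mean |w_i|.

    Ranking uses the fold-mean absolute gate weight (descending); signed means
    are reported alongside since fold weights can disagree in sign.
    """
    nonzero = cv.fold_weights != 0
    n_nonzero = nonzero.sum(axis=0)
    selected = {name for name, c in zip(cv.index_names, n_nonzero) if c > 0}
    mean_w = cv.fold_weights.mean(axis=0)
    mean_abs = np.abs(cv.fold_weights).mean(axis=0)
    order = np.argsort(-mean_abs, kind="stable")
    ranking = [cv.index_names[j] for j in order]
    return SelectionResult(
        selected, mean_w, mean_abs, n_nonzero, ranking, list(cv.index_names)
    )


def _validation_cross_entropy(model: SparseLLGMNModel, values, targets) -> float:
    post = model.posteriors(values)
    return float(-(targets * np.log(np.clip(post, POSTERIOR_CLIP, None))).sum())


def permutation_importance(
    model: SparseLLGMNModel,
    val_table: FeatureTable,
    seed: int,
    repeats: int = 1,
    permutations: dict[int, np.ndarray] | None = None,
) -> np.ndarray:
    """PI_i = e_i - e: validation cross-entropy after shuffling column i,
    minus the intact cross-entropy.

    ``val_table`` must already be standardized with the model's training-fold
    parameters.  One seeded shuffle per index by default; ``repeats`` averages
    several.  ``permutations`` forces explicit permutations (diagnostics /
    oracle tests); an identity permutation yields PI exactly 0, as does any
    index whose gate weight is exactly 0 (the model output cannot depend on
    that column).
    """
    if val_table.n_samples == 0:
        raise ValueError("empty validation set")
    rng = np.random.default_rng(seed)
    targets = val_table.onehot_targets()
    base = _validation_cross_entropy(model, val_table.values, targets)
    p = val_table.n_indices
    pi = np.zeros(p)
    for i in range(p):
        if model.reduction_weights[i] == 0 and (
            permutations is None or i not in permutations
        ):
            # output is invariant to column i; skip the shuffles entirely
            continue
        acc = 0.0
        for _ in range(repeats):
            perm = (
                permutations[i]
                if permutations is not None and i in permutations
                else rng.permutation(val_table.n_samples)
            )
            shuffled = val_table.values.copy()
            shuffled[:, i] = shuffled[perm, i]
            acc += _validation_cross_entropy(model, shuffled, targets) - base
        pi[i] = acc / repeats
    return pi


@dataclass
class ImportanceReport:
    pi_matrix: np.ndarray  # (K, P)
    pi_mean: np.ndarray  # (P,)
    index_names: list[str]


def aggregate_importance(
    cv: CVResult, table: FeatureTable, seed: int, repeats: int = 1
) -> ImportanceReport:
    """Per-fold permutation importances and their arithmetic mean.

    Each fold's validation rows are re-standardized with that fold's stored
    training parameters, scored against that fold's model, and the K values
    per index are averaged for the final evaluation.
    """
    k = cv.n_folds
    p = len(cv.index_names)
    pi = np.zeros((k, p))
    for fold in range(1, k + 1):
        val_mask = cv.fold_assignments == fold
        held = apply_standardization(
            table.subset_rows(val_mask), cv.fold_params[fold - 1]
        )
        pi[fold - 1] = permutation_importance(
            cv.models[fold - 1], held, seed=seed + fold, repeats=repeats
        )
    return ImportanceReport(pi, pi.mean(axis=0), list(cv.index_names))
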
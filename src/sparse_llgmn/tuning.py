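"""Tree-structured Parzen estimator (TPE) search for the L1 coefficient.

A compact single-parameter TPE: trials are split at a quantile ``gamma`` into
"good" and "bad" sets, Parzen (Gaussian kernel) densities l(x) and g(x) are
fitted to each in log-lambda space, and the next trial maximizes the ratio
l(x)/g(x) over candidates drawn from l.  The first ``n_startup`` trials are
log-uniform random.  Everything is driven by one seeded RNG, so a fixed seed
gives a fixed lambda.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .feature_table import AnalysisConfig, FeatureTable


@dataclass
class TPETrial:
    x: float
    value: float


def _parzen_logpdf(points: np.ndarray, query: np.ndarray, span: float) -> np.ndarray:
    """Log density of an equal-weight Gaussian kernel mixture at query points."""
    n = points.size
    # Scott-style bandwidth, floored so single/degenerate sets stay proper
    sigma = max(points.std() * n ** (-0.2), 0.05 * span, 1e-12)
    diff = (query[:, None] - points[None, :]) / sigma
    log_k = -0.5 * diff**2 - 0.5 * np.log(2 * np.pi) - np.log(sigma)
    return np.logaddexp.reduce(log_k, axis=1) - np.log(n)


def tpe_minimize(
    objective,
    low: float,
    high: float,
    n_trials: int,
    seed: int = 0,
    n_startup: int = 10,
    gamma: float = 0.25,
    n_candidates: int = 24,
) -> tuple[float, float, list[TPETrial]]:
    """Minimize ``objective(x)`` over log-uniform x in [low, high].

    Returns ``(best_x, best_value, trials)``.  A degenerate range
    (low == high) short-circuits to that single point.
    """
    if low > high or low <= 0:
        raise ValueError("need 0 < low <= high for a log-uniform range")
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = np.random.default_rng(seed)
    if low == high:
        return low, float(objective(low)), [TPETrial(low, float(objective(low)))]

    lo, hi = np.log(low), np.log(high)
    span = hi - lo
    trials: list[TPETrial] = []
    for t in range(n_trials):
        if t < n_startup or len(trials) < 2:
            z = rng.uniform(lo, hi)
        else:
            xs = np.array([tr.x for tr in trials])
            vals = np.array([tr.value for tr in trials])
            n_good = max(1, int(np.ceil(gamma * len(trials))))
            order = np.argsort(vals, kind="stable")
            good = np.log(xs[order[:n_good]])
            bad = np.log(xs[order[n_good:]])
            if bad.size == 0:
                bad = np.log(xs)
            sigma_good = max(good.std() * good.size ** (-0.2), 0.05 * span, 1e-12)
            cand = good[rng.integers(0, good.size, n_candidates)] + rng.normal(
                0, sigma_good, n_candidates
            )
            cand = np.clip(cand, lo, hi)
            score = _parzen_logpdf(good, cand, span) - _parzen_logpdf(bad, cand, span)
            z = cand[int(np.argmax(score))]
        x = float(np.exp(z))
        trials.append(TPETrial(x, float(objective(x))))
    best = min(trials, key=lambda tr: tr.value)
    return best.x, best.value, trials


def inner_cv_objective(
    table: FeatureTable, config: AnalysisConfig, n_folds: int | None = None
):
    """Objective factory: mean out-of-fold cross-entropy of the sparse network.

    For a candidate lambda, the training table is split into ``n_folds``
    stratified folds; each fold's model is trained on the remaining rows
    (standardized per fold) and scored on the held-out rows.  Returns total
    out-of-fold cross-entropy divided by N (a per-sample mean, scale-stable
    across fold sizes).
    """
    # local import: selection imports tuning for per-fold TPE
    from .llgmn import POSTERIOR_CLIP
    from .selection import make_folds
    from .feature_table import apply_standardization, standardize
    from .sparse import train_sparse_llgmn

    k = n_folds or config.tpe_inner_folds
    folds = make_folds(table.n_samples, k, table.labels, config.seed)

    def objective(lam: float) -> float:
        total = 0.0
        for fold in range(1, k + 1):
            val = folds == fold
            train = standardize(table.subset_rows(~val), on_constant="zero")
            held = apply_standardization(
                table.subset_rows(val), train.standardization_params
            )
            model = train_sparse_llgmn(train, config.replace(lam=float(lam)))
            post = model.posteriors(held.values)
            t = held.onehot_targets()
            total += float(-(t * np.log(np.clip(post, POSTERIOR_CLIP, None))).sum())
        return total / table.n_samples

    return objective


def tune_lambda_tpe(
    table: FeatureTable,
    config: AnalysisConfig,
    search: tuple[float, float, int] | None = None,
) -> float:
    """Choose lambda by TPE over a log-uniform range.

    ``search`` is ``(low, high, n_trials)``; defaults come from the config
    (tpe_low, tpe_high, tpe_trials).  The objective is the inner-CV mean
    out-of-fold cross-entropy on ``table``.  Deterministic given the seed.
    """
    low, high, n_trials = search or (config.tpe_low, config.tpe_high, config.tpe_trials)
    objective = inner_cv_objective(table, config)
    best_x, _, _ = tpe_minimize(objective, low, high, n_trials, seed=config.seed)
    return best_x
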
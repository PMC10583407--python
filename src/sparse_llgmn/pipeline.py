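"""End-to-end orchestration: selection, scoring, statistics, report writing.

``run_full_analysis`` runs any subset of the three methods (proposed sparse
network, stepwise partial-KLI elimination, Lasso) on one feature table with a
single shared fold assignment, so that out-of-fold scores are paired and AUC
comparisons can use the DeLong test.  Artifacts (ROC points, selected sets,
importances, fold assignment, JSON report) are written as plain CSV/JSON.
"""

from __future__ import annotations

import json
import logging
import time
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .baselines import lasso_select, stepwise_kli_selection
from .feature_table import AnalysisConfig, FeatureTable, standardize
from .selection import (
    aggregate_importance,
    cross_validate,
    make_folds,
    select_indices,
)
from .stats import (
    brunner_munzel,
    confusion_and_association,
    delong_test,
    holm_adjust,
    roc_analysis,
)
from .tuning import tune_lambda_tpe

logger = logging.getLogger(__name__)

METHODS = ("proposed", "kli", "lasso")


def _roc_block(scores: np.ndarray, labels: np.ndarray) -> tuple[dict, "np.ndarray"]:
    roc = roc_analysis(scores, labels)
    predicted = np.where(scores >= roc.best_threshold, 1, 2)
    tab, fisher_p, yule_q = confusion_and_association(predicted, labels)
    block = {
        "auc": roc.auc,
        "threshold": roc.best_threshold,
        "sensitivity": roc.sens_at_best,
        "specificity": roc.spec_at_best,
        "confusion": {"a": tab.a, "b": tab.b, "c": tab.c, "d": tab.d},
        "fisher_p": fisher_p,
        "yule_q": yule_q,
    }
    return block, roc


def run_full_analysis(
    table: FeatureTable,
    config: AnalysisConfig,
    methods: tuple[str, ...] = METHODS,
    outdir: str | Path | None = None,
) -> dict:
    """Run the selected methods end-to-end and assemble a machine-readable
    report (returned as a dict, optionally written to ``outdir``).

    All methods share one stratified fold assignment.  With ``config.lam ==
    "tpe"`` and ``config.tpe_scope == "global"`` (the default) the proposed
    network's L1 coefficient is tuned once on the full table before
    cross-validation; ``"per_fold"`` re-tunes inside every fold.
    """
    if not methods:
        raise ValueError("at least one method required")
    unknown = set(methods) - set(METHODS)
    if unknown:
        raise ValueError(f"unknown methods: {sorted(unknown)}")
    folds = make_folds(table.n_samples, config.n_folds, table.labels, config.seed)
    report: dict = {
        "config": config.to_dict(),
        "n_samples": table.n_samples,
        "n_indices": table.n_indices,
        "methods": {},
        "timing_seconds": {},
    }
    oof_scores: dict[str, np.ndarray] = {}
    artifacts: dict[str, pd.DataFrame] = {
        "folds": pd.DataFrame({"row": np.arange(table.n_samples), "fold": folds})
    }

    for method in methods:
        t0 = time.perf_counter()
        logger.info("running method %s", method)
        if method == "proposed":
            cfg = config
            if isinstance(config.lam, str) and config.tpe_scope == "global":
                lam = tune_lambda_tpe(table, config.replace(lam=0.0))
                logger.info("global TPE selected lambda=%.5g", lam)
                cfg = config.replace(lam=lam)
                report["lambda_tpe_global"] = lam
            cv = cross_validate(table, cfg, fold_assignments=folds)
            sel = select_indices(cv)
            imp = aggregate_importance(cv, table, seed=config.seed)
            scores = cv.oof_posteriors
            block, roc = _roc_block(scores, table.labels)
            block.update(
                {
                    "selected": sorted(sel.selected),
                    "n_selected": len(sel.selected),
                    "ranking": sel.ranking,
                    "fold_lambdas": cv.fold_lambdas,
                }
            )
            artifacts["selected_proposed"] = pd.DataFrame(
                {
                    "name": sel.index_names,
                    "mean_w": sel.mean_weights,
                    "mean_abs_w": sel.mean_abs_weights,
                    "n_folds_nonzero": sel.n_folds_nonzero,
                }
            )
            pi_cols = {
                f"fold_{k + 1}": imp.pi_matrix[k] for k in range(imp.pi_matrix.shape[0])
            }
            artifacts["permutation_importance"] = pd.DataFrame(
                {"name": imp.index_names, **pi_cols, "mean_pi": imp.pi_mean}
            )
        elif method == "kli":
            trace = stepwise_kli_selection(table, config, fold_assignments=folds)
            scores = trace.oof_scores
            block, roc = _roc_block(scores, table.labels)
            block.update(
                {
                    "selected": sorted(trace.selected),
                    "n_selected": len(trace.selected),
                    "ranking": trace.ranking,
                    "removal_order": trace.removal_order,
                    "auc_at_step": trace.auc_at_step,
                }
            )
            artifacts["selected_kli"] = pd.DataFrame(
                {"name": sorted(trace.selected)}
            )
        else:  # lasso
            fit, ranking, scores = lasso_select(
                table, config, fold_assignments=folds
            )
            block, roc = _roc_block(scores, table.labels)
            selected = [
                n for n, b in zip(fit.index_names, fit.coefficients) if b != 0
            ]
            block.update(
                {
                    "selected": sorted(selected),
                    "n_selected": len(selected),
                    "ranking": ranking,
                    "lambda": fit.lam,
                }
            )
            artifacts["selected_lasso"] = pd.DataFrame(
                {"name": fit.index_names, "coefficient": fit.coefficients}
            )
        oof_scores[method] = scores
        artifacts[f"roc_{method}"] = pd.DataFrame(
            {
                "threshold": roc.thresholds,
                "sensitivity": roc.sensitivity,
                "specificity": roc.specificity,
            }
        )
        artifacts[f"scores_{method}"] = pd.DataFrame(
            {"row": np.arange(table.n_samples), "score": scores,
             "label": table.labels}
        )
        report["methods"][method] = block
        report["timing_seconds"][method] = time.perf_counter() - t0

    if len(methods) >= 2:
        pairs = [
            (a, b) for i, a in enumerate(methods) for b in methods[i + 1 :]
        ]
        raw = []
        for a, b in pairs:
            _, p = delong_test(oof_scores[a], oof_scores[b], table.labels)
            raw.append(p)
        adjusted = holm_adjust(raw)
        report["delong"] = [
            {"pair": f"{a} vs {b}", "p_raw": pr, "p_holm": float(ph)}
            for (a, b), pr, ph in zip(pairs, raw, adjusted)
        ]

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, df in artifacts.items():
            df.to_csv(outdir / f"{name}.csv", index=False, float_format="%.17g")
        with open(outdir / "report.json", "w") as fh:
            json.dump(report, fh, indent=1, default=_json_default)
    return report


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def group_comparison_table(table: FeatureTable, alpha: float = 0.05) -> pd.DataFrame:
    """Per-index two-group comparison listing.

    Binary indices (values within {0, 1}) are tested with Fisher's exact test
    and reported as counts/percentages; continuous indices with the
    Brunner-Munzel test and reported as mean +- SD per group.  The returned
    frame has one row per index with the p-value and a significance flag.
    """
    groups = np.unique(table.labels)
    if groups.size < 2:
        raise ValueError("two groups required")
    g1 = table.labels == 1
    rows = []
    for j, name in enumerate(table.index_names):
        col = table.values[:, j]
        a, b = col[g1], col[~g1]
        binary = set(np.unique(col)) <= {0.0, 1.0}
        if binary:
            tab = np.array(
                [
                    [int(a.sum()), int(a.size - a.sum())],
                    [int(b.sum()), int(b.size - b.sum())],
                ]
            )
            from scipy.stats import fisher_exact

            _, p = fisher_exact(tab, alternative="two-sided")
            summary1 = f"{int(a.sum())} ({100 * a.mean():.1f}%)"
            summary2 = f"{int(b.sum())} ({100 * b.mean():.1f}%)"
            test = "fisher"
        else:
            if np.unique(col).size == 1:
                p = np.nan
                test = "degenerate"
            else:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    _, p, _ = brunner_munzel(a, b)
                test = "brunner-munzel"
            summary1 = f"{a.mean():.1f} ± {a.std(ddof=1):.1f}"
            summary2 = f"{b.mean():.1f} ± {b.std(ddof=1):.1f}"
        rows.append(
            {
                "index": name,
                "group1": summary1,
                "group2": summary2,
                "test": test,
                "p_value": p,
                "significant": bool(p < alpha) if np.isfinite(p) else False,
            }
        )
    return pd.DataFrame(rows)
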
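"""ROC analysis, association tests, DeLong AUC comparison, Brunner-Munzel.

AUC is computed as the pairwise concordance probability (Mann-Whitney
statistic with ties counted 1/2), which equals the trapezoidal area under the
empirical ROC curve.  The operating threshold is the one maximizing
sensitivity + specificity (Youden).  Standard tests delegate to scipy /
statsmodels; DeLong's covariance of paired AUCs is implemented via placement
values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


@dataclass
class ROCResult:
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    best_threshold: float
    sens_at_best: float
    spec_at_best: float


def _as_pos_mask(labels: np.ndarray) -> np.ndarray:
    """Positive = class 1 for {1,2}-coded labels, truthiness otherwise."""
    labels = np.asarray(labels)
    if set(np.unique(labels)) <= {1, 2}:
        return labels == 1
    return labels.astype(bool)


def auc_mann_whitney(scores: np.ndarray, pos: np.ndarray) -> float:
    """AUC as the tie-aware pairwise concordance probability."""
    scores = np.asarray(scores, float)
    ranks = sps.rankdata(scores)  # midranks
    n_pos = int(pos.sum())
    n_neg = pos.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    return float((ranks[pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def roc_analysis(scores: np.ndarray, labels: np.ndarray) -> ROCResult:
    """ROC curve over midpoint thresholds with +-inf sentinels.

    A sample is predicted positive when its score >= threshold.  The best
    threshold maximizes sensitivity + specificity, ties broken by higher
    sensitivity, then by lower threshold.
    """
    scores = np.asarray(scores, float)
    pos = _as_pos_mask(labels)
    n_pos = int(pos.sum())
    n_neg = pos.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present for ROC analysis")

    distinct = np.unique(scores)
    mids = (distinct[:-1] + distinct[1:]) / 2
    thresholds = np.concatenate(([-np.inf], mids, [np.inf]))
    sens = np.empty(thresholds.size)
    spec = np.empty(thresholds.size)
    for j, thr in enumerate(thresholds):
        pred = scores >= thr
        sens[j] = (pred & pos).sum() / n_pos
        spec[j] = (~pred & ~pos).sum() / n_neg

    auc = auc_mann_whitney(scores, pos)
    youden = sens + spec
    # lexicographic: max youden, then max sensitivity, then min threshold
    best = min(
        range(thresholds.size), key=lambda j: (-youden[j], -sens[j], thresholds[j])
    )
    return ROCResult(
        thresholds,
        sens,
        spec,
        auc,
        float(thresholds[best]),
        float(sens[best]),
        float(spec[best]),
    )


@dataclass
class ContingencyTable2x2:
    """Counts with rows = actual (pos, neg) and cols = predicted (pos, neg)."""

    a: int  # actual pos, predicted pos
    b: int  # actual pos, predicted neg
    c: int  # actual neg, predicted pos
    d: int  # actual neg, predicted neg

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


def confusion_and_association(
    predicted: np.ndarray, actual: np.ndarray
) -> tuple[ContingencyTable2x2, float, float]:
    """2x2 table, two-sided Fisher exact p, and Yule's Q = (ad-bc)/(ad+bc).

    Q is NaN (with a warning) when ad + bc = 0 — undefined, not silently 0.
    """
    pred = _as_pos_mask(predicted)
    act = _as_pos_mask(actual)
    if pred.shape != act.shape or pred.size == 0:
        raise ValueError("predicted and actual must be equal-length, non-empty")
    tab = ContingencyTable2x2(
        int((act & pred).sum()),
        int((act & ~pred).sum()),
        int((~act & pred).sum()),
        int((~act & ~pred).sum()),
    )
    _, fisher_p = sps.fisher_exact(tab.as_array(), alternative="two-sided")
    ad, bc = tab.a * tab.d, tab.b * tab.c
    if ad + bc == 0:
        warnings.warn("Yule's Q undefined (ad + bc = 0)", stacklevel=2)
        q = float("nan")
    else:
        q = (ad - bc) / (ad + bc)
    return tab, float(fisher_p), float(q)


def _placements(scores: np.ndarray, pos: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """DeLong placement values V10 (per positive) and V01 (per negative)."""
    s_pos = scores[pos][:, None]
    s_neg = scores[~pos][None, :]
    psi = (s_pos > s_neg).astype(float) + 0.5 * (s_pos == s_neg)
    return psi.mean(axis=1), 1.0 - psi.mean(axis=0)


def delong_auc_variance(scores: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """AUC and its DeLong variance estimate for a single score vector."""
    scores = np.asarray(scores, float)
    pos = _as_pos_mask(labels)
    v10, v01 = _placements(scores, pos)
    auc = float(v10.mean())
    m, n = v10.size, v01.size
    var = v10.var(ddof=1) / m + (1.0 - v01).var(ddof=1) / n
    return auc, float(var)


def delong_test(
    scores_a: np.ndarray, scores_b: np.ndarray, labels: np.ndarray
) -> tuple[float, float]:
    """Paired DeLong test of AUC_A vs AUC_B on the same samples.

    Returns (z, two-sided p).  Zero variance of the difference (e.g. identical
    score vectors) yields z = 0, p = 1 with a warning.
    """
    scores_a = np.asarray(scores_a, float)
    scores_b = np.asarray(scores_b, float)
    pos = _as_pos_mask(labels)
    if scores_a.shape != scores_b.shape:
        raise ValueError("paired score vectors must have equal length")
    v10a, v01a = _placements(scores_a, pos)
    v10b, v01b = _placements(scores_b, pos)
    auc_a, auc_b = v10a.mean(), v10b.mean()
    m, n = v10a.size, v01a.size
    s10 = np.cov(np.vstack([v10a, v10b]), ddof=1)
    s01 = np.cov(np.vstack([1 - v01a, 1 - v01b]), ddof=1)
    cov = s10 / m + s01 / n
    var_diff = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    if var_diff <= 0:
        warnings.warn(
            "zero DeLong variance of the AUC difference; p set to 1", stacklevel=2
        )
        return 0.0, 1.0
    z = float((auc_a - auc_b) / np.sqrt(var_diff))
    p = float(2 * sps.norm.sf(abs(z)))
    return z, p


def holm_adjust(pvals) -> np.ndarray:
    """Step-down Holm adjustment with monotonicity enforcement, capped at 1."""
    pvals = np.asarray(pvals, float)
    if pvals.size == 0:
        return pvals
    if np.any((pvals < 0) | (pvals > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    _, adjusted, _, _ = multipletests(pvals, method="holm")
    return adjusted


def brunner_munzel(
    sample_a: np.ndarray, sample_b: np.ndarray
) -> tuple[float, float, float]:
    """Brunner-Munzel test: (statistic, two-sided p, relative effect).

    The relative effect p_hat = P(A < B) + 0.5 P(A = B) is estimated via
    midranks; statistic and p use the studentized form with Welch-type
    degrees of freedom (t reference distribution).  All-tied samples have no
    rank variance; statistic/p are NaN with a warning.
    """
    a = np.asarray(sample_a, float)
    b = np.asarray(sample_b, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 values")
    ranks = sps.rankdata(np.concatenate([a, b]))
    rb = ranks[a.size :].mean()
    p_hat = (rb - (b.size + 1) / 2) / a.size
    if np.unique(np.concatenate([a, b])).size == 1:
        warnings.warn("all values tied; Brunner-Munzel statistic undefined",
                      stacklevel=2)
        return float("nan"), float("nan"), float(p_hat)
    with np.errstate(divide="ignore", invalid="ignore"):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            stat, p = sps.brunnermunzel(a, b)
    if not np.isfinite(stat):
        warnings.warn("degenerate rank variance in Brunner-Munzel", stacklevel=2)
    return float(stat), float(p), float(p_hat)
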
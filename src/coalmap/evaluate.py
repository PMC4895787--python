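"""ROC evaluation of association scores against causal-SNP ground truth.

Scores are p-values (smaller = more significant); ROC curves are built on
the negated scores with tie-aware steps, so the trapezoidal AUROC equals
the Mann-Whitney statistic with tie correction.  Correlated AUROCs of two
methods scored on the same instances are compared with the DeLong
placement-value (structural-component) test, and families of such
comparisons are corrected with Benjamini-Hochberg.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score, roc_curve
from statsmodels.stats.multitest import multipletests

__all__ = [
    "RocSummary",
    "roc_and_auroc",
    "delong_test",
    "bh_correct",
    "causal_pvalue_histogram",
    "plot_roc_overlay",
]


@dataclass
class RocSummary:
    """A pooled ROC curve with its headline scalars."""

    fpr: np.ndarray
    tpr: np.ndarray
    auroc: float
    tpr_at_fpr: float
    fpr_target: float
    n_pos: int
    n_neg: int


def _check_labels(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels).astype(bool)
    if labels.all() or not labels.any():
        raise ValueError("ROC needs at least one positive and one negative")
    return labels


def roc_and_auroc(
    pvalues: np.ndarray, labels: np.ndarray, fpr_target: float = 0.05
) -> RocSummary:
    """ROC curve, AUROC, and conservative TPR at a target FPR.

    ``labels`` marks causal SNPs (positives); smaller p-values rank more
    positive.  The TPR at the target FPR is the largest TPR achievable by
    a threshold whose FPR does not exceed the target (step-function
    evaluation, no interpolation).
    """
    pvalues = np.asarray(pvalues, dtype=float)
    labels = _check_labels(labels)
    scores = -pvalues
    fpr, tpr, _ = roc_curve(labels, scores, drop_intermediate=False)
    auroc = float(roc_auc_score(labels, scores))
    ok = fpr <= fpr_target + 1e-12
    tpr_at = float(tpr[ok].max()) if ok.any() else 0.0
    return RocSummary(
        fpr=fpr,
        tpr=tpr,
        auroc=auroc,
        tpr_at_fpr=tpr_at,
        fpr_target=fpr_target,
        n_pos=int(labels.sum()),
        n_neg=int((~labels).sum()),
    )


def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def delong_test(
    pvalues_a: np.ndarray, pvalues_b: np.ndarray, labels: np.ndarray
) -> tuple[float, float, float, float]:
    """DeLong comparison of two correlated AUROCs on the same instances.

    Returns ``(auroc_a, auroc_b, z, p)`` with a two-sided normal p-value.
    The AUROC covariance is estimated from the per-instance placement
    values (structural components).  A non-positive variance of the
    difference (e.g. identical score vectors) yields ``z = 0, p = 1``.
    """
    labels = _check_labels(labels)
    pvalues_a = np.asarray(pvalues_a, dtype=float)
    pvalues_b = np.asarray(pvalues_b, dtype=float)
    if pvalues_a.shape != pvalues_b.shape or pvalues_a.size != labels.size:
        raise ValueError("both score vectors must align with the labels")

    m = int(labels.sum())
    n = int((~labels).sum())
    v10 = np.empty((2, m))
    v01 = np.empty((2, n))
    aucs = np.empty(2)
    for i, p in enumerate((pvalues_a, pvalues_b)):
        s = -p
        pos, neg = s[labels], s[~labels]
        all_r = _midrank(np.concatenate([pos, neg]))
        pos_r, neg_r = _midrank(pos), _midrank(neg)
        # placement values: fraction of the other class each instance beats
        v10[i] = (all_r[:m] - pos_r) / n
        v01[i] = 1.0 - (all_r[m:] - neg_r) / m
        aucs[i] = v10[i].mean()

    s10 = np.cov(v10)
    s01 = np.cov(v01)
    var_diff = (
        (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m
        + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    )
    if var_diff <= 0:
        return float(aucs[0]), float(aucs[1]), 0.0, 1.0
    z = (aucs[0] - aucs[1]) / np.sqrt(var_diff)
    p = 2.0 * stats.norm.sf(abs(z))
    return float(aucs[0]), float(aucs[1]), float(z), float(min(p, 1.0))


def bh_correct(
    pvals, alpha: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up q-values and rejection set."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return np.array([]), np.array([], dtype=bool)
    reject, qvals, _, _ = multipletests(pvals, alpha=alpha, method="fdr_bh")
    return qvals, reject


def plot_roc_overlay(summaries: dict[str, RocSummary], path) -> None:
    """Overlay ROC curves of several methods and save to ``path``.

    Requires matplotlib (optional dependency, ``coalmap[plot]``).
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    for name, s in summaries.items():
        ax.step(s.fpr, s.tpr, where="post",
                label=f"{name} (AUROC {s.auroc:.3f})")
    ax.plot([0, 1], [0, 1], ls=":", c="grey", lw=1)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def causal_pvalue_histogram(
    pvalues_by_method: dict[str, np.ndarray],
    labels: np.ndarray,
    cutoffs: np.ndarray | None = None,
) -> pd.DataFrame:
    """Cumulative counts of causal-SNP p-values at a grid of cutoffs.

    Pools over whatever replicates the callers concatenated into the
    vectors; one column per method, one row per cutoff.
    """
    labels = np.asarray(labels).astype(bool)
    if cutoffs is None:
        cutoffs = np.concatenate([[1e-12], np.logspace(-10, 0, 41)])
    out = {"cutoff": np.asarray(cutoffs, dtype=float)}
    for name, p in pvalues_by_method.items():
        p = np.asarray(p, dtype=float)[labels]
        out[name] = np.array([(p <= c).sum() for c in cutoffs], dtype=int)
    return pd.DataFrame(out)
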
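"""Classification metrics: confusion counts, exact binomial CIs, ROC/AUC.

Responders are the positive class everywhere. Accuracy confidence
intervals use the exact Clopper–Pearson construction (inversion of the
exact binomial test, computed from beta quantiles). AUC is the
trapezoidal / Mann–Whitney statistic with midrank tie handling; its CI is
computed by DeLong's method (implemented here — no pre-installed package
exposes it).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError
from .io import ExpressionMatrix


@dataclass(frozen=True)
class EvaluationReport:
    tp: int
    fn: int
    tn: int
    fp: int
    sensitivity: float
    specificity: float
    accuracy: float
    accuracy_ci_95: tuple[float, float]
    auc: float | None = None
    auc_ci_95: tuple[float, float] | None = None

    def to_dict(self) -> dict:
        d = {
            "tp": self.tp, "fn": self.fn, "tn": self.tn, "fp": self.fp,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
            "accuracy_ci_95": list(self.accuracy_ci_95),
        }
        if self.auc is not None:
            d["auc"] = self.auc
            d["auc_ci_95"] = list(self.auc_ci_95)
        return d


def clopper_pearson_ci(successes: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Exact binomial confidence interval.

    Beta-quantile closed form: low = B(alpha/2; k, n-k+1),
    high = B(1-alpha/2; k+1, n-k); low = 0 at k = 0 and high = 1 at k = n.
    """
    if n < 1 or not 0 <= successes <= n:
        raise DataError(f"invalid counts ({successes}, {n})")
    if not 0.0 < level < 1.0:
        raise DataError("confidence level must be in (0, 1)")
    alpha = 1.0 - level
    k = successes
    low = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    high = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return (low, high)


def confusion_metrics_from_counts(tp: int, fn: int, tn: int, fp: int) -> EvaluationReport:
    """Sensitivity/specificity/accuracy (+ exact accuracy CI) from counts."""
    if min(tp, fn, tn, fp) < 0 or tp + fn + tn + fp == 0:
        raise DataError("invalid confusion counts")
    n = tp + fn + tn + fp
    return EvaluationReport(
        tp=tp, fn=fn, tn=tn, fp=fp,
        sensitivity=tp / (tp + fn) if tp + fn else float("nan"),
        specificity=tn / (tn + fp) if tn + fp else float("nan"),
        accuracy=(tp + tn) / n,
        accuracy_ci_95=clopper_pearson_ci(tp + tn, n),
    )


def confusion_metrics(
    predicted: Sequence[int],
    truth: Sequence[int],
) -> EvaluationReport:
    """Compare predicted labels with truth (1 = responder = positive)."""
    yhat = np.asarray(predicted, dtype=int)
    y = np.asarray(truth, dtype=int)
    if yhat.shape != y.shape or y.size == 0:
        raise DataError("predicted and truth labels must align and be non-empty")
    return confusion_metrics_from_counts(
        tp=int(((yhat == 1) & (y == 1)).sum()),
        fn=int(((yhat == 0) & (y == 1)).sum()),
        tn=int(((yhat == 0) & (y == 0)).sum()),
        fp=int(((yhat == 1) & (y == 0)).sum()),
    )


def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def roc_auc(
    scores: Sequence[float],
    truth: Sequence[int],
    level: float = 0.95,
) -> tuple[float, tuple[float, float]]:
    """AUC with a DeLong confidence interval.

    The midrank AUC equals the normalized Mann–Whitney U statistic and the
    trapezoidal area under the empirical ROC curve. The DeLong variance is
    computed from the per-observation placement values; the CI is a normal
    interval on that variance, clipped to [0, 1]. A degenerate variance
    (perfect separation) yields a point interval.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(truth, dtype=int)
    if s.shape != y.shape:
        raise DataError("scores and truth must align")
    pos = s[y == 1]
    neg = s[y == 0]
    m, n = len(pos), len(neg)
    if m == 0 or n == 0:
        raise DataError("both classes must be present")
    all_ranks = _midrank(np.concatenate([pos, neg]))
    auc = (all_ranks[:m].sum() - m * (m + 1) / 2) / (m * n)

    # DeLong structural components: V10 over positives, V01 over negatives
    v10 = (all_ranks[:m] - _midrank(pos)) / n
    v01 = 1.0 - (all_ranks[m:] - _midrank(neg)) / m
    var = 0.0
    if m > 1:
        var += np.var(v10, ddof=1) / m
    if n > 1:
        var += np.var(v01, ddof=1) / n
    z = stats.norm.ppf(0.5 + level / 2)
    half = z * np.sqrt(var)
    ci = (float(max(0.0, auc - half)), float(min(1.0, auc + half)))
    return float(auc), ci


def signature_gene_de(
    expr: ExpressionMatrix,
    truth: Sequence[int],
    genes: Sequence[str],
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, int]:
    """Per-gene Welch t-test between responders and non-responders.

    Returns the per-gene table (mean per class, t, p) and the count of genes
    with p < alpha. A gene with zero variance in both classes has an
    undefined statistic and is reported as NA (and not counted).
    """
    y = np.asarray(truth, dtype=int)
    if y.shape != (expr.n_samples,):
        raise DataError("truth labels must align with samples")
    gene_idx = expr.gene_index()
    missing = [g for g in genes if g not in gene_idx]
    if missing:
        raise DataError(f"genes absent from matrix: {missing}")
    x = expr.values[[gene_idx[g] for g in genes]]
    a = x[:, y == 1]
    b = x[:, y == 0]
    rows = []
    for i, gene in enumerate(genes):
        if a[i].var(ddof=0) == 0.0 and b[i].var(ddof=0) == 0.0:
            t_stat, p = np.nan, np.nan
        else:
            res = stats.ttest_ind(a[i], b[i], equal_var=False)
            t_stat, p = float(res.statistic), float(res.pvalue)
        rows.append((gene, float(a[i].mean()), float(b[i].mean()), t_stat, p))
    table = pd.DataFrame(
        rows, columns=["gene", "mean_responder", "mean_nonresponder", "t", "p"]
    ).set_index("gene")
    n_de = int((table["p"] < alpha).sum())
    return table, n_de
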
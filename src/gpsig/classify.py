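"""Apply a gene-pair signature to samples.

A sample "votes response" on a pair when its within-sample ordering shows
gene_a > gene_b. The response ratio (votes / evaluable pairs) is the
continuous score used for ROC curves and high/low grouping; the hard label
is a strict majority vote. Signature pairs whose genes are missing from
the expression platform are dropped per sample rather than failing the run,
so a signature discovered on one array can be applied on another.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError, DegenerateInputError
from .io import ExpressionMatrix, Signature


@dataclass(frozen=True)
class PredictionResult:
    sample_id: str
    n_response_pairs: int
    n_evaluable_pairs: int
    score: float           # n_response_pairs / n_evaluable_pairs
    label: int             # 1 = responder

    def __post_init__(self):
        if not 0 <= self.n_response_pairs <= self.n_evaluable_pairs:
            raise DataError("response-pair count out of range")
        if not 0.0 <= self.score <= 1.0:
            raise DataError("score out of [0, 1]")


def predictions_frame(predictions: list[PredictionResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [(p.sample_id, p.n_response_pairs, p.n_evaluable_pairs, p.score, p.label)
         for p in predictions],
        columns=["sample_id", "n_response_pairs", "n_evaluable_pairs", "score", "label"],
    ).set_index("sample_id")


def predict(expr: ExpressionMatrix, signature: Signature) -> list[PredictionResult]:
    """Count response-orientation pairs per sample and vote a label.

    Label = responder iff strictly more than half of the evaluable pairs are
    in response orientation; an exact tie (possible for an even evaluable
    count) is called non-responder — no majority, no predicted benefit.
    """
    if len(signature) == 0:
        raise DataError("empty signature")
    gene_idx = expr.gene_index()
    absent_genes = {g for g in signature.genes if g not in gene_idx}
    if absent_genes:
        frac = len(absent_genes) / len(signature.genes)
        if frac > 0.20:
            warnings.warn(
                f"{len(absent_genes)} of {len(signature.genes)} signature genes "
                f"absent from the matrix ({frac:.0%})",
                stacklevel=2,
            )
    evaluable = [
        (a, b) for a, b in signature.pairs
        if a in gene_idx and b in gene_idx
    ]
    if not evaluable:
        raise DataError("no signature pair is evaluable on this matrix")
    rows_a = np.array([gene_idx[a] for a, _ in evaluable])
    rows_b = np.array([gene_idx[b] for _, b in evaluable])
    votes = (expr.values[rows_a] > expr.values[rows_b]).sum(axis=0)
    n_eval = len(evaluable)

    results = []
    for s, sample in enumerate(expr.sample_ids):
        k = int(votes[s])
        results.append(PredictionResult(
            sample_id=sample,
            n_response_pairs=k,
            n_evaluable_pairs=n_eval,
            score=k / n_eval,
            label=int(k * 2 > n_eval),
        ))
    return results


def split_high_low(predictions: list[PredictionResult]) -> pd.Series:
    """Median split on the response-pair count.

    High = strictly above the median count; ties at the median go low.
    Used when no response label exists and survival is compared between
    signature-defined groups.
    """
    if len(predictions) < 2:
        raise DataError("median split needs >= 2 samples")
    counts = np.array([p.n_response_pairs for p in predictions], dtype=float)
    if np.all(counts == counts[0]):
        raise DegenerateInputError("all samples have the same response-pair count")
    median = float(np.median(counts))
    return pd.Series(
        counts > median,
        index=pd.Index([p.sample_id for p in predictions], name="sample_id"),
        name="high_response",
    )


def response_ratio_by_group(
    predictions: list[PredictionResult],
    grouping: pd.Series,
) -> dict:
    """Mean response ratio per group plus a Welch t-test on the scores.

    ``grouping`` is a boolean series indexed by sample id (True = first
    group, e.g. treatment-sensitive). Groups of size < 2 skip the t-test
    with a warning; means are still returned.
    """
    scores = pd.Series(
        {p.sample_id: p.score for p in predictions}, name="score"
    ).loc[grouping.index]
    a = scores[grouping.astype(bool)].to_numpy()
    b = scores[~grouping.astype(bool)].to_numpy()
    if len(a) == 0 or len(b) == 0:
        raise DataError("both groups must be non-empty")
    out = {
        "mean_true": float(a.mean()),
        "mean_false": float(b.mean()),
        "n_true": len(a),
        "n_false": len(b),
        "p_value": None,
    }
    if len(a) < 2 or len(b) < 2:
        warnings.warn("a group has < 2 samples; t-test skipped", stacklevel=2)
        return out
    t = stats.ttest_ind(a, b, equal_var=False)
    out["t_statistic"] = float(t.statistic)
    out["p_value"] = float(t.pvalue)
    return out
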
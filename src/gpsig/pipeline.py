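"""End-to-end workflows: discover a signature, validate one.

``run_discover`` chains the reversal screen, random-forest importance
ranking and best top-N selection on a labeled training cohort.
``run_validate`` applies a signature to a cohort: majority-vote
predictions, confusion metrics with exact CIs and AUC, and — when survival
columns are present — KM/log-rank and covariate-adjusted Cox between
signature-defined groups.

All randomness flows from one top-level seed, fanned out per stage through
``numpy.random.SeedSequence`` so each stage is independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classify import PredictionResult, predict, predictions_frame, split_high_low
from .errors import DataError
from .evaluate import EvaluationReport, confusion_metrics, roc_auc
from .io import ExpressionMatrix, PhenotypeTable, Signature
from .ranking import RFConfig, RankedPairs, encode_pairs, rank_by_mdg
from .reo import DEFAULT_ALPHA, find_reversal_pairs
from .selection import DEFAULT_N_MAX, select_best_top_n
from .survival import CoxResult, KMResult, cox_adjusted, km_logrank, make_survival_dataset


def fan_out_seed(seed: int, n: int) -> list[int]:
    """Derive n per-stage 31-bit seeds from one top-level seed."""
    return [int(s) % 2**31 for s in np.random.SeedSequence(seed).generate_state(n)]


@dataclass(frozen=True)
class DiscoverResult:
    signature: Signature
    ranked: RankedPairs
    curve: pd.DataFrame = field(repr=False)
    report: EvaluationReport
    n_reversal_pairs: int
    params: dict


def run_discover(
    expr: ExpressionMatrix,
    pheno: PhenotypeTable,
    alpha: float = DEFAULT_ALPHA,
    rf_config: RFConfig | None = None,
    n_max: int | None = DEFAULT_N_MAX,
    candidate_pairs=None,
    allow_large: bool = False,
) -> DiscoverResult:
    """Screen -> rank -> select on a labeled training cohort."""
    try:
        records = find_reversal_pairs(
            expr, pheno, alpha=alpha, candidate_pairs=candidate_pairs,
            allow_large=allow_large,
        )
    except DataError as exc:
        raise DataError(f"screen stage: {exc}") from exc
    if not records:
        raise DataError("screen stage: no reversal pairs at this alpha")
    labels = pheno.response_labels(expr.sample_ids)
    rf_config = rf_config or RFConfig()
    try:
        features = encode_pairs(expr, records)
        ranked = rank_by_mdg(features, labels, rf_config)
    except DataError as exc:
        raise DataError(f"rank stage: {exc}") from exc
    try:
        signature = select_best_top_n(ranked, expr, labels, n_max=n_max)
    except DataError as exc:
        raise DataError(f"select stage: {exc}") from exc

    predictions = predict(expr, signature)
    report = evaluate_predictions(predictions, labels)
    return DiscoverResult(
        signature=signature,
        ranked=ranked,
        curve=signature.provenance["curve"],
        report=report,
        n_reversal_pairs=len(records),
        params={
            "alpha": alpha,
            "n_max": n_max,
            **ranked.metadata,
        },
    )


def evaluate_predictions(
    predictions: list[PredictionResult], truth
) -> EvaluationReport:
    """Confusion metrics plus AUC over the response-ratio scores."""
    labels = [p.label for p in predictions]
    scores = [p.score for p in predictions]
    report = confusion_metrics(labels, truth)
    auc, auc_ci = roc_auc(scores, truth)
    return EvaluationReport(
        tp=report.tp, fn=report.fn, tn=report.tn, fp=report.fp,
        sensitivity=report.sensitivity, specificity=report.specificity,
        accuracy=report.accuracy, accuracy_ci_95=report.accuracy_ci_95,
        auc=auc, auc_ci_95=auc_ci,
    )


@dataclass(frozen=True)
class ValidateResult:
    predictions: list[PredictionResult]
    report: EvaluationReport | None
    km: KMResult | None = None
    cox: CoxResult | None = None

    @property
    def predictions_frame(self) -> pd.DataFrame:
        return predictions_frame(self.predictions)


def run_validate(
    expr: ExpressionMatrix,
    signature: Signature,
    pheno: PhenotypeTable | None = None,
    survival: bool = True,
    cox_covariates: tuple[str, ...] = (),
    group_by: str = "label",
) -> ValidateResult:
    """Apply a signature; evaluate against labels and survival if available.

    ``group_by``: "label" stratifies survival by the voted responder call
    (used when true labels exist for training-style cohorts), "median"
    uses the high/low split on the response-pair count (used when no
    response annotation exists).
    """
    predictions = predict(expr, signature)
    report = None
    km = cox = None
    if pheno is not None:
        have_response = pheno.df["response"].notna().all()
        if have_response:
            truth = pheno.response_labels(expr.sample_ids)
            try:
                report = evaluate_predictions(predictions, truth)
            except DataError as exc:
                raise DataError(f"evaluate stage: {exc}") from exc
        if survival and pheno.df["dfs_time"].notna().all():
            if group_by == "median":
                grouping = split_high_low(predictions)
                group = grouping.map({True: "high", False: "low"})
            else:
                group = pd.Series(
                    {p.sample_id: ("responder" if p.label else "non-responder")
                     for p in predictions}, name="group",
                )
            sub = pheno.df.loc[list(expr.sample_ids)]
            dataset = make_survival_dataset(
                group.loc[list(expr.sample_ids)],
                sub["dfs_time"], sub["dfs_event"],
                covariates=sub[list(cox_covariates)] if cox_covariates else None,
            )
            try:
                km = km_logrank(dataset)
                cox = cox_adjusted(dataset, covariates=cox_covariates)
            except DataError as exc:
                raise DataError(f"survival stage: {exc}") from exc
    return ValidateResult(predictions=predictions, report=report, km=km, cox=cox)
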
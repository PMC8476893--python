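"""Survival stratification: Kaplan–Meier, log-rank, covariate-adjusted Cox.

Groups come from the signature (hard responder/non-responder labels, or the
high/low median split when no label exists). Disease-free survival is the
time from surgery to relapse or last follow-up, in months. Mean survival
per group is reported as the restricted mean survival time (RMST) over the
observed follow-up window — the only mean that is well-defined under
censoring. Tied event times use the Efron approximation (the lifelines
default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test
from lifelines.utils import restricted_mean_survival_time

from .errors import DataError, DegenerateInputError


@dataclass(frozen=True)
class SurvivalDataset:
    """Per-sample group indicator, DFS time/event and optional covariates."""

    df: pd.DataFrame = field(repr=False)  # columns: group, dfs_time, dfs_event [+ covariates]

    def __post_init__(self):
        for col in ("group", "dfs_time", "dfs_event"):
            if col not in self.df.columns:
                raise DataError(f"survival dataset needs a {col!r} column")
        if (self.df["dfs_time"] < 0).any():
            raise DataError("negative dfs_time")
        if not self.df["dfs_event"].isin((0, 1)).all():
            raise DataError("dfs_event must be 0/1")
        if self.df["group"].nunique() < 2:
            raise DataError("need >= 2 groups")


@dataclass(frozen=True)
class KMResult:
    curves: dict            # group -> DataFrame(time, survival)
    statistic: float        # log-rank chi-square
    p_value: float
    rmst: dict              # group -> restricted mean survival time
    rmst_horizon: float


def km_logrank(dataset: SurvivalDataset) -> KMResult:
    """Product-limit curves per group and the two-group log-rank test.

    With no events anywhere the log-rank statistic is undefined and an
    explicit error is raised. RMST is computed to the latest observed time.
    """
    df = dataset.df
    groups = sorted(df["group"].unique())
    if len(groups) != 2:
        raise DataError(f"two-group log-rank expected 2 groups, got {len(groups)}")
    if df["dfs_event"].sum() == 0:
        raise DegenerateInputError("no events in either group; log-rank undefined")
    horizon = float(df["dfs_time"].max())
    curves: dict = {}
    rmst: dict = {}
    for g in groups:
        sub = df[df["group"] == g]
        km = KaplanMeierFitter()
        km.fit(sub["dfs_time"], sub["dfs_event"], label=str(g))
        surv = km.survival_function_
        curves[g] = pd.DataFrame(
            {"time": surv.index.to_numpy(dtype=float),
             "survival": surv.iloc[:, 0].to_numpy()}
        )
        rmst[g] = float(restricted_mean_survival_time(km, t=horizon))
    a = df[df["group"] == groups[0]]
    b = df[df["group"] == groups[1]]
    res = logrank_test(a["dfs_time"], b["dfs_time"], a["dfs_event"], b["dfs_event"])
    return KMResult(
        curves=curves,
        statistic=float(res.test_statistic),
        p_value=float(res.p_value),
        rmst=rmst,
        rmst_horizon=horizon,
    )


@dataclass(frozen=True)
class CoxResult:
    hazard_ratio: float      # for the group indicator
    ci_95: tuple[float, float]
    p_value: float
    log_hr: float
    summary: pd.DataFrame = field(repr=False)


def cox_adjusted(
    dataset: SurvivalDataset,
    covariates: tuple[str, ...] = (),
) -> CoxResult:
    """Cox proportional-hazards fit for the group indicator, adjusted for
    the named covariates.

    Categorical covariates (``stage``, ``gender``, any non-numeric column)
    enter as indicator contrasts; ``age`` and other numeric columns enter
    as-is. The hazard ratio is for group membership (coded 1 vs 0), with a
    Wald confidence interval. Complete separation / a monotone partial
    likelihood is surfaced as an error with lifelines' diagnostic attached.
    """
    df = dataset.df
    for cov in covariates:
        if cov not in df.columns:
            raise DataError(f"covariate {cov!r} not in dataset")
        if df[cov].isna().any():
            raise DataError(f"covariate {cov!r} has missing values")
    n_events = int(df["dfs_event"].sum())
    groups = sorted(df["group"].unique())
    if len(groups) != 2:
        raise DataError("cox_adjusted expects a binary group indicator")
    model = pd.DataFrame({
        "group": (df["group"] == groups[1]).astype(float),
        "dfs_time": df["dfs_time"].astype(float),
        "dfs_event": df["dfs_event"].astype(int),
    }, index=df.index)
    for cov in covariates:
        col = df[cov]
        if col.dtype.kind in "biufc" and col.nunique() > 2:
            model[cov] = col.astype(float)
        else:
            dummies = pd.get_dummies(col.astype(str), prefix=cov, drop_first=True)
            for c in dummies.columns:
                model[c] = dummies[c].astype(float)
    n_params = model.shape[1] - 2
    if n_events < n_params:
        raise DataError(
            f"{n_events} events cannot support {n_params} parameters"
        )
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", category=RuntimeWarning)
            cph.fit(model, duration_col="dfs_time", event_col="dfs_event")
    except (ConvergenceError, RuntimeWarning) as exc:
        raise DataError(
            f"Cox fit failed to converge (possible complete separation): {exc}"
        ) from exc
    row = cph.summary.loc["group"]
    return CoxResult(
        hazard_ratio=float(np.exp(row["coef"])),
        ci_95=(float(np.exp(row["coef lower 95%"])), float(np.exp(row["coef upper 95%"]))),
        p_value=float(row["p"]),
        log_hr=float(row["coef"]),
        summary=cph.summary,
    )


def make_survival_dataset(
    group: pd.Series,
    dfs_time: pd.Series,
    dfs_event: pd.Series,
    covariates: pd.DataFrame | None = None,
) -> SurvivalDataset:
    """Assemble a survival dataset from aligned per-sample series."""
    df = pd.DataFrame({
        "group": group,
        "dfs_time": pd.to_numeric(dfs_time),
        "dfs_event": pd.to_numeric(dfs_event).astype(int),
    })
    if covariates is not None:
        for col in covariates.columns:
            df[col] = covariates[col]
    if df[["group", "dfs_time", "dfs_event"]].isna().any().any():
        raise DataError("missing group/time/event values")
    return SurvivalDataset(df)
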
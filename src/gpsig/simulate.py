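"""Synthetic cohorts with planted reversal pairs and linked survival.

The generator emulates the statistical world the pipeline assumes:

* two classes (responders / non-responders) of configurable size;
* a set of planted gene pairs whose within-sample ordering is forced to the
  responder orientation with probability ``stability_resp`` in responders
  and ``1 - stability_nonresp`` in non-responders — planting swaps the two
  values where needed, so per-class orientation frequencies are exact,
  matching the binomial model of the screen;
* a majority of null genes with independent Gaussian log2 expression;
* optional per-sample strictly increasing distortions (batch surrogates)
  drawn from a seeded parameterized family — REO-based computation must be
  bit-identical with and without them;
* exponential survival whose hazard depends on true response status, with
  independent censoring.

Both partner genes of a planted pair share a baseline mean, so the planted
signal lives (almost) purely in the ordering rather than in per-gene
abundance. What the generator does NOT emulate: gene–gene correlation
structure and platform-specific probe effects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError
from .io import ExpressionMatrix, PhenotypeTable

TRANSFORM_FAMILIES = ("affine", "power", "logistic", "mixed")


@dataclass(frozen=True)
class SimulationConfig:
    """Stated world for one simulated cohort.

    Defaults describe the reference recovery scenario used throughout the
    tests: 500 genes, 50 planted pairs (100 planted genes, 400 null genes),
    40 + 40 samples, orientation stability 0.95 in each class, unit log2
    noise, true hazard ratio 0.25 for responders, 30% censoring.
    """

    n_genes: int = 500
    n_resp: int = 40
    n_nonresp: int = 40
    n_planted_pairs: int = 50
    stability_resp: float = 0.95
    stability_nonresp: float = 0.95
    noise_sd: float = 1.0
    batch_transforms: str | None = None   # None or one of TRANSFORM_FAMILIES
    hr_true: float = 0.25
    censor_rate: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.stability_resp <= 1.0 and 0.0 < self.stability_nonresp <= 1.0):
            raise DataError("stabilities must be in (0, 1]")
        if self.n_planted_pairs * 2 > self.n_genes:
            raise DataError("planted pairs need 2 genes each")
        if self.noise_sd <= 0:
            raise DataError("noise_sd must be > 0")
        if self.hr_true <= 0:
            raise DataError("hr_true must be > 0")
        if not 0.0 <= self.censor_rate < 1.0:
            raise DataError("censor_rate must be in [0, 1)")
        if self.batch_transforms is not None and self.batch_transforms not in TRANSFORM_FAMILIES:
            raise DataError(f"unknown transform family {self.batch_transforms!r}")
        if min(self.n_resp, self.n_nonresp) < 2:
            raise DataError("need >= 2 samples per class")


def _monotone_transform(kind: str, rng: np.random.Generator):
    """One strictly increasing R -> R map with randomly drawn parameters."""
    if kind == "mixed":
        kind = rng.choice(("affine", "power", "logistic"))
    if kind == "affine":
        a = rng.uniform(0.5, 2.0)
        b = rng.uniform(-2.0, 2.0)
        return lambda x: a * x + b
    if kind == "power":
        c = rng.uniform(1.2, 3.0)
        # shift keeps the base positive so the power map stays monotone
        return lambda x: np.power(x - x.min() + 1.0, c)
    if kind == "logistic":
        k = rng.uniform(0.3, 1.0)
        x0 = rng.uniform(4.0, 12.0)
        return lambda x: 1.0 / (1.0 + np.exp(-k * (x - x0)))
    raise DataError(f"unknown transform kind {kind!r}")


def apply_batch_transforms(
    expr: ExpressionMatrix, kind: str, seed: int
) -> ExpressionMatrix:
    """Apply an independent strictly increasing distortion to every sample.

    REO-based stages must produce bit-identical output on the result.
    """
    rng = np.random.default_rng(seed)
    values = expr.values.copy()
    for s in range(expr.n_samples):
        values[:, s] = _monotone_transform(kind, rng)(values[:, s])
    return ExpressionMatrix(expr.gene_ids, expr.sample_ids, values)


def simulate_cohort(
    config: SimulationConfig,
    with_survival: bool = True,
    sample_seed: int | None = None,
) -> tuple[ExpressionMatrix, PhenotypeTable, list[tuple[str, str]]]:
    """Draw one cohort; returns (expression, phenotype, planted truth).

    Truth pairs are oriented so gene_a > gene_b is the responder-dominant
    direction, matching the normalization of the screen's output. Identical
    config and seed give bit-identical output.

    The gene *layout* (per-gene means, which pairs are planted) is drawn
    from ``config.seed`` alone; per-sample draws come from a second stream,
    overridable via ``sample_seed`` — two cohorts with the same config and
    different sample seeds share the same planted truth, giving proper
    train/test pairs from one world.
    """
    layout_rng, default_sample_rng = (
        np.random.default_rng(s) for s in np.random.SeedSequence(config.seed).spawn(2)
    )
    rng = default_sample_rng if sample_seed is None else np.random.default_rng(sample_seed)
    g, n = config.n_genes, config.n_resp + config.n_nonresp
    gene_ids = tuple(f"G{i:04d}" for i in range(1, g + 1))
    sample_ids = tuple(f"S{i:03d}" for i in range(1, n + 1))
    labels = np.concatenate([
        np.ones(config.n_resp, dtype=int), np.zeros(config.n_nonresp, dtype=int)
    ])

    means = layout_rng.uniform(4.0, 12.0, size=g)
    planted_genes = layout_rng.permutation(g)[: 2 * config.n_planted_pairs]
    truth_idx = [
        (planted_genes[2 * i], planted_genes[2 * i + 1])
        for i in range(config.n_planted_pairs)
    ]
    # partners share a mean: the planted signal is the ordering, not abundance
    for ia, ib in truth_idx:
        means[ib] = means[ia]

    values = means[:, None] + rng.normal(0.0, config.noise_sd, size=(g, n))

    for ia, ib in truth_idx:
        p_forward = np.where(
            labels == 1, config.stability_resp, 1.0 - config.stability_nonresp
        )
        want_forward = rng.random(n) < p_forward
        a, b = values[ia].copy(), values[ib].copy()
        swap = want_forward != (a > b)
        values[ia] = np.where(swap, b, a)
        values[ib] = np.where(swap, a, b)

    expr = ExpressionMatrix(gene_ids, sample_ids, values)
    if config.batch_transforms is not None:
        expr = apply_batch_transforms(
            expr, config.batch_transforms, seed=int(rng.integers(2**31))
        )

    columns: dict = {"response": labels}
    if with_survival:
        dfs_time, dfs_event = simulate_survival(
            labels, config.hr_true, config.censor_rate,
            seed=int(rng.integers(2**31)),
        )
        columns["dfs_time"] = dfs_time
        columns["dfs_event"] = dfs_event
        columns["stage"] = rng.choice(("II", "III"), size=n)
        columns["age"] = np.round(rng.uniform(35, 80, size=n), 1)
        columns["gender"] = rng.choice(("female", "male"), size=n)
    pheno = PhenotypeTable.from_records(sample_ids, **columns)
    truth = [(gene_ids[ia], gene_ids[ib]) for ia, ib in truth_idx]
    return expr, pheno, truth


def simulate_survival(
    labels,
    hr_true: float,
    censor_rate: float,
    seed: int,
    baseline_mean_months: float = 48.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Exponential DFS times whose hazard depends on true response status.

    Non-responders have hazard 1/baseline_mean_months; responders have that
    hazard times ``hr_true`` (HR < 1 = longer disease-free survival). Each
    subject is independently censored with probability ``censor_rate``, at a
    uniform fraction of its event time, so the realized censoring fraction
    matches the configured rate in expectation.
    """
    if hr_true <= 0:
        raise DataError("hr_true must be > 0")
    if not 0.0 <= censor_rate < 1.0:
        raise DataError("censor_rate must be in [0, 1)")
    y = np.asarray(labels, dtype=int)
    rng = np.random.default_rng(seed)
    lam = (1.0 / baseline_mean_months) * np.where(y == 1, hr_true, 1.0)
    event_time = rng.exponential(1.0 / lam)
    censored = rng.random(len(y)) < censor_rate
    time = np.where(censored, event_time * rng.random(len(y)), event_time)
    event = (~censored).astype(int)
    return np.round(time, 3), event


def train_test_pair(
    config: SimulationConfig,
) -> tuple[tuple[ExpressionMatrix, PhenotypeTable, list], tuple[ExpressionMatrix, PhenotypeTable, list]]:
    """Train and held-out test cohorts from the same world: identical gene
    layout and planted truth, independent samples."""
    train = simulate_cohort(config)
    test = simulate_cohort(config, sample_seed=(config.seed * 2_000_003 + 1) % 2**31)
    return train, test
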
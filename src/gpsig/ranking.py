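"""Random-forest importance ranking of reversal pairs.

Each reversal pair becomes one binary feature per sample: 1 when the sample
shows the pair's responder orientation, 0 otherwise. This indicator is the
only encoding that keeps exactly the rank information the screen used, so
the whole chain stays invariant to per-sample monotone transforms. A
random forest is fit on these features and pairs are ranked by mean
decrease Gini (MDG) — total Gini-impurity reduction attributed to the
feature, averaged over trees.

Forest randomness is seeded but is not portable across libraries or
versions, so the fitted metadata records the seed and scikit-learn version;
nothing downstream depends on bit-exact forest reproduction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import sklearn
from sklearn.ensemble import RandomForestClassifier

from .errors import DataError
from .io import ExpressionMatrix
from .reo import ReversalPairRecord


@dataclass(frozen=True)
class RFConfig:
    """Forest hyper-parameters.

    ntree: number of trees. mtry: features considered per split; when None
    the usual floor(sqrt(n_features)) default applies. The published model
    used ntree=2500, mtry=88 (R randomForest, seed 20200914); those values
    are honored when configured but cannot reproduce the same forest here.
    """

    ntree: int = 500
    mtry: int | None = None
    seed: int = 0

    def __post_init__(self):
        if self.ntree < 1:
            raise DataError("ntree must be >= 1")
        if self.mtry is not None and self.mtry < 1:
            raise DataError("mtry must be >= 1")

    def resolved_mtry(self, n_features: int) -> int:
        if self.mtry is None:
            return max(1, math.floor(math.sqrt(n_features)))
        if self.mtry > n_features:
            raise DataError(f"mtry={self.mtry} exceeds {n_features} features")
        return self.mtry


@dataclass(frozen=True)
class PairFeatureMatrix:
    """Binary REO indicators, pairs x samples."""

    pair_ids: tuple[tuple[str, str], ...]
    sample_ids: tuple[str, ...]
    values: np.ndarray  # uint8, pairs x samples

    def __post_init__(self):
        values = np.asarray(self.values)
        if values.shape != (len(self.pair_ids), len(self.sample_ids)):
            raise DataError("feature matrix shape mismatch")
        if not np.isin(values, (0, 1)).all():
            raise DataError("pair features must be binary")
        object.__setattr__(self, "values", values.astype(np.uint8))


@dataclass(frozen=True)
class RankedPairs:
    """Pairs sorted by MDG descending; ties broken by pair id."""

    pair_ids: tuple[tuple[str, str], ...]
    mdg: tuple[float, ...]
    metadata: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        if len(self.pair_ids) != len(self.mdg):
            raise DataError("ranking length mismatch")
        if any(not math.isfinite(v) or v < 0 for v in self.mdg):
            raise DataError("MDG values must be finite and >= 0")

    def __len__(self) -> int:
        return len(self.pair_ids)

    @property
    def ranks(self) -> tuple[int, ...]:
        return tuple(range(1, len(self) + 1))


def encode_pairs(
    expr: ExpressionMatrix,
    pairs: Sequence[ReversalPairRecord | tuple[str, str]],
) -> PairFeatureMatrix:
    """Binary feature matrix: entry(p, s) = 1 iff sample s shows pair p's
    responder orientation (gene_a > gene_b, ties counting as 0)."""
    gene_idx = expr.gene_index()
    ids: list[tuple[str, str]] = []
    for p in pairs:
        ids.append(p.pair if isinstance(p, ReversalPairRecord) else tuple(p))
    missing = sorted({g for a, b in ids for g in (a, b) if g not in gene_idx})
    if missing:
        raise DataError(f"pair genes absent from matrix: {missing}")
    rows_a = np.array([gene_idx[a] for a, _ in ids], dtype=int)
    rows_b = np.array([gene_idx[b] for _, b in ids], dtype=int)
    values = (expr.values[rows_a] > expr.values[rows_b]).astype(np.uint8)
    return PairFeatureMatrix(tuple(ids), expr.sample_ids, values)


def rank_by_mdg(
    features: PairFeatureMatrix,
    labels: Sequence[int],
    config: RFConfig | None = None,
) -> RankedPairs:
    """Fit a Gini random forest on pair indicators and rank by importance.

    Returns every pair with its MDG, sorted descending; exact ties fall back
    to lexicographic pair order so the ranking is deterministic given the
    seed. Metadata echoes ntree/mtry/seed and the library version.
    """
    config = config or RFConfig()
    y = np.asarray(labels, dtype=int)
    if y.shape != (len(features.sample_ids),):
        raise DataError("label vector length mismatch")
    if len(np.unique(y)) < 2:
        raise DataError("labels contain a single class; need both")
    mtry = config.resolved_mtry(len(features.pair_ids))
    forest = RandomForestClassifier(
        n_estimators=config.ntree,
        criterion="gini",
        max_features=mtry,
        random_state=config.seed,
        n_jobs=1,
    )
    forest.fit(features.values.T, y)
    mdg = forest.feature_importances_
    order = sorted(
        range(len(mdg)), key=lambda i: (-mdg[i], features.pair_ids[i])
    )
    return RankedPairs(
        pair_ids=tuple(features.pair_ids[i] for i in order),
        mdg=tuple(float(mdg[i]) for i in order),
        metadata={
            "ntree": config.ntree,
            "mtry": mtry,
            "seed": config.seed,
            "sklearn_version": sklearn.__version__,
        },
    )
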
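"""Best top-N signature selection by majority-vote training accuracy.

Only prefixes of the importance ranking are considered ("top-N"): for each
N from 1 to a cap, every training sample is classified by majority vote
over the top-N pairs and the resubstitution accuracy recorded. The
signature is the smallest N attaining the maximum accuracy (parsimony on
ties). The full (N, accuracy) curve is kept as metadata so the choice is
auditable.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DataError
from .io import ExpressionMatrix, Signature
from .ranking import RankedPairs, encode_pairs

DEFAULT_N_MAX = 500


def vote_accuracy_curve(
    ranked: RankedPairs,
    expr: ExpressionMatrix,
    labels: Sequence[int],
    n_max: int | None = None,
) -> pd.DataFrame:
    """Majority-vote accuracy for every prefix length N = 1..n_max.

    Vote rule matches the classifier: responder iff strictly more than N/2
    of the top-N pairs show response orientation.
    """
    if len(ranked) == 0:
        raise DataError("empty ranking")
    n_max = len(ranked) if n_max is None else min(n_max, len(ranked))
    if n_max < 1:
        raise DataError("n_max must be >= 1")
    y = np.asarray(labels, dtype=int)
    features = encode_pairs(expr, ranked.pair_ids[:n_max])
    cumvotes = np.cumsum(features.values, axis=0)          # N x samples
    n_col = np.arange(1, n_max + 1)[:, None]
    predicted = cumvotes * 2 > n_col
    accuracy = (predicted == (y == 1)).mean(axis=1)
    return pd.DataFrame({"n": n_col.ravel(), "accuracy": accuracy})


def select_best_top_n(
    ranked: RankedPairs,
    expr: ExpressionMatrix,
    labels: Sequence[int],
    n_max: int | None = DEFAULT_N_MAX,
) -> Signature:
    """Pick the smallest N whose top-N majority vote maximizes training
    accuracy; returns the signature with the accuracy curve in provenance."""
    curve = vote_accuracy_curve(ranked, expr, labels, n_max)
    best = int(curve.loc[curve["accuracy"].idxmax(), "n"])   # idxmax -> first/smallest N
    best_acc = float(curve["accuracy"].max())
    return Signature(
        pairs=tuple(ranked.pair_ids[:best]),
        provenance={
            "selection": "best top-N by majority-vote training accuracy",
            "n": best,
            "training_accuracy": best_acc,
            "n_max": int(curve["n"].iloc[-1]),
            "curve": curve,
            "ranking_metadata": dict(ranked.metadata),
        },
    )
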
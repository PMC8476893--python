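"""Within-sample relative expression orderings (REO) and the reversal screen.

The REO of a gene pair (a, b) in one sample is the comparison of the two
expression values: FORWARD when G_a > G_b, REVERSE otherwise (ties count as
REVERSE — "not strictly greater"). Because the comparison happens within a
sample, it is invariant to any strictly increasing transform of that
sample's values, which is what makes REO-based signatures robust to batch
effects and normalization choices.

A *reversal pair* is a pair whose dominant orientation differs between the
two phenotype classes, with the majority orientation statistically stable
in each class separately (exact one-sided binomial test against 0.5).
Records are normalized so the responder-dominant direction is stored as
gene_a > gene_b.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import DataError
from .io import ExpressionMatrix, PhenotypeTable

DEFAULT_ALPHA = 0.05
DEFAULT_MAX_GENES = 2000


class Orientation(enum.Enum):
    FORWARD = "forward"   # G_a > G_b
    REVERSE = "reverse"   # G_a <= G_b


def orientation(expr_a: float, expr_b: float) -> Orientation:
    """Orientation of one pair in one sample; ties resolve to REVERSE."""
    if not (math.isfinite(expr_a) and math.isfinite(expr_b)):
        raise DataError(f"non-finite expression value ({expr_a}, {expr_b})")
    return Orientation.FORWARD if expr_a > expr_b else Orientation.REVERSE


def binomial_majority_p(k: int, n: int, two_sided: bool = False) -> float:
    """Exact binomial tail for the majority orientation.

    One-sided P(X >= max(k, n-k)) with X ~ Binomial(n, 1/2): the chance of a
    majority at least as extreme as the observed one under no preferred
    orientation. Symmetric in k and n-k by construction. The two-sided
    variant doubles the tail (capped at 1), which for p = 1/2 coincides with
    the exact symmetric test.
    """
    if n < 1:
        raise DataError("binomial test needs n >= 1")
    if not 0 <= k <= n:
        raise DataError(f"invalid count k={k} for n={n}")
    m = max(k, n - k)
    p = float(stats.binom.sf(m - 1, n, 0.5))
    if two_sided:
        p = min(1.0, 2.0 * p)
    return p


@dataclass(frozen=True)
class ReversalPairRecord:
    """One screened reversal pair, normalized so that FORWARD (gene_a >
    gene_b) is the responder-dominant orientation."""

    gene_a: str
    gene_b: str
    k_resp: int        # responder samples showing gene_a > gene_b
    n_resp: int
    k_nonresp: int
    n_nonresp: int
    p_resp: float
    p_nonresp: float
    response_orientation: Orientation = Orientation.FORWARD

    def __post_init__(self):
        if not (0 <= self.k_resp <= self.n_resp and 0 <= self.k_nonresp <= self.n_nonresp):
            raise DataError("orientation counts out of range")
        if not (0.0 <= self.p_resp <= 1.0 and 0.0 <= self.p_nonresp <= 1.0):
            raise DataError("p-values out of [0, 1]")

    @property
    def pair(self) -> tuple[str, str]:
        return (self.gene_a, self.gene_b)


def _tail_table(n: int) -> np.ndarray:
    """tail[m] = P(X >= m) for X ~ Binomial(n, 1/2), m = 0..n."""
    return stats.binom.sf(np.arange(-1, n), n, 0.5)


def _forward_counts(x: np.ndarray, rows: np.ndarray, cols: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Counts of samples with x[rows] > x[cols] and x[cols] > x[rows]."""
    a = x[rows]
    b = x[cols]
    return (a > b).sum(axis=1), (b > a).sum(axis=1)


def find_reversal_pairs(
    expr: ExpressionMatrix,
    pheno: PhenotypeTable,
    alpha: float = DEFAULT_ALPHA,
    candidate_pairs: Sequence[tuple[str, str]] | None = None,
    two_sided: bool = False,
    max_genes: int = DEFAULT_MAX_GENES,
    allow_large: bool = False,
    chunk: int = 256,
) -> list[ReversalPairRecord]:
    """Screen gene pairs whose dominant orientation reverses between classes.

    A pair is emitted when the responder-dominant orientation differs from
    the non-responder-dominant orientation and the binomial majority test is
    below ``alpha`` in *both* classes. Each unordered pair appears at most
    once, stored with the responder-dominant direction as gene_a > gene_b,
    and output is sorted lexicographically by (gene_a, gene_b).

    Without ``candidate_pairs`` all g*(g-1)/2 unordered pairs are
    enumerated; that is refused above ``max_genes`` genes unless
    ``allow_large`` is set.
    """
    if not 0.0 < alpha < 1.0:
        raise DataError(f"alpha must be in (0, 1), got {alpha}")
    labels = pheno.response_labels(expr.sample_ids)
    resp_cols = np.flatnonzero(labels == 1)
    non_cols = np.flatnonzero(labels == 0)
    n_resp, n_non = len(resp_cols), len(non_cols)
    if n_resp < 2 or n_non < 2:
        raise DataError(
            f"need >= 2 samples per class, got {n_resp} responders / {n_non} non-responders"
        )

    gene_idx = expr.gene_index()
    if candidate_pairs is not None:
        missing = sorted(
            {g for p in candidate_pairs for g in p if g not in gene_idx}
        )
        if missing:
            raise DataError(f"candidate pair genes absent from matrix: {missing}")
        rows = np.array([gene_idx[a] for a, _ in candidate_pairs], dtype=int)
        cols = np.array([gene_idx[b] for _, b in candidate_pairs], dtype=int)
    else:
        g = expr.n_genes
        if g > max_genes and not allow_large:
            raise DataError(
                f"{g} genes would enumerate {g * (g - 1) // 2} pairs; pass "
                f"allow_large=True (or a candidate list / pre-filter) to proceed"
            )
        rows, cols = np.triu_indices(g, k=1)

    xr = expr.values[:, resp_cols]
    xn = expr.values[:, non_cols]
    tail_resp = _tail_table(n_resp)
    tail_non = _tail_table(n_non)
    side = 2.0 if two_sided else 1.0

    records: list[ReversalPairRecord] = []
    for start in range(0, len(rows), chunk * chunk):
        r = rows[start:start + chunk * chunk]
        c = cols[start:start + chunk * chunk]
        kf_r, kr_r = _forward_counts(xr, r, c)   # responders: a>b, b>a counts
        kf_n, kr_n = _forward_counts(xn, r, c)   # non-responders

        for stored_as_ab, kresp, knon in (
            (True, kf_r, kf_n),    # keep (a, b): responders dominantly a > b
            (False, kr_r, kr_n),   # flip to (b, a): responders dominantly b > a
        ):
            resp_fwd_dom = kresp * 2 > n_resp
            non_rev_dom = knon * 2 < n_non
            p_resp = np.minimum(1.0, side * tail_resp[np.maximum(kresp, n_resp - kresp)])
            p_non = np.minimum(1.0, side * tail_non[np.maximum(knon, n_non - knon)])
            hit = resp_fwd_dom & non_rev_dom & (p_resp < alpha) & (p_non < alpha)
            for i in np.flatnonzero(hit):
                ia, ib = (r[i], c[i]) if stored_as_ab else (c[i], r[i])
                records.append(ReversalPairRecord(
                    gene_a=expr.gene_ids[ia],
                    gene_b=expr.gene_ids[ib],
                    k_resp=int(kresp[i]),
                    n_resp=n_resp,
                    k_nonresp=int(knon[i]),
                    n_nonresp=n_non,
                    p_resp=float(p_resp[i]),
                    p_nonresp=float(p_non[i]),
                ))
    records.sort(key=lambda rec: (rec.gene_a, rec.gene_b))
    return records


def top_variance_genes(expr: ExpressionMatrix, n_top: int) -> list[str]:
    """Optional pre-filter hook: the ``n_top`` genes by variance across samples."""
    variances = expr.values.var(axis=1)
    order = np.argsort(-variances, kind="stable")[:n_top]
    return [expr.gene_ids[i] for i in order]
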
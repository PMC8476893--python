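"""Delimited-text I/O and probe-to-gene collapsing.

Three on-disk formats, all plain delimited text (tab for ``.tsv``/unknown
extensions, comma for ``.csv``; override with ``delimiter=``):

* expression matrix — genes (or probes) in rows, first column the identifier,
  header row of sample ids, values on the log2 scale;
* phenotype table — one row per sample, columns ``sample_id``, ``response``
  and optional survival/covariate columns;
* signature — ordered gene pairs, columns ``rank``, ``gene_a``, ``gene_b``;
  the orientation gene_a > gene_b encodes the responder class.

Writers can prepend ``#key=value`` metadata lines; readers skip ``#`` lines.
Identifiers are matched case-sensitively after whitespace stripping; missing
or non-numeric expression values are rejected at load, never imputed.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DataError

_41GPS_RESOURCE = "signature_41gps.tsv"
_41GPS_SHA256 = "02e097a70b2d065f9233ef5d7d368e02e0d84f8b9954bd4a4fb157391dee354a"

PHENOTYPE_COLUMNS = (
    "sample_id", "response", "dfs_time", "dfs_event",
    "stage", "age", "gender", "resistance",
)

_RESPONSE_CODES = {
    "responder": 1, "response": 1, "r": 1, "1": 1, "true": 1, "yes": 1,
    "non-responder": 0, "nonresponder": 0, "non-response": 0, "nr": 0,
    "0": 0, "false": 0, "no": 0,
}


def _delimiter_for(path: str | Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "," if str(path).endswith(".csv") else "\t"


def _write_metadata(handle, metadata: Mapping[str, object] | None) -> None:
    for key, value in (metadata or {}).items():
        handle.write(f"#{key}={value}\n")


def read_metadata(path: str | Path) -> dict[str, str]:
    """Parse ``#key=value`` header lines from any of the package's files."""
    meta: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, value = line[1:].rstrip("\n").partition("=")
            meta[key] = value
    return meta


@dataclass(frozen=True)
class ExpressionMatrix:
    """Log2 expression values, genes x samples.

    Invariants (enforced at construction): unique gene ids, unique sample
    ids, all values finite, shape consistent with the id lists.
    """

    gene_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise DataError(
                f"value matrix shape {values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        for kind, ids in (("gene", self.gene_ids), ("sample", self.sample_ids)):
            seen: set[str] = set()
            for identifier in ids:
                if identifier in seen:
                    raise DataError(f"duplicate {kind} id: {identifier!r}")
                seen.add(identifier)
        if not np.isfinite(values).all():
            g, s = np.argwhere(~np.isfinite(values))[0]
            raise DataError(
                f"non-finite expression value at gene {self.gene_ids[g]!r}, "
                f"sample {self.sample_ids[s]!r}"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_ids)}

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        return cls(
            gene_ids=tuple(str(g).strip() for g in df.index),
            sample_ids=tuple(str(s).strip() for s in df.columns),
            values=df.to_numpy(dtype=float),
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.gene_ids), columns=list(self.sample_ids)
        )

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        index = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in index]
        if missing:
            raise DataError(f"samples absent from matrix: {missing}")
        cols = [index[s] for s in sample_ids]
        return ExpressionMatrix(self.gene_ids, tuple(sample_ids), self.values[:, cols])


@dataclass(frozen=True)
class PhenotypeTable:
    """Per-sample labels and covariates.

    ``response`` is coded 1 = responder (the positive class throughout the
    package), 0 = non-responder; it may be absent (all-NA) for cohorts that
    only carry survival information. ``dfs_event`` must be present wherever
    ``dfs_time`` is.
    """

    df: pd.DataFrame = field(repr=False)

    def __post_init__(self):
        df = self.df
        if df.index.name != "sample_id":
            raise DataError("phenotype table must be indexed by sample_id")
        if df.index.duplicated().any():
            dup = df.index[df.index.duplicated()][0]
            raise DataError(f"duplicate sample id: {dup!r}")
        for col in PHENOTYPE_COLUMNS[1:]:
            if col not in df.columns:
                df[col] = np.nan
        has_time = df["dfs_time"].notna()
        if (has_time & df["dfs_event"].isna()).any():
            raise DataError("dfs_event missing for samples with dfs_time")
        if (df.loc[has_time, "dfs_time"] < 0).any():
            raise DataError("negative dfs_time")

    @property
    def sample_ids(self) -> tuple[str, ...]:
        return tuple(self.df.index)

    def response_labels(self, sample_ids: Sequence[str]) -> np.ndarray:
        """Binary response vector (1 = responder) for the given samples.

        Raises if any sample is missing from the table or unlabeled.
        """
        missing = [s for s in sample_ids if s not in self.df.index]
        if missing:
            raise DataError(f"samples absent from phenotype table: {missing}")
        labels = self.df.loc[list(sample_ids), "response"]
        if labels.isna().any():
            bad = labels.index[labels.isna()][0]
            raise DataError(f"sample {bad!r} has no response label")
        return labels.to_numpy(dtype=int)

    @classmethod
    def from_records(cls, sample_ids: Sequence[str], **columns) -> "PhenotypeTable":
        df = pd.DataFrame(columns, index=pd.Index([str(s) for s in sample_ids], name="sample_id"))
        return cls(df)


@dataclass(frozen=True)
class Signature:
    """An ordered list of gene pairs; gene_a > gene_b votes 'responder'."""

    pairs: tuple[tuple[str, str], ...]
    provenance: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        seen: set[tuple[str, str]] = set()
        for a, b in self.pairs:
            if a == b:
                raise DataError(f"degenerate pair ({a!r}, {b!r})")
            if (a, b) in seen:
                raise DataError(f"duplicate pair ({a!r}, {b!r})")
            seen.add((a, b))

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def genes(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for a, b in self.pairs:
            seen.setdefault(a)
            seen.setdefault(b)
        return tuple(seen)


# ---------------------------------------------------------------------------
# expression matrix


def read_expression(
    path: str | Path,
    delimiter: str | None = None,
    collapse_duplicates: bool = False,
) -> ExpressionMatrix:
    """Load a genes x samples matrix from delimited text.

    First column holds gene (or probe) ids, the header row sample ids.
    Duplicate gene rows are averaged only when ``collapse_duplicates`` is
    set; otherwise they are a load error, as are duplicate sample ids,
    missing cells and non-numeric cells (reported with coordinates).
    """
    sep = _delimiter_for(path, delimiter)
    with open(path) as fh:
        header = None
        for line in fh:
            if not line.startswith("#"):
                header = line.rstrip("\n").split(sep)
                break
    if not header or len(header) < 2:
        raise DataError(f"{path}: no sample columns found")
    samples = [s.strip() for s in header[1:]]
    seen: set[str] = set()
    for s in samples:
        if s in seen:
            raise DataError(f"{path}: duplicate sample id in header: {s!r}")
        seen.add(s)

    raw = pd.read_csv(path, sep=sep, comment="#", index_col=0, dtype=str,
                      skip_blank_lines=True)
    raw.columns = samples
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna()
    if bad.to_numpy().any():
        g, s = np.argwhere(bad.to_numpy())[0]
        cell = raw.iat[g, s]
        what = "missing" if pd.isna(cell) else f"non-numeric ({cell!r})"
        raise DataError(
            f"{path}: {what} value at row {raw.index[g]!r}, column {samples[s]!r}"
        )
    numeric.index = [str(g).strip() for g in numeric.index]
    if numeric.index.duplicated().any():
        if not collapse_duplicates:
            dup = numeric.index[numeric.index.duplicated()][0]
            raise DataError(
                f"{path}: duplicate gene id {dup!r} (pass collapse_duplicates "
                f"or a probe map to average)"
            )
        numeric = numeric.groupby(level=0, sort=False).mean()
    return ExpressionMatrix.from_dataframe(numeric)


def write_expression(
    matrix: ExpressionMatrix,
    path: str | Path,
    delimiter: str | None = None,
    metadata: Mapping[str, object] | None = None,
) -> None:
    sep = _delimiter_for(path, delimiter)
    with open(path, "w") as fh:
        _write_metadata(fh, metadata)
        df = matrix.to_dataframe()
        df.index.name = "gene_id"
        # default float formatting is shortest-round-trip, so read-back is bit-exact
        df.to_csv(fh, sep=sep)


def collapse_probes(
    probe_matrix: ExpressionMatrix,
    probe_to_gene: Mapping[str, str],
) -> ExpressionMatrix:
    """Collapse probe-level rows to gene level by the arithmetic mean of the
    (log2-scale) probe values.

    Probes without a mapping are dropped; map entries that reference absent
    probes raise a warning and are ignored; an empty map is an error.
    """
    if not probe_to_gene:
        raise DataError("probe_to_gene map is empty")
    present = set(probe_matrix.gene_ids)
    absent = [p for p in probe_to_gene if p not in present]
    if absent:
        warnings.warn(
            f"{len(absent)} mapped probes absent from matrix (e.g. {absent[0]!r}); ignored",
            stacklevel=2,
        )
    df = probe_matrix.to_dataframe()
    mapped = df.loc[[p for p in probe_matrix.gene_ids if p in probe_to_gene]]
    if mapped.empty:
        raise DataError("no probes in the matrix are covered by the map")
    genes = [str(probe_to_gene[p]).strip() for p in mapped.index]
    collapsed = mapped.groupby(pd.Index(genes, name="gene"), sort=True).mean()
    return ExpressionMatrix.from_dataframe(collapsed)


# ---------------------------------------------------------------------------
# phenotype table


def _parse_response(value) -> float:
    if pd.isna(value):
        return np.nan
    key = str(value).strip().lower()
    if key in _RESPONSE_CODES:
        return float(_RESPONSE_CODES[key])
    raise DataError(f"unrecognized response label {value!r}")


def read_phenotype(path: str | Path, delimiter: str | None = None) -> PhenotypeTable:
    sep = _delimiter_for(path, delimiter)
    df = pd.read_csv(path, sep=sep, comment="#", dtype={0: str})
    if "sample_id" not in df.columns:
        raise DataError(f"{path}: phenotype table needs a sample_id column")
    df["sample_id"] = df["sample_id"].str.strip()
    df = df.set_index("sample_id")
    if "response" in df.columns:
        df["response"] = df["response"].map(_parse_response)
    for col in ("dfs_time", "dfs_event", "age", "resistance"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col])
    return PhenotypeTable(df)


def write_phenotype(
    pheno: PhenotypeTable,
    path: str | Path,
    delimiter: str | None = None,
    metadata: Mapping[str, object] | None = None,
) -> None:
    sep = _delimiter_for(path, delimiter)
    with open(path, "w") as fh:
        _write_metadata(fh, metadata)
        pheno.df.to_csv(fh, sep=sep)


# ---------------------------------------------------------------------------
# signature


def read_signature(path: str | Path, delimiter: str | None = None) -> Signature:
    """Read an ordered gene-pair signature.

    The ``rank`` column is optional on input (row order is used) but must be
    consecutive from 1 when present.
    """
    sep = _delimiter_for(path, delimiter)
    df = pd.read_csv(path, sep=sep, comment="#", dtype=str)
    for col in ("gene_a", "gene_b"):
        if col not in df.columns:
            raise DataError(f"{path}: signature needs a {col} column")
    if "rank" in df.columns:
        ranks = pd.to_numeric(df["rank"]).to_numpy()
        if not np.array_equal(ranks, np.arange(1, len(df) + 1)):
            raise DataError(f"{path}: ranks must be consecutive from 1")
    pairs = tuple(
        (a.strip(), b.strip()) for a, b in zip(df["gene_a"], df["gene_b"])
    )
    return Signature(pairs=pairs, provenance={"source": str(path)})


def write_signature(
    signature: Signature,
    path: str | Path,
    delimiter: str | None = None,
    metadata: Mapping[str, object] | None = None,
) -> None:
    sep = _delimiter_for(path, delimiter)
    with open(path, "w") as fh:
        _write_metadata(fh, metadata)
        fh.write(sep.join(("rank", "gene_a", "gene_b")) + "\n")
        for i, (a, b) in enumerate(signature.pairs, start=1):
            fh.write(sep.join((str(i), a, b)) + "\n")


def load_published_signature() -> Signature:
    """The published 41-gene-pair nCRT-response signature (41-GPS).

    Verified against a frozen checksum so a corrupted install fails loudly.
    """
    ref = resources.files("gpsig").joinpath("data", _41GPS_RESOURCE)
    payload = ref.read_bytes()
    digest = hashlib.sha256(payload).hexdigest()
    if digest != _41GPS_SHA256:
        raise DataError(
            f"built-in 41-GPS fixture is corrupted (sha256 {digest[:12]}..., "
            f"expected {_41GPS_SHA256[:12]}...)"
        )
    rows = [line.split("\t") for line in payload.decode().splitlines()[1:] if line]
    pairs = tuple((a.strip(), b.strip()) for _, a, b in rows)
    return Signature(pairs=pairs, provenance={"source": "builtin:41gps"})


def file_sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
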
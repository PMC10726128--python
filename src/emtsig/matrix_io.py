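"""Expression-matrix data model, file I/O and normalization transforms.

The pipeline's in-memory containers are thin wrappers around pandas
objects: an :class:`ExpressionMatrix` is a genes-by-samples DataFrame
carrying an explicit scale tag (``counts``, ``cpm``, ``log2cpm`` or
``zscore``), sample annotations are a DataFrame with fixed column names,
and gene sets live in a :class:`GeneSetCollection` backed by an ordered
dict.  All interchange formats are plain text: TSV for matrices and
annotations, GMT for gene sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SCALES = ("counts", "cpm", "log2cpm", "zscore")

ANNOTATION_COLUMNS = (
    "sample_id",
    "condition",
    "cohort",
    "subtype",
    "time_days",
    "event",
    "cnv",
)


class ParseError(ValueError):
    """Raised when an input file violates the expected layout."""


@dataclass
class ExpressionMatrix:
    """Gene-by-sample numeric matrix with an explicit scale tag.

    Parameters
    ----------
    data
        DataFrame indexed by gene id with sample ids as columns.
    scale
        One of ``counts``, ``cpm``, ``log2cpm``, ``zscore``.  Values must
        be finite everywhere and non-negative on the count/CPM scales.
    """

    data: pd.DataFrame
    scale: str

    def __post_init__(self) -> None:
        if self.scale not in SCALES:
            raise ValueError(f"unknown scale {self.scale!r}; expected one of {SCALES}")
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()][0]
            raise ValueError(f"duplicate gene id {dup!r}")
        if self.data.columns.has_duplicates:
            dup = self.data.columns[self.data.columns.duplicated()][0]
            raise ValueError(f"duplicate sample id {dup!r}")
        values = self.data.to_numpy()
        if values.size and not np.isfinite(values).all():
            raise ValueError("expression values must be finite")
        if self.scale in ("counts", "cpm") and values.size and (values < 0).any():
            raise ValueError(f"negative values are not valid on the {self.scale} scale")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape


@dataclass
class GeneSetCollection:
    """Ordered mapping from set name to a duplicate-free gene list."""

    sets: dict[str, list[str]] = field(default_factory=dict)
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")
            if len(set(genes)) != len(genes):
                raise ValueError(f"gene set {name!r} contains duplicate genes")

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GeneSetCollection):
            return NotImplemented
        return self.sets == other.sets

    def items(self):
        return self.sets.items()


def read_matrix(path, scale: str) -> ExpressionMatrix:
    """Read a TSV expression matrix (first column ``gene_id``, header row of samples)."""
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise ParseError(f"cannot parse {path}: {exc}") from exc
    if df.columns.size == 0:
        raise ParseError(f"{path}: no sample columns in header")
    non_numeric = df.columns[[not np.issubdtype(d, np.number) for d in df.dtypes]]
    if len(non_numeric):
        raise ParseError(f"{path}: non-numeric values in column {non_numeric[0]!r}")
    df.index = df.index.astype(str)
    try:
        return ExpressionMatrix(df.astype(float), scale)
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_matrix(m: ExpressionMatrix, path) -> None:
    m.data.to_csv(path, sep="\t", index_label="gene_id", float_format="%.10g")


def read_annotation(path) -> pd.DataFrame:
    """Read a sample annotation TSV with the fixed column schema.

    Required column: ``sample_id`` (unique).  Optional columns:
    condition, cohort, subtype, time_days, event, cnv.  ``time_days``
    and ``event`` must be present together.
    """
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if "sample_id" not in df.columns:
        raise ParseError(f"{path}: missing required column 'sample_id'")
    unknown = set(df.columns) - set(ANNOTATION_COLUMNS)
    if unknown:
        raise ParseError(f"{path}: unknown columns {sorted(unknown)}")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ParseError(f"{path}: duplicate sample_id {dup!r}")
    has_time = "time_days" in df.columns
    has_event = "event" in df.columns
    if has_time != has_event:
        raise ParseError(f"{path}: time_days and event must be present together")
    if has_time:
        present = df["time_days"].notna()
        if (present != df["event"].notna()).any():
            raise ParseError(f"{path}: survival_event present iff survival_time present")
        if (df.loc[present, "time_days"] < 0).any():
            raise ParseError(f"{path}: negative survival time")
        events = df.loc[present, "event"]
        if not events.isin([0, 1]).all():
            raise ParseError(f"{path}: event must be 0 or 1")
    return df.set_index("sample_id", drop=False)


def write_annotation(ann: pd.DataFrame, path) -> None:
    ann.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file: per line, set name, description, then >=1 gene, tab-separated."""
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: GMT line has {len(fields)} fields, need >=3")
            name, desc, *genes = fields
            genes = [g for g in genes if g]
            if not genes:
                raise ParseError(f"{path}:{lineno}: gene set {name!r} has no genes")
            if name in sets:
                raise ParseError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = genes
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, genes in collection.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *genes]) + "\n")


def to_cpm(m: ExpressionMatrix) -> ExpressionMatrix:
    """Counts-per-million normalization: each column rescaled to sum to 1e6."""
    if m.scale != "counts":
        raise ValueError(f"to_cpm expects a counts matrix, got scale {m.scale!r}")
    libsize = m.data.sum(axis=0)
    zero = libsize[libsize == 0]
    if len(zero):
        raise ValueError(f"sample {zero.index[0]!r} has zero total count")
    return ExpressionMatrix(m.data / libsize * 1e6, "cpm")


def log2_plus1(m: ExpressionMatrix) -> ExpressionMatrix:
    """log2(x + 1) transform of a CPM matrix; maps 0 to 0 and is monotone."""
    if m.scale != "cpm":
        raise ValueError(f"log2_plus1 expects a cpm matrix, got scale {m.scale!r}")
    return ExpressionMatrix(np.log2(m.data + 1.0), "log2cpm")


def row_zscore(m: ExpressionMatrix) -> tuple[ExpressionMatrix, list[str]]:
    """Z-score each gene across samples using the sample (n-1) standard deviation.

    Zero-variance rows are mapped to all-zero and returned in the second
    element so downstream clustering stays total; callers should drop or
    flag them before correlation-based distances.
    """
    if m.shape[1] < 2:
        raise ValueError("row_zscore needs at least 2 samples")
    values = m.data.to_numpy(dtype=float)
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=1, keepdims=True)
    constant = sd[:, 0] == 0
    sd[constant] = 1.0
    z = (values - mean) / sd
    z[constant] = 0.0
    constant_genes = [g for g, c in zip(m.gene_ids, constant) if c]
    if constant_genes:
        logger.info("row_zscore: %d constant gene(s) set to zero", len(constant_genes))
    zm = ExpressionMatrix(pd.DataFrame(z, index=m.data.index, columns=m.data.columns), "zscore")
    return zm, constant_genes


def restrict_to_genes(m: ExpressionMatrix, genes: list[str]) -> tuple[ExpressionMatrix, list[str]]:
    """Subset a matrix to ``genes``, dropping (and reporting) absent ones.

    Mirrors the practice of applying a fixed signature to cohorts profiled
    on different platforms, where a handful of signature genes are missing
    from the cohort's gene list.
    """
    present = [g for g in genes if g in m.data.index]
    dropped = [g for g in genes if g not in m.data.index]
    if dropped:
        logger.info("restrict_to_genes: %d of %d genes absent from matrix", len(dropped), len(genes))
    return ExpressionMatrix(m.data.loc[present], m.scale), dropped
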
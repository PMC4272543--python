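"""Reading count/annotation/metadata tables, RPKM normalization and
browning-class assignment.

The on-disk formats are plain TSV: a genes × samples count matrix with a
header row of sample ids, a gene annotation table (``gene_id``,
``cds_length_bp``, optional ``bin_label``) and a sample metadata table
(``sample_id``, ``tissue``, ``timepoint``, ``browning_index``,
``total_mapped_reads`` and an optional pre-assigned ``class`` column).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("pomebrown")

TISSUES = ("inner", "outer")
TIMEPOINTS = ("harvest", "stored")
CLASSES = ("healthy", "affected", "unassigned")

__all__ = [
    "CountMatrix",
    "GeneAnnotation",
    "SampleTable",
    "ExpressionMatrix",
    "read_counts",
    "write_counts",
    "read_gene_annotation",
    "read_samples",
    "compute_rpkm",
    "classify_samples",
    "expressed_gene_counts",
    "genes_expressed_in_all",
]


def _check_unique(index: pd.Index, what: str) -> None:
    if index.has_duplicates:
        dupes = index[index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate {what} id(s): {', '.join(map(str, dupes))}")


@dataclass
class CountMatrix:
    """Raw read counts, genes × samples (non-negative integers)."""

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.counts.index, "gene")
        _check_unique(self.counts.columns, "sample")
        if self.counts.size == 0:
            raise ValueError("count matrix has no data rows")
        arr = self.counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            bad = np.argwhere(arr != np.floor(arr))
            if bad.size:
                g, s = bad[0]
                raise ValueError(
                    f"non-integer count at gene {self.counts.index[g]!r}, "
                    f"sample {self.counts.columns[s]!r}"
                )
            self.counts = self.counts.astype(np.int64)
            arr = self.counts.to_numpy()
        if (arr < 0).any():
            g, s = np.argwhere(arr < 0)[0]
            raise ValueError(
                f"negative count at gene {self.counts.index[g]!r}, "
                f"sample {self.counts.columns[s]!r}"
            )

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape


@dataclass
class GeneAnnotation:
    """Per-gene CDS length (bp) and optional functional bin label(s).

    Multiple bins for one gene are ';'-separated in ``bin_label``.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.table.index, "gene")
        if "cds_length_bp" not in self.table.columns:
            raise ValueError("annotation requires a cds_length_bp column")
        lengths = self.table["cds_length_bp"]
        if (lengths < 1).any() or lengths.isna().any():
            bad = self.table.index[(lengths < 1) | lengths.isna()].tolist()
            raise ValueError(f"non-positive/missing CDS length for: {bad[:5]}")
        if "bin_label" not in self.table.columns:
            self.table = self.table.assign(bin_label="")
        self.table["bin_label"] = self.table["bin_label"].fillna("")

    @property
    def gene_ids(self) -> pd.Index:
        return self.table.index

    @property
    def cds_length_bp(self) -> pd.Series:
        return self.table["cds_length_bp"]

    @property
    def bin_label(self) -> pd.Series:
        return self.table["bin_label"]


@dataclass
class SampleTable:
    """Sample metadata: tissue, timepoint, browning index and library size."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.table.index, "sample")
        required = {"tissue", "timepoint"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"sample table missing column(s): {sorted(missing)}")
        bad_tissue = set(self.table["tissue"]) - set(TISSUES)
        if bad_tissue:
            raise ValueError(f"unknown tissue value(s): {sorted(bad_tissue)}")
        bad_tp = set(self.table["timepoint"]) - set(TIMEPOINTS)
        if bad_tp:
            raise ValueError(f"unknown timepoint value(s): {sorted(bad_tp)}")
        if "browning_index" in self.table.columns:
            bi = self.table["browning_index"].dropna()
            if ((bi < 1) | (bi > 10)).any():
                raise ValueError("browning_index must lie in [1, 10]")
        if "class" not in self.table.columns:
            self.table = self.table.assign(**{"class": "unassigned"})
        bad_cls = set(self.table["class"].dropna()) - set(CLASSES)
        if bad_cls:
            raise ValueError(f"unknown class value(s): {sorted(bad_cls)}")

    @property
    def sample_ids(self) -> pd.Index:
        return self.table.index

    def subset(self, sample_ids) -> "SampleTable":
        return SampleTable(self.table.loc[list(sample_ids)].copy())


@dataclass
class ExpressionMatrix:
    """RPKM expression values, genes × samples (non-negative reals)."""

    rpkm: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.rpkm.index, "gene")
        _check_unique(self.rpkm.columns, "sample")
        if (self.rpkm.to_numpy() < 0).any():
            raise ValueError("RPKM values must be non-negative")

    @property
    def gene_ids(self) -> pd.Index:
        return self.rpkm.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.rpkm.columns


# ---------------------------------------------------------------------------
# readers / writers


def read_counts(path) -> CountMatrix:
    """Read a genes × samples TSV count matrix (first column: gene ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[0] == 0:
        raise ValueError(f"{path}: no data rows")
    return CountMatrix(df)


def write_counts(cm: CountMatrix, path) -> None:
    cm.counts.to_csv(path, sep="\t", index_label="gene_id")


def read_gene_annotation(path) -> GeneAnnotation:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[0] == 0:
        raise ValueError(f"{path}: no data rows")
    return GeneAnnotation(df)


def read_samples(path) -> SampleTable:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[0] == 0:
        raise ValueError(f"{path}: no data rows")
    return SampleTable(df)


# ---------------------------------------------------------------------------
# operations


def compute_rpkm(
    counts: CountMatrix,
    genes: GeneAnnotation,
    samples: SampleTable | None = None,
) -> ExpressionMatrix:
    """Reads per kilobase of CDS per million mapped reads.

    rpkm[g, s] = counts[g, s] * 1e9 / (total_mapped_reads[s] * cds_length_bp[g])

    The per-sample denominator comes from the metadata column
    ``total_mapped_reads``; when ``samples`` is None or the column is
    absent, per-sample column sums of the count matrix are used instead
    (logged as a fallback).
    """
    missing = counts.gene_ids.difference(genes.gene_ids)
    if len(missing):
        raise ValueError(
            f"missing CDS length for {len(missing)} gene(s), e.g. "
            f"{missing[:5].tolist()}"
        )
    lengths = genes.cds_length_bp.reindex(counts.gene_ids).to_numpy(float)

    lib = None
    if samples is not None and "total_mapped_reads" in samples.table.columns:
        lib = samples.table["total_mapped_reads"].reindex(counts.sample_ids)
        if lib.isna().any():
            raise ValueError(
                "total_mapped_reads missing for sample(s): "
                f"{lib.index[lib.isna()].tolist()}"
            )
        lib = lib.to_numpy(float)
    if lib is None:
        logger.info("total_mapped_reads not provided; using column sums")
        lib = counts.counts.sum(axis=0).to_numpy(float)
    if (lib <= 0).any():
        raise ValueError("zero or negative library size encountered")

    rpkm = counts.counts.to_numpy(float) * 1e9 / (lib[None, :] * lengths[:, None])
    return ExpressionMatrix(
        pd.DataFrame(rpkm, index=counts.gene_ids, columns=counts.sample_ids)
    )


def classify_samples(samples: SampleTable, bi_cutoff: float = 3.0) -> SampleTable:
    """Assign healthy/affected classes from the browning index (BI, 1-10).

    Harvest samples are healthy by definition.  Stored samples with
    BI strictly greater than ``bi_cutoff`` are affected, otherwise healthy.
    A pre-assigned non-'unassigned' ``class`` value in the metadata takes
    precedence over the BI rule.  Idempotent.
    """
    df = samples.table.copy()
    preset = df["class"].isin(("healthy", "affected"))
    stored = df["timepoint"] == "stored"
    if "browning_index" not in df.columns or df.loc[
        stored & ~preset, "browning_index"
    ].isna().any():
        bad = df.index[stored & ~preset]
        if "browning_index" in df.columns:
            bad = df.index[stored & ~preset & df["browning_index"].isna()]
        raise ValueError(f"missing browning_index for stored sample(s): {bad.tolist()}")
    cls = pd.Series("healthy", index=df.index)
    cls[stored & (df.get("browning_index", pd.Series(index=df.index)) > bi_cutoff)] = (
        "affected"
    )
    cls[preset] = df.loc[preset, "class"]
    df["class"] = cls
    return SampleTable(df)


def expressed_gene_counts(expr: ExpressionMatrix, min_rpkm: float = 0.0) -> pd.Series:
    """Number of genes with RPKM strictly above ``min_rpkm``, per sample."""
    return (expr.rpkm > min_rpkm).sum(axis=0)


def genes_expressed_in_all(
    expr: ExpressionMatrix, sample_ids=None, min_rpkm: float = 0.0
) -> pd.Index:
    """Genes with RPKM > ``min_rpkm`` in every sample of the given group."""
    sub = expr.rpkm if sample_ids is None else expr.rpkm[list(sample_ids)]
    mask = (sub > min_rpkm).all(axis=1)
    return expr.gene_ids[mask]
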
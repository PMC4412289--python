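"""Reading, validation, filtering and aggregation of count inputs.

Two kinds of input are handled: gene x sample read-count matrices for the
parental inbred strains, and per-SNP allele-count tables for the F1
crosses.  Both travel as TSV with ``#``-prefixed provenance comments.  The
filtering rules enforced here are the standard allele-specific expression
hygiene rules: drop SNP observations with per-sample coverage below four,
drop entire SNPs carrying any quality flag (third allele, repeat region,
proximity to an indel, exon-intron junction, non-monoallelic signal in the
parents), then pool replicates and SNPs into per-gene allelic totals.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from . import __version__

__all__ = [
    "SchemaError",
    "FLAG_VOCABULARY",
    "CONDITIONS",
    "GeneCountMatrix",
    "read_counts",
    "write_counts",
    "read_snp_table",
    "write_snp_table",
    "filter_snps",
    "aggregate_gene_allele_counts",
    "informative_genes",
]

#: recognised SNP quality flags
FLAG_VOCABULARY = frozenset(
    {
        "third_allele",
        "repeat_region",
        "near_indel",
        "exon_intron_junction",
        "non_monoallelic_parent",
    }
)

#: the two treatment conditions, in canonical order
CONDITIONS = ("control", "TM")

#: minimum maternal+paternal coverage for a single SNP observation
MIN_SNP_COVERAGE = 4

#: pooled-coverage thresholds (strict ">") per analysis purpose
COVERAGE_THRESHOLDS = {"cistrans": 20, "ase": 50}

SNP_COLUMNS = [
    "gene",
    "snp_id",
    "position",
    "sample",
    "maternal_count",
    "paternal_count",
    "flags",
]


class SchemaError(ValueError):
    """Input file violates the expected schema."""


def _comment_header(extra: Mapping[str, object] | None = None) -> str:
    lines = [f"# cistrans v{__version__}"]
    for key, value in (extra or {}).items():
        lines.append(f"# {key}: {value}")
    return "\n".join(lines) + "\n"


@dataclass
class GeneCountMatrix:
    """Gene x sample integer counts with sample metadata.

    Attributes
    ----------
    counts : DataFrame indexed by gene, one column per sample.
    samples : DataFrame indexed by sample id with columns
        ``strain``, ``condition`` and ``replicate``.
    norm_factors : per-sample TMM-style scaling factors (default 1).
    """

    counts: pd.DataFrame
    samples: pd.DataFrame
    norm_factors: pd.Series | None = field(default=None)

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            dup = self.counts.index[self.counts.index.duplicated()][0]
            raise SchemaError(f"duplicate gene id: {dup!r}")
        missing = [s for s in self.counts.columns if s not in self.samples.index]
        if missing:
            raise SchemaError(f"samples without metadata: {missing}")
        for col in ("strain", "condition", "replicate"):
            if col not in self.samples.columns:
                raise SchemaError(f"sample metadata lacks column {col!r}")
        bad_cond = set(self.samples["condition"]) - set(CONDITIONS)
        if bad_cond:
            raise SchemaError(f"unknown conditions: {sorted(bad_cond)}")
        values = self.counts.to_numpy()
        if (values < 0).any():
            raise SchemaError("negative counts are not allowed")
        if not np.issubdtype(values.dtype, np.integer):
            if not np.allclose(values, np.floor(values)):
                warnings.warn(
                    "non-integer counts floored (expected for allele-averaged "
                    "alignments)",
                    stacklevel=2,
                )
            self.counts = self.counts.apply(np.floor).astype(np.int64)
        # keep metadata restricted and ordered to match the matrix
        self.samples = self.samples.loc[list(self.counts.columns)]
        if self.norm_factors is None:
            self.norm_factors = pd.Series(1.0, index=self.counts.columns)
        else:
            self.norm_factors = self.norm_factors.loc[list(self.counts.columns)]
            if (self.norm_factors <= 0).any():
                raise SchemaError("normalization factors must be positive")

    @property
    def lib_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0).astype(float)

    @property
    def effective_lib_sizes(self) -> pd.Series:
        return self.lib_sizes * self.norm_factors

    def subset_samples(self, sample_ids: Iterable[str]) -> "GeneCountMatrix":
        ids = list(sample_ids)
        return GeneCountMatrix(
            counts=self.counts[ids].copy(),
            samples=self.samples.loc[ids].copy(),
            norm_factors=self.norm_factors.loc[ids].copy(),
        )

    def strain_samples(self, strain: str, condition: str | None = None) -> list[str]:
        meta = self.samples
        mask = meta["strain"] == strain
        if condition is not None:
            mask &= meta["condition"] == condition
        return list(meta.index[mask])


def write_counts(
    matrix: GeneCountMatrix,
    path,
    metadata_path,
    params: Mapping[str, object] | None = None,
) -> None:
    """Write the count matrix and its sample metadata as commented TSVs."""
    with open(path, "w") as fh:
        fh.write(_comment_header(params))
        matrix.counts.to_csv(fh, sep="\t", index_label="gene")
    with open(metadata_path, "w") as fh:
        fh.write(_comment_header())
        matrix.samples.to_csv(fh, sep="\t", index_label="sample")


def read_counts(path, metadata_path) -> GeneCountMatrix:
    """Read a gene x sample count matrix plus metadata, validating both."""
    counts = pd.read_csv(path, sep="\t", comment="#", index_col="gene")
    samples = pd.read_csv(metadata_path, sep="\t", comment="#", index_col="sample")
    if counts.columns.duplicated().any():
        raise SchemaError("duplicate sample column")
    return GeneCountMatrix(counts=counts, samples=samples)


def write_snp_table(
    records: pd.DataFrame,
    path,
    metadata_path=None,
    params: Mapping[str, object] | None = None,
) -> None:
    """Write per-SNP allele counts (and optionally F1 sample metadata)."""
    out = records[SNP_COLUMNS].copy()
    out["flags"] = out["flags"].fillna("")
    with open(path, "w") as fh:
        fh.write(_comment_header(params))
        out.to_csv(fh, sep="\t", index=False)
    if metadata_path is not None:
        meta = (
            records[["sample", "cross", "condition", "replicate"]]
            .drop_duplicates()
            .set_index("sample")
            .sort_index()
        )
        with open(metadata_path, "w") as fh:
            fh.write(_comment_header())
            meta.to_csv(fh, sep="\t", index_label="sample")


def read_snp_table(path, metadata_path=None) -> pd.DataFrame:
    """Read per-SNP allele counts; merge cross/condition/replicate metadata.

    Returns a validated DataFrame.  Coordinates are 1-based; the maternal
    allele is the reference (B6-analog) allele throughout.
    """
    records = pd.read_csv(
        path, sep="\t", comment="#", dtype={"flags": "string"}
    )
    missing = [c for c in SNP_COLUMNS if c not in records.columns]
    if missing:
        raise SchemaError(f"SNP table lacks columns: {missing}")
    records["flags"] = records["flags"].fillna("").astype(str)
    for col in ("maternal_count", "paternal_count"):
        if (records[col] < 0).any():
            raise SchemaError(f"negative {col}")
    tokens = {
        tok
        for cell in records["flags"].unique()
        for tok in cell.split(";")
        if tok
    }
    unknown = tokens - FLAG_VOCABULARY
    if unknown:
        raise SchemaError(f"unknown SNP flags: {sorted(unknown)}")
    if metadata_path is not None:
        meta = pd.read_csv(metadata_path, sep="\t", comment="#")
        if "sample" not in meta.columns:
            raise SchemaError("SNP sample metadata lacks 'sample' column")
        absent = set(records["sample"]) - set(meta["sample"])
        if absent:
            raise SchemaError(f"samples without metadata: {sorted(absent)}")
        records = records.merge(meta, on="sample", how="left", validate="m:1")
    return records


def filter_snps(records: pd.DataFrame) -> pd.DataFrame:
    """Apply SNP-quality filtering.

    Per-record: drop observations whose maternal+paternal coverage is below
    :data:`MIN_SNP_COVERAGE`.  Per-SNP: drop every record of any SNP that
    carries a quality flag in any sample.  Idempotent; may return an empty
    frame.
    """
    records = records.copy()
    coverage = records["maternal_count"] + records["paternal_count"]
    records = records[coverage >= MIN_SNP_COVERAGE]
    flagged = records.loc[records["flags"].fillna("") != "", ["gene", "snp_id"]]
    if len(flagged):
        bad = set(map(tuple, flagged.to_numpy()))
        keys = list(zip(records["gene"], records["snp_id"]))
        records = records[[k not in bad for k in keys]]
    return records.reset_index(drop=True)


def aggregate_gene_allele_counts(
    records: pd.DataFrame, pool_replicates: bool = True
) -> pd.DataFrame:
    """Pool filtered SNP records into per-gene allelic totals.

    Groups by gene x cross x condition (x replicate unless pooling) and sums
    maternal and paternal counts over surviving SNPs; ``n_snps`` counts the
    distinct surviving SNPs contributing at least one record.
    """
    keys = ["gene", "cross", "condition"]
    if not pool_replicates:
        keys.append("replicate")
    for col in keys:
        if col not in records.columns:
            raise SchemaError(
                f"records lack column {col!r}; merge sample metadata first"
            )
    if records.empty:
        return pd.DataFrame(
            columns=keys + ["maternal_total", "paternal_total", "n_snps"]
        )
    agg = (
        records.groupby(keys, sort=True)
        .agg(
            maternal_total=("maternal_count", "sum"),
            paternal_total=("paternal_count", "sum"),
            n_snps=("snp_id", "nunique"),
        )
        .reset_index()
    )
    return agg


def informative_genes(
    gac: pd.DataFrame, purpose: str, condition: str | None = None
) -> dict[str, frozenset]:
    """Genes with enough discriminating SNPs and allelic coverage to test.

    A gene is informative for a cross when it has >= 2 surviving SNPs and a
    pooled maternal+paternal total strictly above 20 (``purpose='cistrans'``)
    or 50 (``purpose='ase'``), within each condition considered.  With
    ``condition=None`` the requirement must hold in every condition present.

    Returns a mapping cross -> frozenset of gene ids.
    """
    if purpose not in COVERAGE_THRESHOLDS:
        raise ValueError(
            f"unknown purpose {purpose!r}; expected one of "
            f"{sorted(COVERAGE_THRESHOLDS)}"
        )
    threshold = COVERAGE_THRESHOLDS[purpose]
    table = gac.copy()
    if condition is not None:
        table = table[table["condition"] == condition]
    conditions = sorted(table["condition"].unique())
    result: dict[str, frozenset] = {}
    for cross, sub in table.groupby("cross"):
        total = sub["maternal_total"] + sub["paternal_total"]
        ok = sub[(total > threshold) & (sub["n_snps"] >= 2)]
        per_gene = ok.groupby("gene")["condition"].nunique()
        genes = per_gene.index[per_gene == len(conditions)]
        result[str(cross)] = frozenset(genes)
    return result
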
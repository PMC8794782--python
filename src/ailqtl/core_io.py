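"""Shared data containers and readers/writers for the pipeline's tabular formats.

Conventions used throughout the package
---------------------------------------
* Genomic coordinates are 1-based inclusive base-pair positions (MM10-style).
  Any half-open arithmetic is internal to a function and never crosses a
  module boundary.
* Genotype codes count copies of the S1 founder allele:
  ``0 = S2/S2``, ``1 = heterozygous``, ``2 = S1/S1``; missing calls are NaN.
  This orientation matches how allele effects are reported downstream
  (S1/S1 vs HET and S1/S1 vs S2/S2 class differences).
* The canonical interchange format is UTF-8 tab-separated text with a dot
  decimal separator and ``NA`` for missing values.  VCF input is supported
  as sugar for genotype matrices; everything else is matrix-shaped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

GENOTYPE_CODES = (0.0, 1.0, 2.0)

CONSEQUENCE_CATEGORIES = (
    "stop_gain",
    "stop_loss",
    "missense",
    "promoter",
    "splice_site",
    "utr",
    "enhancer",
    "ctcf_binding_site",
    "other",
)

SIFT_CLASSES = ("deleterious", "tolerated", "none")

GENOTYPED_BY = ("array", "targeted", "none")

#: phenotype-table columns that are never treated as traits
RESERVED_PHENO_COLS = ("litter_size", "subfamily", "line", "genotyped_by")


class ValidationError(ValueError):
    """An input table violates one of its schema invariants."""


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------


@dataclass
class GenotypeMatrix:
    """SNP-by-individual matrix of parental-origin genotype codes.

    Parameters
    ----------
    markers
        One row per marker, indexed by unique marker id, with columns
        ``chrom`` (str) and ``pos`` (int, 1-based bp).  Rows are kept sorted
        by position within chromosome; chromosomes keep their order of first
        appearance.
    calls
        Genotype codes, same row index as ``markers``, one column per
        individual id; float64 with NaN for missing calls.
    """

    markers: pd.DataFrame
    calls: pd.DataFrame

    def __post_init__(self) -> None:
        m = self.markers
        if not {"chrom", "pos"} <= set(m.columns):
            raise ValidationError("markers must have 'chrom' and 'pos' columns")
        if not m.index.is_unique:
            dups = m.index[m.index.duplicated()].tolist()
            raise ValidationError(f"duplicate marker ids: {dups[:5]}")
        if not m.index.equals(self.calls.index):
            raise ValidationError("markers and calls must share the same index")
        self.markers = m = m.assign(pos=m["pos"].astype(np.int64))
        # sort within chromosome, chromosomes in first-appearance order
        order = pd.unique(m["chrom"])
        key = m["chrom"].map({c: i for i, c in enumerate(order)})
        if not (
            m.groupby(key, sort=False)["pos"].apply(lambda s: s.is_monotonic_increasing).all()
        ):
            logger.warning("marker positions not sorted within chromosome; sorting")
        idx = m.assign(_k=key).sort_values(["_k", "pos"], kind="stable").index
        self.markers = m.loc[idx]
        self.calls = self.calls.loc[idx].astype(np.float64)
        bad = ~(self.calls.isin(GENOTYPE_CODES) | self.calls.isna())
        if bad.to_numpy().any():
            raise ValidationError("genotype codes must be 0, 1, 2 or missing")

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def individuals(self) -> list[str]:
        return list(self.calls.columns)

    @property
    def chromosomes(self) -> list[str]:
        return list(pd.unique(self.markers["chrom"]))

    def subset_individuals(self, ids: Sequence[str]) -> "GenotypeMatrix":
        missing = [i for i in ids if i not in self.calls.columns]
        if missing:
            raise KeyError(f"unknown individuals: {missing[:5]}")
        return GenotypeMatrix(self.markers.copy(), self.calls[list(ids)].copy())

    def subset_markers(self, ids: Sequence[str]) -> "GenotypeMatrix":
        return GenotypeMatrix(self.markers.loc[list(ids)].copy(), self.calls.loc[list(ids)].copy())

    def codes(self, marker: str) -> pd.Series:
        """Genotype codes for one marker, indexed by individual id."""
        return self.calls.loc[marker]

    def s1_allele_freq(self) -> pd.Series:
        """Per-marker frequency of the S1 allele among non-missing calls."""
        return self.calls.mean(axis=1, skipna=True) / 2.0


def write_genotypes(g: GenotypeMatrix, path: str | Path) -> None:
    """Write a genotype matrix as TSV: ``marker chr pos ind1 ind2 ...``."""
    out = g.markers.rename(columns={"chrom": "chr"})[["chr", "pos"]].copy()
    out = pd.concat([out, g.calls], axis=1)
    out.index.name = "marker"
    out.to_csv(path, sep="\t", na_rep="NA", float_format="%g")


def read_genotypes(
    path: str | Path,
    dialect: str = "tsv_matrix",
    founder_alleles: Mapping[str, str] | str | Path | None = None,
) -> GenotypeMatrix:
    """Read genotypes from TSV (canonical) or VCF.

    For ``dialect="vcf"`` the diploid genotypes are mapped to S1-allele
    counts; ``founder_alleles`` must give the S1 founder's allele (the base,
    not REF/ALT) per variant id, either as a mapping or as the path of a
    two-column TSV ``variant s1_allele``.  Records whose S1 allele matches
    neither REF nor ALT are collected and reported together.
    """
    if dialect == "tsv_matrix":
        df = pd.read_csv(path, sep="\t", index_col="marker", na_values=["NA"])
        markers = df[["chr", "pos"]].rename(columns={"chr": "chrom"})
        markers["chrom"] = markers["chrom"].astype(str)
        calls = df.drop(columns=["chr", "pos"]).astype(np.float64)
        return GenotypeMatrix(markers, calls)
    if dialect == "vcf":
        return _read_genotypes_vcf(path, founder_alleles)
    raise ValueError(f"unknown dialect: {dialect!r}")


def _read_genotypes_vcf(
    path: str | Path, founder_alleles: Mapping[str, str] | str | Path | None
) -> GenotypeMatrix:
    from cyvcf2 import VCF

    if founder_alleles is None:
        raise ValueError("VCF input requires founder_alleles (S1 allele per variant)")
    if not isinstance(founder_alleles, Mapping):
        side = pd.read_csv(founder_alleles, sep="\t", dtype=str)
        founder_alleles = dict(zip(side["variant"], side["s1_allele"]))

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows, chroms, poss, ids, errors = [], [], [], [], []
    for v in vcf:
        vid = v.ID if v.ID not in (None, ".") else f"{v.CHROM}_{v.POS}"
        s1 = founder_alleles.get(vid)
        if s1 is None:
            errors.append(f"{vid}: no founder allele declared")
            continue
        if s1 == v.REF:
            s1_index = 0
        elif s1 in v.ALT:
            s1_index = 1 + v.ALT.index(s1)
        else:
            errors.append(f"{vid}: S1 allele {s1!r} matches neither REF nor ALT")
            continue
        codes = np.full(len(samples), np.nan)
        for j, gt in enumerate(v.genotypes):
            alleles = [a for a in gt[:-1] if a >= 0]
            if len(alleles) == 2:
                codes[j] = sum(a == s1_index for a in alleles)
        rows.append(codes)
        chroms.append(str(v.CHROM))
        poss.append(int(v.POS))
        ids.append(vid)
    if errors:
        raise ValidationError("VCF founder-allele mismatches: " + "; ".join(errors))
    markers = pd.DataFrame({"chrom": chroms, "pos": poss}, index=pd.Index(ids, name="marker"))
    calls = pd.DataFrame(np.asarray(rows, dtype=float), index=markers.index, columns=samples)
    return GenotypeMatrix(markers, calls)


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------
#
# PhenotypeTable is a plain pandas DataFrame indexed by unique individual id.
# Numeric columns other than the reserved covariate/label columns are traits.


def validate_phenotypes(df: pd.DataFrame) -> pd.DataFrame:
    if not df.index.is_unique:
        raise ValidationError("individual ids must be unique")
    if "genotyped_by" in df.columns:
        vals = set(df["genotyped_by"].dropna().unique())
        bad = vals - set(GENOTYPED_BY)
        if bad:
            raise ValidationError(f"genotyped_by values outside {GENOTYPED_BY}: {sorted(bad)}")
    for t in trait_columns(df):
        if not pd.api.types.is_numeric_dtype(df[t]):
            raise ValidationError(f"trait column {t!r} is not numeric")
    return df


def trait_columns(df: pd.DataFrame) -> list[str]:
    """Columns holding trait values (numeric, not reserved covariates/labels)."""
    return [
        c
        for c in df.columns
        if c not in RESERVED_PHENO_COLS and pd.api.types.is_numeric_dtype(df[c])
    ]


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="id", na_values=["NA"])
    return validate_phenotypes(df)


def write_phenotypes(df: pd.DataFrame, path: str | Path) -> None:
    out = df.copy()
    out.index.name = "id"
    out.to_csv(path, sep="\t", na_rep="NA", float_format="%.8g")


# ---------------------------------------------------------------------------
# Variant annotations (VEP-style, one row per variant x consequence)
# ---------------------------------------------------------------------------

_ANNOT_COLS = ["variant", "chrom", "pos", "gene", "consequence", "in_functional_domain", "sift_class"]


def read_variant_annotations(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=["NA"], dtype={"chrom": str})
    missing = [c for c in _ANNOT_COLS if c not in df.columns]
    if missing:
        raise ValidationError(f"annotation table missing columns: {missing}")
    return validate_variant_annotations(df)


def validate_variant_annotations(df: pd.DataFrame) -> pd.DataFrame:
    """Validate and normalize a variant-annotation table.

    Unknown consequence strings are mapped to ``other`` (count logged); a
    SIFT class or functional-domain flag on a non-missense row is an error.
    """
    df = df.copy()
    if len(df) == 0:
        logger.warning("empty variant annotation table")
        for c in _ANNOT_COLS:
            if c not in df.columns:
                df[c] = pd.Series(dtype=object)
        return df
    df["sift_class"] = df["sift_class"].fillna("none")
    df["in_functional_domain"] = df["in_functional_domain"].fillna(False).astype(bool)
    unknown = ~df["consequence"].isin(CONSEQUENCE_CATEGORIES)
    if unknown.any():
        logger.warning(
            "%d annotation rows with unknown consequence mapped to 'other'", int(unknown.sum())
        )
        df.loc[unknown, "consequence"] = "other"
    bad_sift = df["sift_class"].isin(("deleterious", "tolerated")) & (df["consequence"] != "missense")
    if bad_sift.any():
        raise ValidationError(
            f"sift_class set on non-missense rows: {df.index[bad_sift].tolist()[:10]}"
        )
    bad_dom = df["in_functional_domain"] & (df["consequence"] != "missense")
    if bad_dom.any():
        raise ValidationError(
            f"in_functional_domain set on non-missense rows: {df.index[bad_dom].tolist()[:10]}"
        )
    if not df["sift_class"].isin(SIFT_CLASSES).all():
        raise ValidationError("sift_class must be deleterious, tolerated or none")
    return df


def write_variant_annotations(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


# ---------------------------------------------------------------------------
# Gene models
# ---------------------------------------------------------------------------

_GENE_COLS = ["gene", "name", "chrom", "start", "end", "biotype"]


def read_gene_models(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = [c for c in _GENE_COLS if c not in df.columns]
    if missing:
        raise ValidationError(f"gene model table missing columns: {missing}")
    return validate_gene_models(df)


def validate_gene_models(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    bad = df["start"] > df["end"]
    if bad.any():
        raise ValidationError(f"gene start > end for: {df.loc[bad, 'gene'].tolist()[:10]}")
    return df


def write_gene_models(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def protein_coding(df: pd.DataFrame) -> pd.DataFrame:
    return df[df["biotype"] == "protein_coding"]


# ---------------------------------------------------------------------------
# Expression matrices
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Probe-by-sample intensity matrix with sample group labels.

    ``values`` holds intensities (probes x samples); ``samples`` is indexed
    by sample id with columns ``line`` and ``tissue``; ``probe_genes`` maps
    probe id to gene id (may contain NA for unannotated probes).
    """

    values: pd.DataFrame
    samples: pd.DataFrame
    probe_genes: pd.Series

    def __post_init__(self) -> None:
        if not self.values.columns.equals(self.samples.index):
            raise ValidationError("expression sample columns must match samples table index")
        if not self.values.index.equals(self.probe_genes.index):
            raise ValidationError("probe_genes must be indexed by the probe ids of values")
        for col in ("line", "tissue"):
            if col not in self.samples.columns:
                raise ValidationError(f"samples table missing column {col!r}")

    @property
    def tissues(self) -> list[str]:
        return list(pd.unique(self.samples["tissue"]))

    def tissue_subset(self, tissue: str) -> "ExpressionMatrix":
        keep = self.samples.index[self.samples["tissue"] == tissue]
        return ExpressionMatrix(
            self.values[keep].copy(), self.samples.loc[keep].copy(), self.probe_genes.copy()
        )


def write_expression(x: ExpressionMatrix, values_path: str | Path, samples_path: str | Path) -> None:
    out = pd.concat([x.probe_genes.rename("gene"), x.values], axis=1)
    out.index.name = "probe"
    out.to_csv(values_path, sep="\t", na_rep="NA", float_format="%.8g")
    s = x.samples.copy()
    s.index.name = "sample"
    s.to_csv(samples_path, sep="\t", na_rep="NA")


def read_expression(values_path: str | Path, samples_path: str | Path) -> ExpressionMatrix:
    df = pd.read_csv(values_path, sep="\t", index_col="probe", na_values=["NA"])
    samples = pd.read_csv(samples_path, sep="\t", index_col="sample", na_values=["NA"])
    probe_genes = df["gene"]
    values = df.drop(columns=["gene"]).astype(float)
    values.columns = values.columns.astype(str)
    samples.index = samples.index.astype(str)
    return ExpressionMatrix(values, samples, probe_genes)
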
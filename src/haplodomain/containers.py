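"""Core in-memory containers shared across the pipeline.

Counts and expression travel as pandas DataFrames (genes x samples); sample
metadata travels as a DataFrame indexed by sample id.  The helpers here
enforce the invariants the downstream models rely on: a valid genotype
vocabulary, the dominant haplotype grouping, and id-based (never positional)
alignment between matrices and metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

#: The five genotypes of the two-locus humanized-allele cross.
GENOTYPES = ("WT/WT", "WT/FC", "FC/FC", "WT/VS", "VS/VS")

#: Dominant grouping: carriers of an allele (het or hom) form one group.
HAPLOTYPE_OF_GENOTYPE = {
    "WT/WT": "WT",
    "WT/FC": "FC",
    "FC/FC": "FC",
    "WT/VS": "VS",
    "VS/VS": "VS",
}

#: Ordered haplotype levels used by the trend model: FC < WT < VS.
HAPLOTYPE_LEVELS = ("FC", "WT", "VS")

#: Allele dosage on the VS-vs-FC axis, for the additive genotype coding.
ADDITIVE_DOSAGE = {
    "FC/FC": -2.0,
    "WT/FC": -1.0,
    "WT/WT": 0.0,
    "WT/VS": 1.0,
    "VS/VS": 2.0,
}

REQUIRED_SAMPLE_COLUMNS = ("genotype", "sex", "age_cohort", "batch")


class SampleTableError(ValueError):
    """Raised when sample metadata violates a structural invariant."""


def haplotype_group(genotype: str) -> str:
    """Map a two-locus genotype to its dominant haplotype group."""
    try:
        return HAPLOTYPE_OF_GENOTYPE[genotype]
    except KeyError:
        raise SampleTableError(
            f"unknown genotype {genotype!r}; expected one of {GENOTYPES}"
        ) from None


def validate_samples(samples: pd.DataFrame) -> pd.DataFrame:
    """Validate and normalize a sample metadata table.

    The table must be indexed by unique sample ids (or carry a ``sample_id``
    column) and contain genotype, sex, age_cohort and batch columns.  A
    ``haplotype_group`` column is derived from genotype; if one is already
    present it must agree with the dominant grouping rule.
    """
    df = samples.copy()
    if "sample_id" in df.columns:
        df = df.set_index("sample_id")
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise SampleTableError(f"duplicate sample ids: {dups}")
    missing = [c for c in REQUIRED_SAMPLE_COLUMNS if c not in df.columns]
    if missing:
        raise SampleTableError(f"sample table missing columns: {missing}")
    bad = sorted(set(df["genotype"]) - set(GENOTYPES))
    if bad:
        raise SampleTableError(f"unknown genotypes: {bad}")
    bad_sex = sorted(set(df["sex"]) - {"F", "M"})
    if bad_sex:
        raise SampleTableError(f"sex must be 'F' or 'M'; got {bad_sex}")
    derived = df["genotype"].map(HAPLOTYPE_OF_GENOTYPE)
    if "haplotype_group" in df.columns:
        mism = df.index[df["haplotype_group"] != derived].tolist()
        if mism:
            raise SampleTableError(
                f"haplotype_group inconsistent with genotype for samples {mism}"
            )
    df["haplotype_group"] = derived
    df.index.name = "sample_id"
    return df


def align_to_samples(matrix: pd.DataFrame, samples: pd.DataFrame) -> pd.DataFrame:
    """Align matrix columns to the sample table by id (order-insensitive).

    Raises if the two id sets differ; returns the matrix with columns in the
    sample-table order.
    """
    mat_ids = set(matrix.columns)
    samp_ids = set(samples.index)
    if mat_ids != samp_ids:
        only_mat = sorted(mat_ids - samp_ids)[:5]
        only_samp = sorted(samp_ids - mat_ids)[:5]
        raise SampleTableError(
            "matrix columns and sample ids differ "
            f"(matrix-only: {only_mat}, metadata-only: {only_samp})"
        )
    return matrix[samples.index]


@dataclass
class ExpressionMatrix:
    """Normalized (optionally residualized) expression values.

    Attributes
    ----------
    data : DataFrame, genes x samples, continuous values.
    residualized : covariates already regressed out, in order.
    pseudocount : pseudocount used by the variance-stabilizing transform.
    size_factor_method : label of the size-factor procedure applied.
    """

    data: pd.DataFrame
    residualized: list[str] = field(default_factory=list)
    pseudocount: float = 1.0
    size_factor_method: str = "median-of-ratios"

    @property
    def genes(self) -> pd.Index:
        return self.data.index

    @property
    def samples(self) -> pd.Index:
        return self.data.columns

    def copy_with(self, data: pd.DataFrame, residualized=None) -> "ExpressionMatrix":
        return ExpressionMatrix(
            data=data,
            residualized=list(self.residualized if residualized is None else residualized),
            pseudocount=self.pseudocount,
            size_factor_method=self.size_factor_method,
        )
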
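"""Readers and writers for the pipeline's on-disk formats.

All tabular formats are TSV.  Count matrices are genes x samples with a header
row of sample ids; MatrixMarket input arrives as a triplet file plus row/col
name files.  Expression matrices carry a provenance comment header recording
normalization choices.  Exon counts are long blocks keyed by (gene_id,
feature_id).
"""

from __future__ import annotations

import pathlib

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .containers import ExpressionMatrix, validate_samples


def read_counts_tsv(path) -> pd.DataFrame:
    """Read a genes x samples integer count matrix from TSV."""
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    return df


def write_counts_tsv(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index_label="gene_id")


def read_counts_mtx(mtx_path, rownames_path, colnames_path) -> pd.DataFrame:
    """Read a MatrixMarket triplet matrix with sidecar row/col name files."""
    mat = scipy.io.mmread(mtx_path)
    if scipy.sparse.issparse(mat):
        mat = mat.toarray()
    genes = pathlib.Path(rownames_path).read_text().split()
    samples = pathlib.Path(colnames_path).read_text().split()
    return pd.DataFrame(np.asarray(mat), index=genes, columns=samples)


def write_counts_mtx(counts: pd.DataFrame, mtx_path, rownames_path, colnames_path) -> None:
    scipy.io.mmwrite(str(mtx_path), scipy.sparse.csr_matrix(counts.to_numpy()))
    pathlib.Path(rownames_path).write_text("\n".join(counts.index.astype(str)) + "\n")
    pathlib.Path(colnames_path).write_text("\n".join(counts.columns.astype(str)) + "\n")


def read_samples_tsv(path) -> pd.DataFrame:
    """Read and validate a sample metadata TSV (sample_id + required columns)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    return validate_samples(df)


def write_samples_tsv(samples: pd.DataFrame, path) -> None:
    samples.to_csv(path, sep="\t", index_label="sample_id")


def write_expression_tsv(expr: ExpressionMatrix, path) -> None:
    """Write an ExpressionMatrix with a provenance comment header."""
    with open(path, "w") as fh:
        fh.write(
            "# haplodomain expression matrix; "
            f"size_factors={expr.size_factor_method}; "
            f"pseudocount={expr.pseudocount}; "
            f"residualized={','.join(expr.residualized) or 'none'}\n"
        )
        expr.data.to_csv(fh, sep="\t", index_label="gene_id")


def read_expression_tsv(path) -> ExpressionMatrix:
    """Read an ExpressionMatrix, recovering provenance from the comment header."""
    residualized: list[str] = []
    pseudocount = 1.0
    method = "median-of-ratios"
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#"):
            for part in first.lstrip("# ").strip().split(";"):
                part = part.strip()
                if part.startswith("residualized="):
                    val = part.split("=", 1)[1]
                    residualized = [] if val == "none" else val.split(",")
                elif part.startswith("pseudocount="):
                    pseudocount = float(part.split("=", 1)[1])
                elif part.startswith("size_factors="):
                    method = part.split("=", 1)[1]
        else:
            fh.seek(0)
        data = pd.read_csv(fh, sep="\t", index_col=0)
    return ExpressionMatrix(
        data=data,
        residualized=residualized,
        pseudocount=pseudocount,
        size_factor_method=method,
    )


def read_exon_counts_tsv(path) -> pd.DataFrame:
    """Read exon/transcript counts: columns gene_id, feature_id, then samples.

    Returns a DataFrame with a (gene_id, feature_id) MultiIndex.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    return df.set_index(["gene_id", "feature_id"])


def write_exon_counts_tsv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t")


def read_ortholog_tsv(path) -> pd.DataFrame:
    """Read a two-column ortholog map (plus optional homology_type column)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError("ortholog map needs at least two id columns")
    return df
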
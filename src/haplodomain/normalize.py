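"""Normalization and nuisance-covariate removal for bulk RNA-seq counts.

The normalization chain is: median-of-ratios size factors, a
variance-stabilizing log transform of factor-scaled counts, then linear
residualization of nuisance covariates (sequencing batch at normalization
time, sex later, before the haplotype analyses).  Residuals keep each gene's
grand mean so set means stay interpretable on the normalized scale.

Sex annotation is validated against marker genes: one X-inactivation marker
expressed in females (Xist) and Y-linked markers expressed only in males
(Eif2s3y, Ddx3y), by default under their Ensembl mouse ids.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, align_to_samples

logger = logging.getLogger(__name__)

#: Default sex-marker spec: Ensembl mouse ids with symbol aliases.
DEFAULT_FEMALE_MARKERS = ("ENSMUSG00000086503", "Xist")
DEFAULT_MALE_MARKERS = (
    ("ENSMUSG00000069049", "Eif2s3y"),
    ("ENSMUSG00000069045", "Ddx3y"),
)


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors, centered to geometric mean 1.

    The reference is the per-gene geometric mean across samples, computed
    over genes expressed in every sample.  If no gene is expressed in all
    samples, the procedure falls back to genes expressed in at least half of
    the samples (geometric mean over their nonzero entries), with a warning.

    Raises
    ------
    ValueError
        If any sample has no nonzero count.
    """
    x = counts.to_numpy(dtype=float)
    if (x < 0).any():
        raise ValueError("counts must be nonnegative")
    dead = (x > 0).sum(axis=0) == 0
    if dead.any():
        raise ValueError(
            f"samples with no nonzero count: {list(counts.columns[dead])}"
        )
    all_expressed = (x > 0).all(axis=1)
    with np.errstate(divide="ignore"):
        logx = np.log(x)
    if all_expressed.any():
        ref = logx[all_expressed].mean(axis=1)  # log geometric mean
        ratios = logx[all_expressed] - ref[:, None]
        log_sf = np.median(ratios, axis=0)
    else:
        frac = (x > 0).mean(axis=1)
        usable = frac >= 0.5
        if not usable.any():
            raise ValueError("no gene expressed in at least half of the samples")
        logger.warning(
            "no gene expressed in all samples; falling back to %d genes "
            "expressed in >= 50%% of samples",
            int(usable.sum()),
        )
        sub = logx[usable]
        mask = np.isfinite(sub)
        ref = np.where(mask, sub, 0.0).sum(axis=1) / mask.sum(axis=1)
        ratios = np.where(mask, sub - ref[:, None], np.nan)
        log_sf = np.nanmedian(ratios, axis=0)
    log_sf = log_sf - log_sf.mean()  # geometric mean of factors = 1
    return pd.Series(np.exp(log_sf), index=counts.columns, name="size_factor")


def vst(
    counts: pd.DataFrame,
    factors: pd.Series,
    pseudocount: float = 1.0,
) -> ExpressionMatrix:
    """Variance-stabilizing transform: log2(count / factor + pseudocount).

    Strictly increasing in counts at fixed factor; an all-zero gene maps to
    the constant log2(pseudocount).
    """
    x = counts.to_numpy(dtype=float)
    if (x < 0).any():
        raise ValueError("counts must be nonnegative")
    f = factors.reindex(counts.columns).to_numpy(dtype=float)
    if np.any(~np.isfinite(f)) or np.any(f <= 0):
        raise ValueError("size factors must be positive and cover all samples")
    data = pd.DataFrame(
        np.log2(x / f[None, :] + pseudocount),
        index=counts.index,
        columns=counts.columns,
    )
    return ExpressionMatrix(data=data, pseudocount=pseudocount)


def _indicator_design(samples: pd.DataFrame, covariates: list[str]) -> np.ndarray:
    """Intercept + drop-first indicator columns for each covariate."""
    cols = [np.ones(len(samples))]
    for cov in covariates:
        if cov not in samples.columns:
            raise KeyError(f"covariate {cov!r} not in sample table")
        values = samples[cov].astype(str)
        levels = sorted(values.unique())
        if len(levels) < 2:
            raise ValueError(
                f"covariate {cov!r} has a single level ({levels[0]!r}) across all "
                "samples and cannot be residualized"
            )
        for lev in levels[1:]:
            cols.append((values == lev).to_numpy(dtype=float))
    return np.column_stack(cols)


def residualize(
    expr: ExpressionMatrix,
    samples: pd.DataFrame,
    covariates: list[str],
) -> ExpressionMatrix:
    """Regress covariate indicators out of every gene, keeping grand means.

    Per gene, ordinary least squares of expression on the covariate
    indicator design; the returned values are the residuals plus the gene's
    grand mean.  Idempotent for a fixed covariate list.
    """
    data = align_to_samples(expr.data, samples)
    X = _indicator_design(samples, list(covariates))
    Y = data.to_numpy(dtype=float).T  # samples x genes
    Q, _ = np.linalg.qr(X)
    resid = Y - Q @ (Q.T @ Y)
    out = resid + Y.mean(axis=0, keepdims=True)
    new = pd.DataFrame(out.T, index=data.index, columns=data.columns)
    done = list(expr.residualized)
    for cov in covariates:
        if cov not in done:
            done.append(cov)
    return expr.copy_with(new, residualized=done)


@dataclass
class SexMarkerSpec:
    """Marker genes for sex validation.

    ``female`` is expressed in females and near zero in males; every gene in
    ``male`` shows the reverse pattern.  Aliases allow symbol or Ensembl-id
    matrices.
    """

    female: tuple[str, ...] = DEFAULT_FEMALE_MARKERS
    male: tuple[tuple[str, ...], ...] = DEFAULT_MALE_MARKERS

    def resolve(self, index: pd.Index) -> tuple[str, list[str]]:
        fem = next((g for g in self.female if g in index), None)
        males = [next((g for g in alias if g in index), None) for alias in self.male]
        missing = []
        if fem is None:
            missing.append("/".join(self.female))
        missing += ["/".join(a) for a, hit in zip(self.male, males) if hit is None]
        males = [m for m in males if m is not None]
        if fem is None or not males:
            raise KeyError(f"sex marker genes absent from matrix: {missing}")
        return fem, males


def validate_sex(
    counts: pd.DataFrame,
    samples: pd.DataFrame,
    marker_spec: SexMarkerSpec | None = None,
) -> pd.DataFrame:
    """Flag samples whose marker expression contradicts the annotated sex.

    Counts are size-factor normalized and log-transformed, then each marker
    casts a vote: a sample is on a marker's female side if its normalized
    value is below (male markers) or above (female marker) the midpoint of
    the two sex-wise medians.  The majority vote across markers gives the
    inferred sex; ``passed`` is True when it matches the annotation.
    """
    spec = marker_spec or SexMarkerSpec()
    counts = align_to_samples(counts, samples)
    fem_gene, male_genes = spec.resolve(counts.index)
    expr = vst(counts, size_factors(counts)).data
    annotated = samples["sex"].astype(str)

    votes = pd.DataFrame(index=samples.index)
    for gene, female_high in [(fem_gene, True)] + [(g, False) for g in male_genes]:
        row = expr.loc[gene]
        med_f = row[annotated == "F"].median()
        med_m = row[annotated == "M"].median()
        cut = 0.5 * (med_f + med_m)
        looks_female = (row > cut) if female_high else (row < cut)
        votes[gene] = np.where(looks_female, "F", "M")

    inferred = votes.mode(axis=1)[0]
    out = pd.DataFrame(
        {
            "annotated_sex": annotated,
            "inferred_sex": inferred,
            "passed": (inferred == annotated),
        },
        index=samples.index,
    )
    n_bad = int((~out["passed"]).sum())
    if n_bad:
        logger.warning("sex validation: %d sample(s) contradict annotation", n_bad)
    return out


def normalize_counts(
    counts: pd.DataFrame,
    samples: pd.DataFrame,
    residualize_covariates: list[str] = ("batch",),
    pseudocount: float = 1.0,
) -> ExpressionMatrix:
    """Convenience chain: size factors -> vst -> residualize covariates."""
    counts = align_to_samples(counts, samples)
    expr = vst(counts, size_factors(counts), pseudocount=pseudocount)
    if residualize_covariates:
        expr = residualize(expr, samples, list(residualize_covariates))
    return expr
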
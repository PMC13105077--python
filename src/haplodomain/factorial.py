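"""Per-gene factorial differential expression.

The model for every gene's normalized expression is

    y = b1*age + b2*sex + b3*haplotype + b12 + b13 + b23 + e

with age and sex as two-level factors, haplotype as the three-level dominant
grouping (FC, WT, VS), and the three pairwise interactions.  Each term is
tested with a partial F-test respecting marginality (type-II style): a main
effect is compared within the model that retains the other mains and the
interactions not involving it; an interaction is compared against the full
model without it.  The denominator mean square always comes from the complete
model.  Benjamini-Hochberg adjustment is applied per term across genes.

Single-age cohorts drop the age terms from the model entirely.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .containers import ADDITIVE_DOSAGE, align_to_samples

logger = logging.getLogger(__name__)

MAIN_TERMS = ("age", "sex", "haplotype")
INTERACTIONS = (("age", "sex"), ("age", "haplotype"), ("sex", "haplotype"))


class DesignError(ValueError):
    """Raised for rank-deficient or degenerate factorial designs."""


def _factor_columns(values: pd.Series) -> tuple[np.ndarray, list[str], str]:
    """Drop-first indicator block for a factor; returns (block, names, reference)."""
    vals = values.astype(str)
    levels = sorted(vals.unique())
    block = np.column_stack(
        [(vals == lev).to_numpy(dtype=float) for lev in levels[1:]]
    ) if len(levels) > 1 else np.empty((len(vals), 0))
    names = [f"{values.name}[{lev}]" for lev in levels[1:]]
    return block, names, levels[0]


@dataclass
class _TermBlock:
    name: str
    columns: np.ndarray  # samples x k
    involves: frozenset[str]


class FactorialDEModel:
    """Factorial linear model of expression on age, sex and haplotype.

    Parameters
    ----------
    expr : ExpressionMatrix or genes x samples DataFrame
        Normalized (batch-residualized) expression.
    samples : DataFrame
        Validated sample table aligned by id.
    cohort : str or None
        Restrict to one age cohort; age terms are then dropped, as in a
        single-age analysis.
    """

    def __init__(self, expr, samples: pd.DataFrame, cohort: str | None = None):
        data = expr.data if hasattr(expr, "data") else expr
        if cohort is not None:
            samples = samples[samples["age_cohort"].astype(str) == str(cohort)]
            if samples.empty:
                raise DesignError(f"no samples in age cohort {cohort!r}")
            data = data[samples.index]
        self.data = align_to_samples(data, samples)
        self.samples = samples
        self.cohort = cohort
        self._build_design()

    def _build_design(self) -> None:
        samples = self.samples
        n = len(samples)
        self.reference_levels: dict[str, str] = {}
        factors: dict[str, np.ndarray] = {}
        factor_names: dict[str, list[str]] = {}
        use_age = samples["age_cohort"].astype(str).nunique() > 1

        for term in MAIN_TERMS:
            col = "age_cohort" if term == "age" else ("haplotype_group" if term == "haplotype" else term)
            series = samples[col].astype(str).rename(term)
            counts = series.value_counts()
            if (counts < 2).any():
                lonely = counts[counts < 2].index.tolist()
                raise DesignError(f"factor {term!r} has levels with < 2 samples: {lonely}")
            if term == "age" and not use_age:
                continue
            block, names, ref = _factor_columns(series)
            factors[term] = block
            factor_names[term] = names
            self.reference_levels[term] = ref

        blocks: list[_TermBlock] = []
        for term, block in factors.items():
            blocks.append(_TermBlock(term, block, frozenset({term})))
        for a, b in INTERACTIONS:
            if a in factors and b in factors:
                cols = [
                    factors[a][:, i] * factors[b][:, j]
                    for i in range(factors[a].shape[1])
                    for j in range(factors[b].shape[1])
                ]
                blocks.append(_TermBlock(f"{a}:{b}", np.column_stack(cols), frozenset({a, b})))

        self.term_blocks = blocks
        self.terms = [b.name for b in blocks]
        X_full = np.column_stack([np.ones(n)] + [b.columns for b in blocks])
        rank = np.linalg.matrix_rank(X_full)
        if rank < X_full.shape[1]:
            # walk term by term to name the aliased addition
            cur = np.ones((n, 1))
            for b in blocks:
                cand = np.hstack([cur, b.columns])
                if np.linalg.matrix_rank(cand) < cur.shape[1] + b.columns.shape[1]:
                    raise DesignError(f"design is collinear: term {b.name!r} is aliased")
                cur = cand
            raise DesignError("design matrix is rank deficient")
        self.X_full = X_full

    @staticmethod
    def _rss(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
        """Residual sum of squares per column of Y under OLS on X."""
        Q, _ = np.linalg.qr(X)
        proj = Q.T @ Y
        return np.einsum("ij,ij->j", Y, Y) - np.einsum("ij,ij->j", proj, proj)

    def fit(self) -> "FactorialDEResults":
        Y = self.data.to_numpy(dtype=float).T  # samples x genes
        n, n_genes = Y.shape
        df_err = n - self.X_full.shape[1]
        if df_err <= 0:
            raise DesignError("no residual degrees of freedom in the full model")
        rss_full = self._rss(self.X_full, Y)
        scale = np.maximum(np.einsum("ij,ij->j", Y, Y), 1.0)
        mse = rss_full / df_err

        records = []
        for block in self.term_blocks:
            # marginality: drop interactions that contain this term from both models
            context = [
                b for b in self.term_blocks
                if b.name != block.name and not (block.involves < b.involves)
            ]
            X_with = np.column_stack(
                [np.ones(n)] + [b.columns for b in context] + [block.columns]
            )
            X_without = (
                np.column_stack([np.ones(n)] + [b.columns for b in context])
                if context
                else np.ones((n, 1))
            )
            rss_with = self._rss(X_with, Y)
            rss_without = self._rss(X_without, Y)
            df_term = block.columns.shape[1]
            num = np.maximum(rss_without - rss_with, 0.0) / df_term
            with np.errstate(divide="ignore", invalid="ignore"):
                F = num / mse
            # degenerate responses (constant genes): F := 0, p := 1
            degenerate = rss_full <= 1e-12 * scale
            F = np.where(degenerate | ~np.isfinite(F), 0.0, F)
            p = scipy.stats.f.sf(F, df_term, df_err)
            p = np.where(F == 0.0, 1.0, p)
            q = multipletests(p, method="fdr_bh")[1]
            records.append(
                pd.DataFrame(
                    {
                        "gene_id": self.data.index,
                        "term": block.name,
                        "F": F,
                        "p": p,
                        "q": q,
                    }
                )
            )
        stats = pd.concat(records, ignore_index=True)
        return FactorialDEResults(stats, terms=self.terms, reference_levels=self.reference_levels, cohort=self.cohort)


@dataclass
class FactorialDEResults:
    """Per-gene, per-term F statistics with BH-adjusted q-values."""

    term_stats: pd.DataFrame
    terms: list[str]
    reference_levels: dict[str, str]
    cohort: str | None = None

    def count_deg(self, fdr: float = 0.05) -> pd.Series:
        """Number of genes with q <= fdr for each model term."""
        if self.term_stats.empty:
            raise ValueError("no term statistics to count")
        counts = (
            self.term_stats.assign(sig=self.term_stats["q"] <= fdr)
            .groupby("term")["sig"]
            .sum()
            .astype(int)
        )
        return counts.reindex(self.terms)

    def summary(self, fdr: float = 0.05) -> pd.DataFrame:
        """DEG-count summary table, one row per cohort, dash for absent terms."""
        counts = self.count_deg(fdr)
        order = ["sex", "haplotype", "sex:haplotype", "age", "age:sex", "age:haplotype"]
        row = {t: (int(counts[t]) if t in counts.index else "-") for t in order}
        label = self.cohort if self.cohort is not None else "all"
        return pd.DataFrame([row], index=pd.Index([label], name="cohort"))


def fit_factorial(expr, samples: pd.DataFrame, cohort: str | None = None) -> FactorialDEResults:
    """Fit the factorial model to every gene; functional wrapper."""
    return FactorialDEModel(expr, samples, cohort=cohort).fit()


def count_deg(results_or_stats, fdr: float = 0.05) -> pd.Series:
    """Per-term DEG counts at an FDR threshold."""
    if isinstance(results_or_stats, FactorialDEResults):
        return results_or_stats.count_deg(fdr)
    stats = results_or_stats
    if stats.empty:
        raise ValueError("no term statistics to count")
    return stats.assign(sig=stats["q"] <= fdr).groupby("term")["sig"].sum().astype(int)


def _adjusted_r2_1pred(y: np.ndarray, x: np.ndarray) -> float:
    """Adjusted R^2 of a single-predictor OLS fit (intercept + x)."""
    n = len(y)
    xc = x - x.mean()
    yc = y - y.mean()
    denom = float(xc @ xc)
    sst = float(yc @ yc)
    if denom == 0.0 or sst == 0.0:
        return 0.0
    beta = float(xc @ yc) / denom
    sse = sst - beta * float(xc @ yc)
    r2 = 1.0 - sse / sst
    return 1.0 - (1.0 - r2) * (n - 1) / (n - 2)


def compare_codings(expr, samples: pd.DataFrame, genes) -> dict[str, float]:
    """Variance explained by dominant vs additive genotype codings.

    The response is the mean expression of ``genes``.  The dominant coding
    places the carrier groups on the ordered axis FC < WT < VS (-1, 0, +1);
    the additive coding uses the VS-vs-FC allele dosage (FC/FC=-2, WT/FC=-1,
    WT/WT=0, WT/VS=+1, VS/VS=+2).  Returns adjusted R^2 for both.
    """
    from .genesets import set_mean_expression

    data = expr.data if hasattr(expr, "data") else expr
    data = align_to_samples(data, samples)
    y = set_mean_expression(data, list(genes)).to_numpy(dtype=float)

    present = set(samples["genotype"].astype(str))
    absent = sorted(set(ADDITIVE_DOSAGE) - present)
    if absent:
        warnings.warn(f"genotype classes absent: {absent}; proceeding with the rest", stacklevel=2)

    dominant_code = {"FC": -1.0, "WT": 0.0, "VS": 1.0}
    x_dom = samples["haplotype_group"].map(dominant_code).to_numpy(dtype=float)
    x_add = samples["genotype"].map(ADDITIVE_DOSAGE).to_numpy(dtype=float)
    return {
        "dominant_R2": _adjusted_r2_1pred(y, x_dom),
        "additive_R2": _adjusted_r2_1pred(y, x_add),
    }
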
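"""Ordered-haplotype trend models for gene-set mean expression.

Each gene set's per-sample mean expression is regressed on the haplotype
ordered factor FC < WT < VS encoded by the centered linear contrast
(-1, 0, +1):

    y = b1 * haplotype + e

The linear-contrast coefficient b1 is the effect size (positive means higher
expression in VS carriers than FC carriers), adjusted R^2 is the reported
strength of the relationship (it can be negative), and the two-sided p-value
comes from the coefficient t-test.  Benjamini-Hochberg q-values are computed
within a testing family (subdomains, Biodomains and pathway intersections are
separate families with their own thresholds: 0.05 for subdomains, 0.001 for
intersections).  The quadratic (curvature) contrast is fitted alongside as a
diagnostic only and never tested.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .containers import HAPLOTYPE_LEVELS, align_to_samples

logger = logging.getLogger(__name__)

#: Centered linear contrast over the ordered levels FC < WT < VS.
LINEAR_CONTRAST = {"FC": -1.0, "WT": 0.0, "VS": 1.0}
#: Centered quadratic contrast (diagnostic only).
QUADRATIC_CONTRAST = {"FC": 1.0, "WT": -2.0, "VS": 1.0}


class TrendModelError(ValueError):
    pass


@dataclass
class TrendFitResult:
    """Ordered-haplotype trend fit for one gene set."""

    set_id: str
    n_FC: int
    n_WT: int
    n_VS: int
    beta: float
    r2_adj: float
    p: float
    q: float = float("nan")
    beta_quadratic: float = float("nan")


class HaplotypeTrendModel:
    """Linear-contrast trend model over one or many gene-set mean responses.

    Parameters
    ----------
    set_means : Series (one set) or DataFrame (sets x samples)
    samples : validated sample table with a ``haplotype_group`` column
    """

    def __init__(self, set_means, samples: pd.DataFrame):
        if isinstance(set_means, pd.Series):
            name = set_means.name if set_means.name is not None else "set"
            set_means = set_means.to_frame(name).T
        self.set_means = align_to_samples(set_means, samples)
        self.samples = samples
        groups = samples["haplotype_group"].astype(str)
        self.group_n = {
            lev: int((groups == lev).sum()) for lev in HAPLOTYPE_LEVELS
        }
        missing = [lev for lev, n in self.group_n.items() if n < 2]
        if missing:
            raise TrendModelError(
                f"haplotype groups with < 2 samples: {missing}"
            )
        self.x = groups.map(LINEAR_CONTRAST).to_numpy(dtype=float)
        self.x_quad = groups.map(QUADRATIC_CONTRAST).to_numpy(dtype=float)

    def fit(self) -> "TrendResults":
        Y = self.set_means.to_numpy(dtype=float)  # sets x samples
        n = Y.shape[1]
        x = self.x
        xc = x - x.mean()
        sxx = float(xc @ xc)
        Yc = Y - Y.mean(axis=1, keepdims=True)
        sxy = Yc @ xc
        beta = sxy / sxx
        sst = np.einsum("ij,ij->i", Yc, Yc)
        sse = sst - beta * sxy
        df_err = n - 2
        with np.errstate(divide="ignore", invalid="ignore"):
            r2 = 1.0 - sse / sst
            se = np.sqrt(np.maximum(sse, 0.0) / df_err / sxx)
            t = beta / se
        p = 2.0 * scipy.stats.t.sf(np.abs(t), df_err)
        r2_adj = 1.0 - (1.0 - r2) * (n - 1) / df_err

        # zero-variance responses: no trend, beta 0, p 1
        degenerate = sst <= 1e-12 * np.maximum(np.einsum("ij,ij->i", Y, Y), 1.0)
        if degenerate.any():
            logger.info("%d set(s) with zero response variance", int(degenerate.sum()))
        beta = np.where(degenerate, 0.0, beta)
        p = np.where(degenerate | ~np.isfinite(p), 1.0, p)
        r2_adj = np.where(degenerate, 0.0, r2_adj)

        # quadratic diagnostic: coefficient from the two-contrast fit
        xq = self.x_quad - self.x_quad.mean()
        xq = xq - (xq @ xc) / sxx * xc  # orthogonalize against linear
        sqq = float(xq @ xq)
        beta_quad = (Yc @ xq) / sqq if sqq > 0 else np.full(Y.shape[0], np.nan)
        logger.debug("quadratic-contrast diagnostics computed for %d sets", Y.shape[0])

        q = multipletests(p, method="fdr_bh")[1]
        table = pd.DataFrame(
            {
                "set_id": self.set_means.index,
                "n_FC": self.group_n["FC"],
                "n_WT": self.group_n["WT"],
                "n_VS": self.group_n["VS"],
                "beta": beta,
                "r2_adj": r2_adj,
                "p": p,
                "q": q,
                "beta_quadratic": beta_quad,
            }
        ).set_index("set_id")
        return TrendResults(table)


@dataclass
class TrendResults:
    """Per-set trend coefficients, adjusted R^2, p and BH q-values."""

    table: pd.DataFrame

    def screen(self, fdr: float) -> pd.DataFrame:
        """Rows with q <= fdr, sorted by beta descending."""
        kept = self.table[self.table["q"] <= fdr]
        return kept.sort_values("beta", ascending=False)

    def summary(self) -> pd.DataFrame:
        cols = ["n_FC", "n_WT", "n_VS", "beta", "r2_adj", "p", "q"]
        return self.table[cols].sort_values("q")

    def __len__(self) -> int:
        return len(self.table)


def fit_haplotype_trend(set_means: pd.Series, samples: pd.DataFrame) -> TrendFitResult:
    """Fit the trend model to a single set's mean expression."""
    res = HaplotypeTrendModel(set_means, samples).fit().table.iloc[0]
    return TrendFitResult(
        set_id=str(res.name),
        n_FC=int(res["n_FC"]),
        n_WT=int(res["n_WT"]),
        n_VS=int(res["n_VS"]),
        beta=float(res["beta"]),
        r2_adj=float(res["r2_adj"]),
        p=float(res["p"]),
        q=float(res["q"]),
        beta_quadratic=float(res["beta_quadratic"]),
    )


def screen_sets(fits, fdr: float) -> pd.DataFrame:
    """BH-screen a family of trend fits and sort by effect size (descending).

    ``fits`` may be a TrendResults, a table indexed by set_id, or a list of
    TrendFitResult.  The BH family is exactly the supplied fits; the caller
    chooses the threshold appropriate to the family (0.05 for subdomains,
    0.001 for intersections).
    """
    if isinstance(fits, TrendResults):
        table = fits.table.copy()
    elif isinstance(fits, pd.DataFrame):
        table = fits.copy()
    else:
        table = pd.DataFrame([f.__dict__ for f in fits]).set_index("set_id")
    if table.empty:
        raise TrendModelError("no fits supplied")
    table["q"] = multipletests(table["p"].to_numpy(), method="fdr_bh")[1]
    kept = table[table["q"] <= fdr]
    return kept.sort_values("beta", ascending=False)


def biadjacency(results: pd.DataFrame) -> pd.DataFrame:
    """Pathway x domain matrix of trend effect sizes.

    ``results`` must carry ``pathway``, ``domain`` and ``beta`` columns (one
    row per retained intersection).  Rows and columns are ordered by mean
    absolute beta, descending; absent pairs are NaN.
    """
    if results.empty:
        return pd.DataFrame()
    required = {"pathway", "domain", "beta"}
    if not required.issubset(results.columns):
        raise ValueError(f"results must have columns {sorted(required)}")
    if results.duplicated(subset=["pathway", "domain"]).any():
        dups = results[results.duplicated(subset=["pathway", "domain"], keep=False)]
        raise ValueError(
            f"duplicate (pathway, domain) entries: "
            f"{sorted(set(zip(dups['pathway'], dups['domain'])))}"
        )
    mat = results.pivot(index="pathway", columns="domain", values="beta")
    row_order = mat.abs().mean(axis=1).sort_values(ascending=False).index
    col_order = mat.abs().mean(axis=0).sort_values(ascending=False).index
    return mat.loc[row_order, col_order]
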
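"""Cross-system effect concordance: mouse haplotype betas vs treatment betas.

A two-group (treated vs untreated) expression dataset over the same
intersection sets is compared to the mouse ordered-haplotype effects.  Mouse
gene sets transfer through a strict one-to-one ortholog map; per set, gene
expression is averaged across replicates within each group and the per-gene
group means are regressed on a centered treatment indicator, giving one
treatment coefficient per set.  Set-level agreement is summarized by the
Spearman rank correlation of the two beta vectors and a per-set concordance
class (concordant / discordant / null) against a magnitude floor.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# orthologs

@dataclass
class OrthologMap:
    """One-to-one gene-id pairs between two species.

    Built from a two-column table (optionally with a homology-type column);
    any id participating in more than one pair is dropped so the retained
    pairs are strictly one-to-one.
    """

    pairs: pd.DataFrame  # columns: a, b

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, homology_filter: str | None = None) -> "OrthologMap":
        df = frame.copy()
        if homology_filter is not None and "homology_type" in df.columns:
            df = df[df["homology_type"] == homology_filter]
        df = df.iloc[:, :2].dropna()
        df.columns = ["a", "b"]
        df = df.drop_duplicates()
        multi_a = df["a"].duplicated(keep=False)
        multi_b = df["b"].duplicated(keep=False)
        dropped = int((multi_a | multi_b).sum())
        if dropped:
            logger.info("dropping %d many-to-many ortholog pairs", dropped)
        df = df[~(multi_a | multi_b)].reset_index(drop=True)
        return cls(pairs=df)

    def __len__(self) -> int:
        return len(self.pairs)

    def to_other(self) -> dict[str, str]:
        return dict(zip(self.pairs["a"], self.pairs["b"]))

    def map_genes(self, genes) -> list[str]:
        table = self.to_other()
        return [table[g] for g in genes if g in table]


# ---------------------------------------------------------------------------
# filtering and per-set treatment effects

def filter_transcripts(counts: pd.DataFrame, min_total: int = 10) -> pd.DataFrame:
    """Keep rows whose total count across all samples is at least ``min_total``."""
    totals = counts.sum(axis=1)
    out = counts[totals >= min_total]
    if out.empty:
        warnings.warn("no transcripts pass the total-count filter", stacklevel=2)
    return out


def treatment_effect(
    expr,
    treatment: pd.Series,
    set_genes,
    orthologs: OrthologMap | None = None,
    use_replicates: bool = False,
) -> float | None:
    """Treatment coefficient for one gene set in the two-group dataset.

    ``set_genes`` are source-species ids when ``orthologs`` is given (they
    are mapped first), otherwise ids native to ``expr``.  By default each
    gene is averaged across replicates within group and the stacked per-gene
    group means are regressed on a centered treatment indicator
    (treated = +1/2, untreated = -1/2) with per-gene intercepts, so the
    coefficient is the mean treated-minus-untreated difference over the
    set's genes.  ``use_replicates`` fits the same model on the per-replicate
    values instead.  Returns None (with a warning) when no mapped gene is
    present in the matrix.
    """
    data = expr.data if hasattr(expr, "data") else expr
    genes = list(set_genes)
    if orthologs is not None:
        genes = orthologs.map_genes(genes)
    genes = [g for g in genes if g in data.index]
    if not genes:
        warnings.warn("no mapped set genes present in the matrix; set skipped", stacklevel=2)
        return None
    groups = treatment.reindex(data.columns)
    labels = sorted(groups.unique())
    if len(labels) != 2:
        raise ValueError(f"treatment must have exactly 2 levels, got {labels}")
    for lab in labels:
        if int((groups == lab).sum()) < 2:
            raise ValueError(f"treatment group {lab!r} has < 2 samples")
    treated_label = "treated" if "treated" in labels else labels[-1]

    sub = data.loc[genes]
    if use_replicates:
        values = sub.to_numpy(dtype=float)
        t = np.where(groups == treated_label, 0.5, -0.5)
        # per-gene intercepts + shared treatment slope
        y = values - values.mean(axis=1, keepdims=True)
        tc = t - t.mean()
        beta = float((y * tc[None, :]).sum() / (len(genes) * (tc @ tc)))
        return beta
    means = pd.DataFrame(
        {lab: sub.loc[:, (groups == lab).to_numpy()].mean(axis=1) for lab in labels}
    )
    other_label = [lab for lab in labels if lab != treated_label][0]
    # stacked 2-obs-per-gene OLS with gene intercepts reduces to this mean
    return float((means[treated_label] - means[other_label]).mean())


# ---------------------------------------------------------------------------
# comparison

def _spearman_exact(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman rho with an exact two-sided permutation p (small n)."""
    rx = scipy.stats.rankdata(x)
    ry = scipy.stats.rankdata(y)
    rxc = rx - rx.mean()
    ryc = ry - ry.mean()
    denom = np.sqrt((rxc @ rxc) * (ryc @ ryc))
    if denom == 0:
        return 0.0, 1.0
    rho = float((rxc @ ryc) / denom)
    s_obs = abs(rxc @ ryc)
    n = len(x)
    count = 0
    total = 0
    chunk: list[tuple[int, ...]] = []

    def flush(chunk):
        idx = np.asarray(chunk)
        s = np.abs(ryc[idx] @ rxc)
        return int((s >= s_obs - 1e-12).sum()), len(chunk)

    for perm in itertools.permutations(range(n)):
        chunk.append(perm)
        if len(chunk) == 100_000:
            c, t = flush(chunk)
            count, total, chunk = count + c, total + t, []
    if chunk:
        c, t = flush(chunk)
        count, total = count + c, total + t
    return rho, count / total


@dataclass
class EffectComparison:
    set_id: str
    beta_mouse: float
    beta_other: float
    concordance: str


def compare_effects(
    mouse_betas: pd.Series,
    other_betas: pd.Series,
    magnitude_floor: tuple[float, float] | None = None,
) -> tuple[float, float, pd.DataFrame]:
    """Spearman correlation and per-set concordance of two effect vectors.

    Shared sets are matched by id; fewer than 3 shared sets is an error.
    The p-value uses the t approximation for n > 10 and exact permutation
    enumeration otherwise.  A set is concordant when both betas clear the
    magnitude floor (default: the median absolute beta of each family) with
    the same sign, discordant when both clear it with opposite signs, and
    null otherwise.
    """
    shared = mouse_betas.index.intersection(other_betas.index)
    if len(shared) < 3:
        raise ValueError(f"only {len(shared)} shared sets; need >= 3")
    bm = mouse_betas.loc[shared].to_numpy(dtype=float)
    bo = other_betas.loc[shared].to_numpy(dtype=float)

    if len(shared) > 10:
        rho, p = scipy.stats.spearmanr(bm, bo)
        rho, p = float(rho), float(p)
    else:
        rho, p = _spearman_exact(bm, bo)

    if magnitude_floor is None:
        floor_m = float(np.median(np.abs(bm)))
        floor_o = float(np.median(np.abs(bo)))
    else:
        floor_m, floor_o = magnitude_floor
    classes = []
    for m, o in zip(bm, bo):
        if abs(m) >= floor_m and abs(o) >= floor_o:
            classes.append("concordant" if np.sign(m) == np.sign(o) else "discordant")
        else:
            classes.append("null")
    table = pd.DataFrame(
        {"beta_mouse": bm, "beta_other": bo, "concordance": classes},
        index=pd.Index(shared, name="set_id"),
    )
    return rho, p, table
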
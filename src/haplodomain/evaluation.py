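"""Simulation-based evaluation of the pipeline's statistical properties.

Each function runs the package end to end on generator output with known
ground truth and measures one property: estimator agreement with a direct
normal-equations solver, type-I error calibration, planted-effect recovery,
coding comparison, Dirichlet-multinomial correctness, differential-usage
calibration and power, filter exactness, cross-system concordance recovery,
and sex-validation accuracy.  The same routines back the test suite and the
reproduction script, so reported numbers always come from a fresh run.

Problem sizes are chosen to mirror the emulated study where it fixes them
(20 samples per haplotype group, depth-500 exon counts, three organoid
replicates) and to give stable Monte-Carlo estimates elsewhere.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import scipy.stats

from . import cross_system, exon_usage, factorial, genesets, normalize, simulate, trend

# a 12-month-style carriers cohort: 20 samples per haplotype group
_CARRIER_CELLS = {
    ("FC/FC", "F", "12mo"): 5, ("FC/FC", "M", "12mo"): 5,
    ("WT/FC", "F", "12mo"): 5, ("WT/FC", "M", "12mo"): 5,
    ("WT/WT", "F", "12mo"): 10, ("WT/WT", "M", "12mo"): 10,
    ("WT/VS", "F", "12mo"): 5, ("WT/VS", "M", "12mo"): 5,
    ("VS/VS", "F", "12mo"): 5, ("VS/VS", "M", "12mo"): 5,
}


def carrier_cohort(seed: int, n_batches: int = 2) -> pd.DataFrame:
    """Single-age cohort with 20 samples in each haplotype group."""
    design = simulate.CohortDesign(
        n_per_cell=dict(_CARRIER_CELLS),
        ages=("12mo",),
        n_batches=n_batches,
        seed=seed,
    )
    return simulate.simulate_cohort(design)


# ---------------------------------------------------------------------------
# estimator agreement with a direct normal-equations solver

def _normal_equations_term_f(X_full, blocks, y):
    """Type-II term F statistics computed via explicit normal equations."""
    n = X_full.shape[0]

    def rss(X):
        XtX = X.T @ X
        beta = np.linalg.solve(XtX, X.T @ y)
        r = y - X @ beta
        return float(r @ r)

    rss_full = rss(X_full)
    df_err = n - X_full.shape[1]
    out = {}
    for block in blocks:
        context = [
            b for b in blocks
            if b.name != block.name and not (block.involves < b.involves)
        ]
        X_with = np.column_stack([np.ones(n)] + [b.columns for b in context] + [block.columns])
        X_without = (
            np.column_stack([np.ones(n)] + [b.columns for b in context])
            if context else np.ones((n, 1))
        )
        df_t = block.columns.shape[1]
        num = max(rss(X_without) - rss(X_with), 0.0) / df_t
        out[block.name] = num / (rss_full / df_err)
    return out


def ols_agreement(seed: int, n_designs: int = 100, max_samples: int = 50) -> dict:
    """Max |difference| between pipeline fits and a normal-equations solver.

    Covers both the factorial per-gene model (term F statistics) and the
    ordered-haplotype trend model (beta, adjusted R^2, p) on random designs
    of up to ``max_samples`` samples.
    """
    rng = np.random.default_rng(seed)
    worst_f = 0.0
    worst_trend = 0.0
    for i in range(n_designs):
        n_cells = rng.integers(2, 5)
        design = simulate.CohortDesign(
            n_per_cell=int(n_cells),
            ages=("4mo", "12mo") if rng.random() < 0.5 else ("12mo",),
            n_batches=1,
            seed=int(rng.integers(2**31)),
        )
        samples = simulate.simulate_cohort(design)
        if len(samples) > max_samples:
            samples = samples.iloc[:max_samples]
            # keep every factor level populated
            if samples["haplotype_group"].nunique() < 3:
                continue
        y = rng.normal(size=len(samples))
        expr = pd.DataFrame([y], index=["g1"], columns=samples.index)
        try:
            model = factorial.FactorialDEModel(expr, samples)
        except factorial.DesignError:
            continue
        res = model.fit().term_stats.set_index("term")
        oracle = _normal_equations_term_f(model.X_full, model.term_blocks, y)
        for term, f_oracle in oracle.items():
            worst_f = max(worst_f, abs(float(res.loc[term, "F"]) - f_oracle))

        # trend model vs scipy.stats.linregress on the same response
        x = samples["haplotype_group"].map(trend.LINEAR_CONTRAST).to_numpy()
        fit = trend.fit_haplotype_trend(pd.Series(y, index=samples.index), samples)
        lr = scipy.stats.linregress(x, y)
        n = len(y)
        r2_adj = 1 - (1 - lr.rvalue**2) * (n - 1) / (n - 2)
        worst_trend = max(
            worst_trend,
            abs(fit.beta - lr.slope),
            abs(fit.r2_adj - r2_adj),
            abs(fit.p - lr.pvalue),
        )
    return {"factorial_max_abs_diff": worst_f, "trend_max_abs_diff": worst_trend}


# ---------------------------------------------------------------------------
# calibration under the global null

def factorial_type1(seed: int, n_genes: int = 10000) -> dict:
    """Per-term rejection rate at p <= 0.05 on null negative-binomial data."""
    design = simulate.CohortDesign(n_per_cell=5, seed=seed)
    samples = simulate.simulate_cohort(design)
    counts = simulate.simulate_counts(
        samples, {}, [], n_genes=n_genes, seed=seed + 1, include_sex_markers=False
    )
    expr = normalize.normalize_counts(counts, samples, ["batch"])
    stats = factorial.fit_factorial(expr, samples).term_stats
    rates = stats.groupby("term")["p"].apply(lambda p: float((p <= 0.05).mean()))
    return {"per_term": rates.to_dict(), "n_genes": n_genes}


def null_intersection_screen(seed: int, n_sims: int = 500, n_sets: int = 200) -> dict:
    """Intersections retained at FDR 0.001 under the null, across simulations.

    Set-mean responses are drawn null-normal for a 20-per-group carrier
    cohort; reported are the mean number retained per simulation and the
    fraction of simulations with any retention (both should be consistent
    with the nominal rate).
    """
    samples = carrier_cohort(seed)
    rng = np.random.default_rng(seed + 1)
    total_retained = 0
    sims_with_hit = 0
    for _ in range(n_sims):
        means = pd.DataFrame(
            rng.normal(size=(n_sets, len(samples))),
            index=[f"S{i}" for i in range(n_sets)],
            columns=samples.index,
        )
        res = trend.HaplotypeTrendModel(means, samples).fit()
        kept = trend.screen_sets(res, 0.001)
        total_retained += len(kept)
        sims_with_hit += int(len(kept) > 0)
    return {
        "mean_retained_per_sim": total_retained / n_sims,
        "fraction_sims_with_any": sims_with_hit / n_sims,
        "n_sims": n_sims,
        "n_sets": n_sets,
    }


# ---------------------------------------------------------------------------
# planted-effect recovery and the age-restriction pattern

def effect_recovery(
    seed: int,
    n_intersections: int = 40,
    n_planted: int = 20,
    delta: float = 2.0,
    n_genes: int = 3000,
) -> dict:
    """Recovery of planted intersection effects and the Table-style DEG pattern.

    A two-age cohort (20 per haplotype group per age) carries planted
    age-restricted set effects of +/- ``delta`` SD plus per-gene haplotype
    and sex effects; measures recall and sign accuracy of intersections
    retained at FDR 0.001 in the old cohort and the per-term DEG counts per
    cohort at FDR 0.05.
    """
    design = simulate.CohortDesign(
        n_per_cell={(g, s, a): _CARRIER_CELLS[(g, s, "12mo")]
                    for (g, s, _) in _CARRIER_CELLS for a in ("4mo", "12mo")},
        ages=("4mo", "12mo"),
        n_batches=2,
        seed=seed,
    )
    samples = simulate.simulate_cohort(design)
    kegg, bio, planted_ids = simulate.simulate_intersecting_collections(
        n_intersections, n_genes=n_genes, seed=seed + 1
    )
    inter = genesets.build_intersections(kegg, bio, 10)
    cores = {s.id: list(s.genes) for s in inter}
    truth = [
        simulate.EffectTruth(planted_ids[i], delta * (1 if i % 2 == 0 else -1),
                             age_restricted=True)
        for i in range(n_planted)
    ]
    counts = simulate.simulate_counts(
        samples, cores, truth,
        n_genes=n_genes, seed=seed + 2,
        n_sex_genes=40, sex_effect_log2=0.6,
        n_hap_genes=200, hap_effect_log2=1.0,
        old_age="12mo",
    )
    expr = normalize.normalize_counts(counts, samples, ["batch"])
    deg_counts = {}
    for cohort in ("4mo", "12mo"):
        res = factorial.fit_factorial(expr, samples, cohort=cohort)
        deg_counts[cohort] = res.count_deg(0.05).to_dict()

    expr_sexless = normalize.residualize(expr, samples, ["sex"])
    old = samples[samples["age_cohort"] == "12mo"]
    expr_old = expr_sexless.copy_with(expr_sexless.data[old.index])
    means = genesets.set_mean_matrix(expr_old, inter)
    fits = trend.HaplotypeTrendModel(means, old).fit()
    kept = trend.screen_sets(fits, 0.001)
    truth_sign = {t.set_id: np.sign(t.delta) for t in truth}
    kept_planted = [i for i in kept.index if i in truth_sign]
    correct_sign = [
        i for i in kept_planted if np.sign(kept.loc[i, "beta"]) == truth_sign[i]
    ]
    return {
        "recall": len(kept_planted) / n_planted,
        "sign_accuracy": (len(correct_sign) / len(kept_planted)) if kept_planted else float("nan"),
        "n_retained": len(kept),
        "n_planted": n_planted,
        "deg_counts": deg_counts,
    }


# ---------------------------------------------------------------------------
# dominant vs additive coding

def coding_comparison(
    seed: int,
    n_sims: int = 100,
    delta: float = 5.0,
    n_genes: int = 300,
) -> dict:
    """Fraction of simulations where the generating coding wins on adjusted R^2."""
    wins = {"dominant": 0, "additive": 0}
    null_r2 = []
    for k in range(n_sims):
        samples = carrier_cohort(seed + 7 * k)
        sets = simulate.simulate_gene_sets(n_genes, 1, set_size=15, seed=seed + 7 * k + 1)
        set_id = next(iter(sets.sets))
        for coding in ("dominant", "additive"):
            truth = [simulate.EffectTruth(set_id, delta, coding=coding)]
            counts = simulate.simulate_counts(
                samples, sets, truth, n_genes=n_genes,
                seed=seed + 7 * k + 2, include_sex_markers=False,
            )
            expr = normalize.normalize_counts(counts, samples, ["batch"])
            r2 = factorial.compare_codings(expr, samples, sets.sets[set_id])
            if r2[f"{coding}_R2"] > r2[("additive" if coding == "dominant" else "dominant") + "_R2"]:
                wins[coding] += 1
        counts0 = simulate.simulate_counts(
            samples, sets, [], n_genes=n_genes,
            seed=seed + 7 * k + 3, include_sex_markers=False,
        )
        expr0 = normalize.normalize_counts(counts0, samples, ["batch"])
        r2_0 = factorial.compare_codings(expr0, samples, sets.sets[set_id])
        null_r2.append((r2_0["dominant_R2"], r2_0["additive_R2"]))
    null_arr = np.array(null_r2)
    return {
        "dominant_win_fraction": wins["dominant"] / n_sims,
        "additive_win_fraction": wins["additive"] / n_sims,
        "null_mean_dominant_R2": float(null_arr[:, 0].mean()),
        "null_mean_additive_R2": float(null_arr[:, 1].mean()),
        "n_sims": n_sims,
    }


# ---------------------------------------------------------------------------
# Dirichlet-multinomial correctness

def dm_correctness() -> dict:
    """Deterministic checks of the DM log-likelihood implementation."""
    worst = 0.0
    for total in range(1, 7):
        for K, props in [(2, (0.3, 0.7)), (3, (0.2, 0.3, 0.5))]:
            p = np.array(props)
            s = 0.0
            for c in itertools.product(range(total + 1), repeat=K):
                if sum(c) == total:
                    s += np.exp(exon_usage.dm_loglik(np.array(c), p, 3.7))
            worst = max(worst, abs(s - 1.0))
    limit = exon_usage.dm_loglik(np.array([2.0, 1.0]), np.array([0.5, 0.5]), 1e9)
    return {
        "max_total_probability_error": worst,
        "multinomial_limit_loglik": float(limit),
        "multinomial_limit_target": float(np.log(0.375)),
    }


# ---------------------------------------------------------------------------
# DTU calibration and power

def dtu_calibration(seed: int, n_null_genes: int = 1000, depth: float = 500.0) -> dict:
    """Type-I error of the usage LRT at alpha 0.05 on null genes."""
    samples = carrier_cohort(seed)
    table = simulate.simulate_exon_counts(
        samples, [], n_genes=n_null_genes, depth=depth, seed=seed + 1
    )
    table = exon_usage.filter_features(table)
    res = exon_usage.dtu_test(table, samples)
    return {
        "type1_error": float((res["p"] <= 0.05).mean()),
        "n_genes_tested": len(res),
    }


def dtu_power(
    seed: int,
    n_planted: int = 100,
    n_null: int = 100,
    shift: float = 0.25,
    depth: float = 500.0,
) -> dict:
    """Power at the planted usage shift, adjusted p <= 0.05."""
    samples = carrier_cohort(seed)
    gene_ids = simulate.exon_gene_ids(n_planted + n_null)
    truth = [
        simulate.DtuTruth(g, 0, shift, precision=50.0) for g in gene_ids[:n_planted]
    ]
    table = simulate.simulate_exon_counts(
        samples, truth, n_genes=n_planted + n_null, depth=depth, seed=seed + 1
    )
    table = exon_usage.filter_features(table)
    res = exon_usage.dtu_test(table, samples)
    planted = res.index.isin(gene_ids[:n_planted])
    return {
        "power": float((res.loc[planted, "p_adj"] <= 0.05).mean()),
        "null_adj_sig_fraction": float((res.loc[~planted, "p_adj"] <= 0.05).mean()),
        "n_planted": n_planted,
    }


# ---------------------------------------------------------------------------
# filter exactness

def filter_exactness(seed: int, n_tables: int = 50) -> dict:
    """Agreement of the filters with brute-force reapplication of the rules."""
    rng = np.random.default_rng(seed)
    feature_ok = True
    transcript_ok = True
    for _ in range(n_tables):
        n_genes = int(rng.integers(3, 8))
        n_feat = int(rng.integers(2, 5))
        n_samp = int(rng.integers(8, 25))
        idx = pd.MultiIndex.from_tuples(
            [(f"g{i}", f"e{j}") for i in range(n_genes) for j in range(n_feat)],
            names=["gene_id", "feature_id"],
        )
        counts = rng.integers(0, 30, size=(n_genes * n_feat, n_samp))
        # sprinkle zeros to stress the expressed-in rule
        counts[rng.random(counts.shape) < 0.3] = 0
        table = pd.DataFrame(counts, index=idx, columns=[f"s{i}" for i in range(n_samp)])
        got = exon_usage.filter_features(table)
        # brute force: loop the stated rules literally
        keep_rows = []
        for row in table.index:
            vals = table.loc[row]
            if (vals > 0).sum() >= 10 and vals.mean() >= 10:
                keep_rows.append(row)
        by_gene: dict[str, list] = {}
        for g, e in keep_rows:
            by_gene.setdefault(g, []).append((g, e))
        expected = [r for g, rows in by_gene.items() if len(rows) >= 2 for r in rows]
        if sorted(got.index.tolist()) != sorted(expected):
            feature_ok = False

        mat = pd.DataFrame(
            rng.integers(0, 6, size=(20, n_samp)),
            index=[f"t{i}" for i in range(20)],
            columns=[f"s{i}" for i in range(n_samp)],
        )
        got_t = cross_system.filter_transcripts(mat, 10)
        expected_t = [r for r in mat.index if mat.loc[r].sum() >= 10]
        if got_t.index.tolist() != expected_t:
            transcript_ok = False
    return {
        "feature_filter_exact": feature_ok,
        "transcript_filter_exact": transcript_ok,
        "n_tables": n_tables,
    }


# ---------------------------------------------------------------------------
# cross-system concordance

def _one_concordance_run(seed: int, cls: str, effect_log2: float = 1.0,
                         n_sets: int = 60) -> float:
    kegg, bio, ids = simulate.simulate_intersecting_collections(
        n_sets, n_genes=2500, seed=seed
    )
    inter = genesets.build_intersections(kegg, bio, 10)
    ortho = simulate.simulate_ortholog_map(
        simulate.simulate_gene_universe(2500), seed=seed + 1
    )
    rng = np.random.default_rng(seed + 2)
    mouse_truth = {
        i: float(rng.uniform(0.5, 2.0) * rng.choice([-1.0, 1.0])) for i in ids
    }
    spec = {i: cls for i in ids}
    counts, treat = simulate.simulate_organoid(
        inter, spec, ortho, mouse_truth,
        effect_log2=effect_log2, n_background_genes=300, seed=seed + 3,
    )
    counts = cross_system.filter_transcripts(counts, 10)
    expr = normalize.vst(counts, normalize.size_factors(counts))
    omap = cross_system.OrthologMap.from_frame(ortho)
    betas = {}
    for s in inter:
        b = cross_system.treatment_effect(expr, treat, list(s.genes), omap)
        if b is not None:
            betas[s.id] = b
    rho, _, _ = cross_system.compare_effects(
        pd.Series(mouse_truth), pd.Series(betas)
    )
    return rho


def concordance_recovery(seed: int, n_null_sims: int = 100) -> dict:
    """Spearman rho under all-concordant, all-discordant and null specs."""
    rho_conc = _one_concordance_run(seed, "concordant")
    rho_disc = _one_concordance_run(seed, "discordant")
    null_rhos = [
        _one_concordance_run(seed + 101 + 13 * k, "null") for k in range(n_null_sims)
    ]
    null_abs = np.abs(null_rhos)
    return {
        "rho_concordant": float(rho_conc),
        "rho_discordant": float(rho_disc),
        "null_fraction_below_0.3": float((null_abs < 0.3).mean()),
        "n_null_sims": n_null_sims,
    }


# ---------------------------------------------------------------------------
# sex validation

def sex_validation_accuracy(seed: int, n_sims: int = 100) -> dict:
    """Fraction of simulations where planted sex swaps are flagged exactly."""
    exact = 0
    for k in range(n_sims):
        design = simulate.CohortDesign(n_per_cell=2, ages=("12mo",), seed=seed + k)
        samples = simulate.simulate_cohort(design)
        counts = simulate.simulate_counts(
            samples, {}, [], n_genes=50, seed=seed + k + 1
        )
        rng = np.random.default_rng(seed + k + 2)
        n_swaps = int(rng.integers(1, 3))
        swapped = list(rng.choice(samples.index, size=n_swaps, replace=False))
        bad = samples.copy()
        bad.loc[swapped, "sex"] = bad.loc[swapped, "sex"].map({"F": "M", "M": "F"})
        flags = normalize.validate_sex(counts, bad)
        if sorted(flags.index[~flags["passed"]]) == sorted(swapped):
            exact += 1
    return {"exact_flag_fraction": exact / n_sims, "n_sims": n_sims}
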
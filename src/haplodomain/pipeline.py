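"""End-to-end orchestration: simulate -> normalize -> deg -> sets -> assoc -> dtu -> compare.

A RunConfig (YAML-loadable) fixes every threshold and simulation parameter;
``run_pipeline`` executes the enabled stages in dependency order, writes each
stage's tables under the output directory, and returns a manifest recording
parameters, output checksums and aggregated warnings.  Outputs are pure
functions of (config, seed): rerunning an identical config reproduces
identical files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import pathlib
import warnings
from dataclasses import dataclass, field

import pandas as pd
import yaml

from . import cross_system, exon_usage, factorial, genesets, io, normalize, simulate, trend

logger = logging.getLogger(__name__)

STAGES = ("simulate", "normalize", "deg", "sets", "assoc", "dtu", "compare")


@dataclass
class RunConfig:
    """Pipeline configuration; defaults mirror the analysis thresholds."""

    seed: int = 0
    out_dir: str = "haplodomain_run"
    stages: dict = field(
        default_factory=lambda: {s: True for s in STAGES}
    )
    # thresholds
    deg_fdr: float = 0.05
    subdomain_fdr: float = 0.05
    intersection_fdr: float = 0.001
    min_intersection: int = 10
    dtu_fdr: float = 0.05
    organoid_min_total: int = 10
    # cohort
    n_per_cell: int = 5
    ages: tuple[str, ...] = ("4mo", "12mo")
    n_batches: int = 3
    # counts
    n_genes: int = 2000
    nb_dispersion: float = 0.05
    batch_sd: float = 0.15
    n_sex_genes: int = 40
    sex_effect_log2: float = 0.6
    n_hap_genes: int = 200
    hap_effect_log2: float = 1.0
    # planted set structure
    n_intersections: int = 30
    n_affected: int = 10
    genes_per_intersection: int = 15
    effect_delta: float = 2.0
    # exon usage
    n_exon_genes: int = 40
    n_dtu_genes: int = 10
    features_per_gene: int = 3
    exon_depth: float = 500.0
    dtu_shift: float = 0.25
    dtu_precision: float = 50.0
    # organoid
    n_replicates: int = 3
    organoid_effect_log2: float = 1.0
    concordant_fraction: float = 0.5

    def __post_init__(self) -> None:
        for name in ("deg_fdr", "subdomain_fdr", "intersection_fdr", "dtu_fdr"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        if self.min_intersection < 2:
            raise ValueError("min_intersection must be >= 2")
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        self.stages = {s: bool(self.stages.get(s, True)) for s in STAGES}

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(pathlib.Path(path).read_text()) or {}
        if "ages" in raw:
            raw["ages"] = tuple(raw["ages"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["ages"] = list(d["ages"])
        return d


def _sha256(path: pathlib.Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run the enabled stages and return the run manifest."""
    out = pathlib.Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": config.to_dict(),
        "stages": {},
        "warnings": [],
    }
    outputs: dict[str, pathlib.Path] = {}

    def record(stage: str, **paths: pathlib.Path) -> None:
        manifest["stages"][stage] = {
            "enabled": True,
            "outputs": {k: str(p) for k, p in paths.items()},
            "checksums": {k: _sha256(p) for k, p in paths.items()},
        }
        outputs.update(paths)

    def need(stage: str, key: str):
        if key not in outputs:
            raise RuntimeError(
                f"stage {stage!r} needs upstream output {key!r}; "
                "enable the producing stage or provide inputs"
            )

    state: dict = {}
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        _run_stages(config, out, manifest, outputs, record, need, state)
        manifest["warnings"] = sorted({str(w.message) for w in caught})

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _run_stages(config, out, manifest, outputs, record, need, state) -> None:
    old_age = config.ages[-1]

    if config.stages["simulate"]:
        design = simulate.CohortDesign(
            n_per_cell=config.n_per_cell,
            ages=tuple(config.ages),
            n_batches=config.n_batches,
            seed=config.seed,
        )
        samples = simulate.simulate_cohort(design)
        kegg, bio, planted_ids = simulate.simulate_intersecting_collections(
            config.n_intersections,
            genes_per_intersection=config.genes_per_intersection,
            n_genes=config.n_genes,
            seed=config.seed + 1,
        )
        cores = {
            s.id: list(s.genes)
            for s in genesets.build_intersections(kegg, bio, config.min_intersection)
        }
        truth = [
            simulate.EffectTruth(
                set_id=planted_ids[i],
                delta=config.effect_delta * (1 if i % 2 == 0 else -1),
                age_restricted=True,
            )
            for i in range(config.n_affected)
        ]
        counts = simulate.simulate_counts(
            samples,
            cores,
            truth,
            n_genes=config.n_genes,
            nb_dispersion=config.nb_dispersion,
            batch_sd=config.batch_sd,
            seed=config.seed + 2,
            n_sex_genes=config.n_sex_genes,
            sex_effect_log2=config.sex_effect_log2,
            n_hap_genes=config.n_hap_genes,
            hap_effect_log2=config.hap_effect_log2,
            old_age=old_age,
        )
        old_samples = samples[samples["age_cohort"] == old_age]
        exon_gene_list = simulate.exon_gene_ids(config.n_exon_genes)
        dtu_truth = [
            simulate.DtuTruth(
                gene_id=exon_gene_list[i],
                shifted_feature_index=0,
                proportion_shift=config.dtu_shift,
                precision=config.dtu_precision,
            )
            for i in range(config.n_dtu_genes)
        ]
        exons = simulate.simulate_exon_counts(
            old_samples,
            dtu_truth,
            n_genes=config.n_exon_genes,
            features_per_gene=config.features_per_gene,
            depth=config.exon_depth,
            seed=config.seed + 3,
        )
        orthologs = simulate.simulate_ortholog_map(
            simulate.simulate_gene_universe(config.n_genes), seed=config.seed + 4
        )
        n_conc = int(round(config.concordant_fraction * config.n_affected))
        concordance = {
            planted_ids[i]: ("concordant" if i < n_conc else "discordant")
            for i in range(config.n_affected)
        }
        mouse_truth = {t.set_id: t.delta for t in truth}
        org_counts, org_treatment = simulate.simulate_organoid(
            [s for s in genesets.build_intersections(kegg, bio, config.min_intersection)],
            concordance,
            orthologs,
            mouse_truth,
            n_replicates=config.n_replicates,
            effect_log2=config.organoid_effect_log2,
            seed=config.seed + 5,
        )

        paths = {
            "samples": out / "samples.tsv",
            "counts": out / "counts.tsv",
            "kegg_gmt": out / "kegg.gmt",
            "biodomains_gmt": out / "biodomains.gmt",
            "exon_counts": out / "exon_counts.tsv",
            "orthologs": out / "orthologs.tsv",
            "organoid_counts": out / "organoid_counts.tsv",
            "organoid_samples": out / "organoid_samples.tsv",
            "truth": out / "truth.tsv",
        }
        io.write_samples_tsv(samples, paths["samples"])
        io.write_counts_tsv(counts, paths["counts"])
        genesets.write_gmt(kegg, paths["kegg_gmt"])
        genesets.write_gmt(bio, paths["biodomains_gmt"])
        io.write_exon_counts_tsv(exons, paths["exon_counts"])
        orthologs.to_csv(paths["orthologs"], sep="\t", index=False)
        io.write_counts_tsv(org_counts, paths["organoid_counts"])
        org_treatment.to_frame().to_csv(paths["organoid_samples"], sep="\t", index_label="sample_id")
        pd.DataFrame([t.__dict__ for t in truth]).to_csv(paths["truth"], sep="\t", index=False)
        record("simulate", **paths)
        state.update(
            samples=samples, counts=counts, kegg=kegg, bio=bio, exons=exons,
            orthologs=orthologs, org_counts=org_counts, org_treatment=org_treatment,
            mouse_truth=mouse_truth, concordance=concordance,
        )
    else:
        manifest["stages"]["simulate"] = {"enabled": False}

    def require_state(stage: str, *keys: str):
        missing = [k for k in keys if k not in state]
        if missing:
            raise RuntimeError(
                f"stage {stage!r} is missing upstream inputs {missing}; "
                "enable the producing stage"
            )

    if config.stages["normalize"]:
        require_state("normalize", "samples", "counts")
        samples, counts = state["samples"], state["counts"]
        sex_check = normalize.validate_sex(counts, samples)
        expr = normalize.normalize_counts(counts, samples, ["batch"])
        expr_sexless = normalize.residualize(expr, samples, ["sex"])
        paths = {
            "expression": out / "expression.tsv",
            "expression_sexless": out / "expression_sex_residualized.tsv",
            "sex_validation": out / "sex_validation.tsv",
        }
        io.write_expression_tsv(expr, paths["expression"])
        io.write_expression_tsv(expr_sexless, paths["expression_sexless"])
        sex_check.to_csv(paths["sex_validation"], sep="\t")
        record("normalize", **paths)
        state.update(expr=expr, expr_sexless=expr_sexless)
    else:
        manifest["stages"]["normalize"] = {"enabled": False}

    if config.stages["deg"]:
        require_state("deg", "samples", "expr")
        samples, expr = state["samples"], state["expr"]
        summaries = []
        stats_frames = []
        cohorts = list(dict.fromkeys(samples["age_cohort"])) + [None]
        for cohort in cohorts:
            res = factorial.fit_factorial(expr, samples, cohort=cohort)
            summaries.append(res.summary(config.deg_fdr))
            stats_frames.append(res.term_stats.assign(cohort=cohort or "all"))
        paths = {
            "deg_stats": out / "deg_term_stats.tsv",
            "deg_summary": out / "deg_summary.tsv",
        }
        pd.concat(stats_frames).to_csv(paths["deg_stats"], sep="\t", index=False)
        pd.concat(summaries).to_csv(paths["deg_summary"], sep="\t")
        record("deg", **paths)
        state["deg_summary"] = pd.concat(summaries)
    else:
        manifest["stages"]["deg"] = {"enabled": False}

    if config.stages["sets"]:
        require_state("sets", "kegg", "bio")
        inter = genesets.build_intersections(
            state["kegg"], state["bio"], config.min_intersection
        )
        paths = {"intersections": out / "intersections.tsv"}
        genesets.intersection_catalog(inter).to_csv(paths["intersections"], sep="\t", index=False)
        record("sets", **paths)
        state["intersections"] = inter
    else:
        manifest["stages"]["sets"] = {"enabled": False}

    if config.stages["assoc"]:
        require_state("assoc", "intersections", "expr_sexless", "samples")
        samples = state["samples"]
        old = samples[samples["age_cohort"] == old_age]
        expr_old = state["expr_sexless"].copy_with(state["expr_sexless"].data[old.index])
        means = genesets.set_mean_matrix(expr_old, state["intersections"])
        results = trend.HaplotypeTrendModel(means, old).fit()
        screened = trend.screen_sets(results, config.intersection_fdr)
        lookup = {s.id: s for s in state["intersections"]}
        screened = screened.assign(
            pathway=[lookup[i].pathway for i in screened.index],
            domain=[lookup[i].domain for i in screened.index],
        )
        biadj = trend.biadjacency(screened.reset_index())
        paths = {
            "trend_fits": out / "intersection_trend_fits.tsv",
            "trend_screened": out / "intersection_trend_screened.tsv",
            "biadjacency": out / "biadjacency.tsv",
        }
        results.table.to_csv(paths["trend_fits"], sep="\t")
        screened.to_csv(paths["trend_screened"], sep="\t")
        biadj.to_csv(paths["biadjacency"], sep="\t", na_rep="NA")
        record("assoc", **paths)
        state["trend_results"] = results
        state["trend_screened"] = screened
    else:
        manifest["stages"]["assoc"] = {"enabled": False}

    if config.stages["dtu"]:
        require_state("dtu", "exons", "samples")
        samples = state["samples"]
        old = samples[samples["age_cohort"] == old_age]
        filtered = exon_usage.filter_features(state["exons"])
        dtu = exon_usage.dtu_test(filtered, old)
        paths = {"dtu_results": out / "dtu_results.tsv"}
        dtu.to_csv(paths["dtu_results"], sep="\t")
        record("dtu", **paths)
        state["dtu"] = dtu
    else:
        manifest["stages"]["dtu"] = {"enabled": False}

    if config.stages["compare"]:
        require_state("compare", "org_counts", "org_treatment", "orthologs", "intersections", "trend_results")
        org = cross_system.filter_transcripts(
            state["org_counts"], config.organoid_min_total
        )
        org_expr = normalize.vst(org, normalize.size_factors(org))
        omap = cross_system.OrthologMap.from_frame(state["orthologs"])
        betas = {}
        for s in state["intersections"]:
            b = cross_system.treatment_effect(
                org_expr, state["org_treatment"], list(s.genes), omap
            )
            if b is not None:
                betas[s.id] = b
        other = pd.Series(betas, name="beta_other")
        mouse = state["trend_results"].table["beta"]
        rho, p, comparison = cross_system.compare_effects(mouse, other)
        paths = {
            "comparison": out / "cross_system_comparison.tsv",
            "scatter": out / "cross_system_scatter.tsv",
        }
        comparison.to_csv(paths["comparison"], sep="\t")
        comparison[["beta_mouse", "beta_other", "concordance"]].to_csv(
            paths["scatter"], sep="\t"
        )
        record("compare", **paths)
        manifest["cross_system"] = {"spearman_rho": rho, "p": p}
        state["cross_system"] = (rho, p, comparison)
    else:
        manifest["stages"]["compare"] = {"enabled": False}
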
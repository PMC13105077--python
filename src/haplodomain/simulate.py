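"""Synthetic cohort, count, exon-count and organoid data with known truth.

The generator emulates the study design the analysis modules expect: a
two-age, two-sex cohort over five genotypes at the humanized locus (WT/WT,
WT/FC, FC/FC, WT/VS, VS/VS) with sequencing-batch structure; overdispersed
negative-binomial gene counts with set-level haplotype effects injected on
the log scale under a dominant (default) or additive coding; per-gene
Dirichlet-multinomial exon splits with planted usage shifts; and a paired
treated/untreated "organoid" dataset whose per-set effects have controlled
concordance with the mouse truth through an ortholog map.

Effect sizes (``delta``) are expressed in units of the within-group standard
deviation of the set's mean normalized expression; the generator converts
them to log2 offsets with a delta-method variance formula, so the
standardized group difference recovered downstream equals ``delta`` by
construction.  Sign convention: positive delta means higher expression in VS
carriers than FC carriers.

All draws derive from an explicit seed; identical seeds give identical
outputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import HAPLOTYPE_OF_GENOTYPE, GENOTYPES, validate_samples
from .genesets import GeneSetCollection, IntersectionSet

LN2 = np.log(2.0)

#: Sex-marker genes always present in simulated count matrices.
FEMALE_MARKER = "Xist"
MALE_MARKERS = ("Eif2s3y", "Ddx3y")


class DesignError(ValueError):
    pass


class TruthError(ValueError):
    pass


# ---------------------------------------------------------------------------
# cohort

@dataclass
class CohortDesign:
    """Factorial cohort layout: one cell per (genotype, sex, age).

    ``n_per_cell`` is either a single integer (balanced design) or a mapping
    ``(genotype, sex, age) -> count``.  ``ages`` are listed young to old; the
    last label is the "old" cohort for age-restricted effects.
    """

    n_per_cell: int | dict = 5
    genotypes: tuple[str, ...] = GENOTYPES
    ages: tuple[str, ...] = ("4mo", "12mo")
    sexes: tuple[str, ...] = ("F", "M")
    n_batches: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.genotypes or not self.ages or not self.sexes:
            raise DesignError("genotype, age and sex lists must be nonempty")
        bad = sorted(set(self.genotypes) - set(GENOTYPES))
        if bad:
            raise DesignError(f"unknown genotypes: {bad}")
        if self.n_batches < 1:
            raise DesignError("n_batches must be >= 1")
        for cell in self.cells():
            if self.cell_size(cell) < 1:
                raise DesignError(f"cell {cell} has count < 1")

    def cells(self):
        for age in self.ages:
            for sex in self.sexes:
                for genotype in self.genotypes:
                    yield (genotype, sex, age)

    def cell_size(self, cell) -> int:
        if isinstance(self.n_per_cell, dict):
            try:
                return int(self.n_per_cell[cell])
            except KeyError:
                raise DesignError(f"no count for cell {cell}") from None
        return int(self.n_per_cell)

    @property
    def n_samples(self) -> int:
        return sum(self.cell_size(c) for c in self.cells())

    def group_sizes(self) -> dict[str, int]:
        """Haplotype-group sizes implied by the design (sums of its cells)."""
        out = {"FC": 0, "WT": 0, "VS": 0}
        for cell in self.cells():
            out[HAPLOTYPE_OF_GENOTYPE[cell[0]]] += self.cell_size(cell)
        return out


def study_cohort_design(age: str = "12mo", n_batches: int = 3, seed: int = 0) -> CohortDesign:
    """A single-age design with the study's reported per-cell animal counts.

    Cell sizes follow the published cohort table (per genotype and sex, at
    four or twelve months); useful as a realistic default single-age layout.
    """
    table = {
        # genotype: (F 4mo, F 12mo, M 4mo, M 12mo)
        "WT/WT": (5, 10, 8, 9),
        "WT/FC": (5, 4, 5, 6),
        "FC/FC": (3, 4, 5, 6),
        "WT/VS": (2, 5, 2, 3),
        "VS/VS": (2, 5, 4, 6),
    }
    col = {"4mo": 0, "12mo": 1}[age]
    n_per_cell = {}
    for g, (f4, f12, m4, m12) in table.items():
        n_per_cell[(g, "F", age)] = (f4, f12)[col]
        n_per_cell[(g, "M", age)] = (m4, m12)[col]
    return CohortDesign(
        n_per_cell=n_per_cell, ages=(age,), n_batches=n_batches, seed=seed
    )


def simulate_cohort(design: CohortDesign) -> pd.DataFrame:
    """Generate the sample table for a cohort design.

    One row per sample; batches assigned round-robin within each cell.
    Deterministic given the design (the seed fixes downstream draws).
    """
    rows = []
    i = 0
    for cell in design.cells():
        genotype, sex, age = cell
        for k in range(design.cell_size(cell)):
            i += 1
            rows.append(
                {
                    "sample_id": f"S{i:04d}",
                    "genotype": genotype,
                    "sex": sex,
                    "age_cohort": age,
                    "batch": f"b{k % design.n_batches + 1}",
                }
            )
    return validate_samples(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# gene sets with planted structure

def simulate_gene_universe(n_genes: int) -> list[str]:
    return [f"G{i:05d}" for i in range(1, n_genes + 1)]


def simulate_gene_sets(
    n_genes: int,
    n_sets: int,
    set_size: int = 15,
    seed: int = 0,
    prefix: str = "SET",
    hierarchy_arity: int = 0,
) -> GeneSetCollection:
    """Random disjoint-by-chance gene sets over the simulated gene universe.

    With ``hierarchy_arity`` > 0, consecutive groups of that many sets become
    subdomains of a shared parent domain (the union of its subdomains),
    emulating a domain/subdomain annotation.
    """
    rng = np.random.default_rng(seed)
    genes = simulate_gene_universe(n_genes)
    sets: dict[str, list[str]] = {}
    for i in range(n_sets):
        members = rng.choice(n_genes, size=set_size, replace=False)
        sets[f"{prefix}{i + 1:03d}"] = [genes[j] for j in sorted(members)]
    hierarchy: dict[str, str] = {}
    if hierarchy_arity > 0:
        names = list(sets)
        for d, start in enumerate(range(0, n_sets, hierarchy_arity)):
            children = names[start : start + hierarchy_arity]
            parent = f"{prefix}_DOMAIN{d + 1:02d}"
            union: list[str] = []
            for c in children:
                union.extend(g for g in sets[c] if g not in union)
                hierarchy[c] = parent
            sets[parent] = union
    return GeneSetCollection(sets=sets, hierarchy=hierarchy, source="simulated")


def simulate_intersecting_collections(
    n_intersections: int,
    genes_per_intersection: int = 15,
    extra_per_set: int = 10,
    n_genes: int = 2000,
    seed: int = 0,
) -> tuple[GeneSetCollection, GeneSetCollection, list[str]]:
    """Pathway and domain collections whose pairwise intersections are planted.

    For each planted intersection k a core of ``genes_per_intersection``
    genes is shared between pathway P{k} and domain D{k}; each set also gets
    private padding genes so the collections are not identical.  Returns the
    two collections and the planted intersection ids ("P x D").
    """
    rng = np.random.default_rng(seed)
    genes = simulate_gene_universe(n_genes)
    need = n_intersections * (genes_per_intersection + 2 * extra_per_set)
    if need > n_genes:
        raise DesignError(f"n_genes={n_genes} too small for the requested sets ({need})")
    perm = rng.permutation(n_genes)
    kegg: dict[str, list[str]] = {}
    bio: dict[str, list[str]] = {}
    ids = []
    pos = 0
    for k in range(1, n_intersections + 1):
        core = [genes[j] for j in sorted(perm[pos : pos + genes_per_intersection])]
        pos += genes_per_intersection
        pad_p = [genes[j] for j in sorted(perm[pos : pos + extra_per_set])]
        pos += extra_per_set
        pad_d = [genes[j] for j in sorted(perm[pos : pos + extra_per_set])]
        pos += extra_per_set
        kegg[f"P{k:03d}"] = core + pad_p
        bio[f"D{k:03d}"] = core + pad_d
        ids.append(IntersectionSet(f"P{k:03d}", f"D{k:03d}", tuple(sorted(core))).id)
    return (
        GeneSetCollection(sets=kegg, source="simulated-kegg"),
        GeneSetCollection(sets=bio, source="simulated-biodomains"),
        ids,
    )


# ---------------------------------------------------------------------------
# gene counts

@dataclass
class EffectTruth:
    """Planted set-level haplotype effect.

    ``delta`` is the signed effect in units of the within-group SD of the
    set's mean normalized expression; positive means higher expression in VS
    carriers than FC carriers.  ``age_restricted`` limits the effect to the
    old cohort.  ``coding`` is 'dominant' (het and hom carriers get the full
    effect) or 'additive' (het carriers get half).
    """

    set_id: str
    delta: float
    age_restricted: bool = False
    coding: str = "dominant"

    def __post_init__(self) -> None:
        if self.coding not in ("dominant", "additive"):
            raise TruthError(f"coding must be dominant or additive, got {self.coding!r}")


def _vst_moments(mu: float, dispersion: float) -> tuple[float, float]:
    """Exact mean and variance of log2(X + 1) for X ~ NB(mu, dispersion)."""
    import scipy.stats

    r = 1.0 / dispersion
    sd = np.sqrt(mu + dispersion * mu**2)
    hi = int(np.ceil(mu + 10 * sd)) + 5
    x = np.arange(0, hi + 1)
    pmf = scipy.stats.nbinom.pmf(x, r, r / (r + mu))
    v = np.log2(x + 1.0)
    m1 = float((pmf * v).sum())
    m2 = float((pmf * v * v).sum())
    return m1, m2 - m1 * m1


def _solve_set_shift(mu: np.ndarray, dispersion: float, delta: float) -> float:
    """Log2 offset c whose symmetric application (+c/2 vs -c/2 on every set
    gene's log2 mean) gives a standardized set-mean difference of exactly
    ``delta`` under NB sampling.  Solved against the exact transformed
    moments rather than a linearization, so low-mean genes do not attenuate
    the planted effect.
    """
    import scipy.optimize

    if delta == 0.0:
        return 0.0
    m = len(mu)
    var_set = sum(_vst_moments(float(g), dispersion)[1] for g in mu) / m**2
    target = abs(delta) * np.sqrt(var_set)

    def gap(a: float) -> float:
        diff = sum(
            _vst_moments(float(g * 2**a), dispersion)[0]
            - _vst_moments(float(g * 2**-a), dispersion)[0]
            for g in mu
        ) / m
        return diff - target

    a = scipy.optimize.brentq(gap, 0.0, 4.0, xtol=1e-6)
    return float(np.sign(delta) * 2.0 * a)


def _carrier_dose(genotype: str, allele: str, coding: str) -> float:
    """Fraction of the full effect received by a genotype for one allele."""
    het, hom = f"WT/{allele}", f"{allele}/{allele}"
    if genotype == hom:
        return 1.0
    if genotype == het:
        return 1.0 if coding == "dominant" else 0.5
    return 0.0


def simulate_counts(
    samples: pd.DataFrame,
    gene_sets: GeneSetCollection | dict,
    truth: list[EffectTruth],
    n_genes: int = 2000,
    nb_dispersion: float = 0.05,
    batch_sd: float = 0.15,
    seed: int = 0,
    base_mean_range: tuple[float, float] = (20.0, 2000.0),
    n_sex_genes: int = 0,
    sex_effect_log2: float = 0.5,
    n_hap_genes: int = 0,
    hap_effect_log2: float = 1.0,
    hap_age_restricted: bool = True,
    old_age: str | None = None,
    include_sex_markers: bool = True,
) -> pd.DataFrame:
    """Negative-binomial gene counts with planted set-level haplotype effects.

    Log-scale gene means combine a per-gene baseline, per-(gene, batch)
    offsets of SD ``batch_sd``, optional per-gene sex effects, and the
    haplotype effects described by ``truth`` (half the standardized effect up
    in VS carriers, half down in FC carriers).  Age-restricted effects apply
    only to the ``old_age`` cohort (default: the last age label in appearance
    order).  Sex-marker genes with deterministic sex-dependent means are
    appended unless disabled.
    """
    sets = gene_sets.sets if isinstance(gene_sets, GeneSetCollection) else dict(gene_sets)
    for t in truth:
        if t.set_id not in sets:
            raise TruthError(f"truth references unknown set {t.set_id!r}")
    if nb_dispersion <= 0:
        raise ValueError("nb_dispersion must be positive")
    union = {g for members in sets.values() for g in members}
    if n_genes < len(union):
        raise ValueError(f"n_genes={n_genes} < union of set sizes ({len(union)})")

    rng = np.random.default_rng(seed)
    genes = simulate_gene_universe(n_genes)
    gene_index = {g: i for i, g in enumerate(genes)}
    missing = sorted(g for g in union if g not in gene_index)
    if missing:
        raise ValueError(f"set genes outside the simulated universe: {missing[:5]}")

    n_samples = len(samples)
    lo, hi = np.log(base_mean_range[0]), np.log(base_mean_range[1])
    base = rng.uniform(lo, hi, size=n_genes)
    log_mu = np.tile(base[:, None], (1, n_samples))

    # batch structure: per-(gene, batch) log offsets, drawn once per batch
    batches = samples["batch"].astype(str)
    for b in sorted(batches.unique()):
        offs = rng.normal(0.0, batch_sd, size=n_genes)
        log_mu[:, (batches == b).to_numpy()] += offs[:, None]

    # per-gene effects go to genes outside every set, so set-level truth
    # (including delta = 0 for unlisted sets) is never contaminated
    member_idx = {gene_index[g] for g in union}
    free_idx = np.array([i for i in range(n_genes) if i not in member_idx])

    # optional per-gene sex effects on randomly chosen non-set genes
    if n_sex_genes > 0:
        sex_idx = rng.choice(free_idx, size=n_sex_genes, replace=False)
        signs = rng.choice([-1.0, 1.0], size=n_sex_genes)
        is_m = (samples["sex"].astype(str) == "M").to_numpy()
        log_mu[np.ix_(sex_idx, is_m)] += (signs * sex_effect_log2 * LN2)[:, None]

    ages = samples["age_cohort"].astype(str)
    if old_age is None:
        old_age = ages.unique()[-1]
    genotype = samples["genotype"].astype(str)
    in_old = (ages == old_age).to_numpy()

    # optional per-gene haplotype effects (dominant coding), age-restricted
    if n_hap_genes > 0:
        hap_idx = rng.choice(free_idx, size=n_hap_genes, replace=False)
        signs = rng.choice([-1.0, 1.0], size=n_hap_genes)
        dose_vs = genotype.map(lambda g: _carrier_dose(g, "VS", "dominant")).to_numpy()
        dose_fc = genotype.map(lambda g: _carrier_dose(g, "FC", "dominant")).to_numpy()
        per_sample = 0.5 * hap_effect_log2 * (dose_vs - dose_fc) * LN2
        if hap_age_restricted:
            per_sample = np.where(in_old, per_sample, 0.0)
        log_mu[np.ix_(hap_idx, np.arange(n_samples))] += signs[:, None] * per_sample[None, :]

    # planted set-level haplotype effects
    for t in truth:
        members = [gene_index[g] for g in sets[t.set_id]]
        c_log2 = _solve_set_shift(np.exp(base[members]), nb_dispersion, t.delta)
        dose_vs = genotype.map(lambda g: _carrier_dose(g, "VS", t.coding)).to_numpy()
        dose_fc = genotype.map(lambda g: _carrier_dose(g, "FC", t.coding)).to_numpy()
        shift = 0.5 * c_log2 * (dose_vs - dose_fc) * LN2  # natural-log units
        if t.age_restricted:
            shift = np.where(in_old, shift, 0.0)
        log_mu[np.ix_(members, np.arange(n_samples))] += shift[None, :]

    mu = np.exp(log_mu)
    r = 1.0 / nb_dispersion
    counts = rng.negative_binomial(r, r / (r + mu))
    frame = pd.DataFrame(counts, index=genes, columns=samples.index)

    if include_sex_markers:
        is_f = (samples["sex"].astype(str) == "F").to_numpy()
        marker_rows = {}
        marker_rows[FEMALE_MARKER] = np.where(is_f, 800.0, 2.0)
        for m in MALE_MARKERS:
            marker_rows[m] = np.where(is_f, 0.5, 400.0)
        for name, mmu in marker_rows.items():
            marker_counts = rng.negative_binomial(r, r / (r + mmu))
            frame.loc[name] = marker_counts
    return frame


# ---------------------------------------------------------------------------
# exon counts

@dataclass
class DtuTruth:
    """Planted usage shift: feature ``shifted_feature_index`` of ``gene_id``
    differs in usage proportion by ``proportion_shift`` between FC and VS
    carriers (VS higher for positive shifts); ``precision`` is the DM gamma.
    """

    gene_id: str
    shifted_feature_index: int = 0
    proportion_shift: float = 0.2
    precision: float = 50.0

    def __post_init__(self) -> None:
        if self.precision <= 0:
            raise TruthError("precision must be positive")


def exon_gene_ids(n_genes: int) -> list[str]:
    return [f"EG{i:04d}" for i in range(1, n_genes + 1)]


def _shift_proportions(p: np.ndarray, j: int, shift: float) -> np.ndarray:
    """Move feature j's proportion by ``shift``, rescaling the others.

    Raises if the shifted vector leaves the simplex (never clips silently).
    """
    q = p.copy()
    new_j = p[j] + shift
    if new_j <= 0 or new_j >= 1:
        raise TruthError(
            f"proportion shift {shift:+.3f} takes feature {j} from {p[j]:.3f} "
            f"to {new_j:.3f}, off the simplex"
        )
    rest = 1.0 - p[j]
    q[j] = new_j
    scale = (1.0 - new_j) / rest
    for k in range(len(p)):
        if k != j:
            q[k] = p[k] * scale
    if (q <= 0).any():
        raise TruthError("proportion shift produced a non-positive proportion")
    return q


def simulate_exon_counts(
    samples: pd.DataFrame,
    dtu_truth: list[DtuTruth],
    n_genes: int = 50,
    features_per_gene: int = 3,
    depth: float = 500.0,
    seed: int = 0,
    default_gamma: float = 50.0,
) -> pd.DataFrame:
    """Dirichlet-multinomial exon-count blocks with planted usage shifts.

    Per gene and sample the total is Poisson(``depth``); the split across
    features is DM with group-specific proportions for truth genes (FC gets
    -shift/2 on the target feature, VS gets +shift/2, everyone else the base
    proportions).  ``precision`` = inf draws exact multinomials.
    """
    if features_per_gene < 2 and dtu_truth:
        raise DesignError("features_per_gene must be >= 2 for genes with DTU truth")
    rng = np.random.default_rng(seed)
    gene_ids = exon_gene_ids(n_genes)
    truth_by_gene = {t.gene_id: t for t in dtu_truth}
    unknown = sorted(set(truth_by_gene) - set(gene_ids))
    if unknown:
        raise TruthError(f"DTU truth references unknown genes: {unknown}")

    hap = samples["haplotype_group"].astype(str).to_numpy()
    n_samples = len(samples)
    rows = []
    index = []
    for gid in gene_ids:
        K = features_per_gene
        base = rng.dirichlet(np.full(K, 5.0))
        t = truth_by_gene.get(gid)
        if t is not None:
            if t.shifted_feature_index >= K:
                raise TruthError(f"gene {gid}: shifted feature index out of range")
            half = abs(t.proportion_shift) / 2
            if half >= 0.5:
                raise TruthError(
                    f"gene {gid}: |proportion_shift| {t.proportion_shift:+.3f} cannot "
                    "fit on the simplex for any base proportions"
                )
            # truth genes need headroom on the shifted feature in both
            # directions; redraw the base split until the shift is feasible
            margin = 0.02
            for _ in range(1000):
                j = t.shifted_feature_index
                if half + margin < base[j] < 1.0 - half - margin:
                    break
                base = rng.dirichlet(np.full(K, 5.0))
            else:
                raise TruthError(f"gene {gid}: no feasible base proportions found")
            p_fc = _shift_proportions(base, t.shifted_feature_index, -t.proportion_shift / 2)
            p_vs = _shift_proportions(base, t.shifted_feature_index, +t.proportion_shift / 2)
            gamma = t.precision
        else:
            p_fc = p_vs = base
            gamma = default_gamma
        totals = rng.poisson(depth, size=n_samples)
        block = np.zeros((K, n_samples), dtype=int)
        for i in range(n_samples):
            p = p_vs if hap[i] == "VS" else (p_fc if hap[i] == "FC" else base)
            if np.isfinite(gamma):
                p = rng.dirichlet(gamma * p)
            block[:, i] = rng.multinomial(totals[i], p)
        for k in range(K):
            rows.append(block[k])
            index.append((gid, f"E{k + 1:02d}"))
    table = pd.DataFrame(
        np.vstack(rows),
        index=pd.MultiIndex.from_tuples(index, names=["gene_id", "feature_id"]),
        columns=samples.index,
    )
    return table


# ---------------------------------------------------------------------------
# organoid comparison data

def simulate_ortholog_map(
    genes: list[str],
    seed: int = 0,
    frac_mapped: float = 0.95,
    prefix: str = "HS_",
) -> pd.DataFrame:
    """One-to-one mouse -> human id pairs covering a fraction of the genes."""
    rng = np.random.default_rng(seed)
    keep = rng.random(len(genes)) < frac_mapped
    mouse = [g for g, k in zip(genes, keep) if k]
    return pd.DataFrame(
        {
            "mouse_id": mouse,
            "human_id": [prefix + g for g in mouse],
            "homology_type": "ortholog_one2one",
        }
    )


def simulate_organoid(
    intersections: list[IntersectionSet] | GeneSetCollection,
    concordance_spec: dict[str, str],
    ortholog_map: pd.DataFrame,
    mouse_truth: dict[str, float],
    n_replicates: int = 3,
    effect_log2: float = 1.0,
    nb_dispersion: float = 0.05,
    base_mean_range: tuple[float, float] = (50.0, 2000.0),
    n_background_genes: int = 500,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Treated/untreated count matrix with controlled per-set concordance.

    For each intersection set, treated-group expression of its mapped genes
    shifts by ``effect_log2`` scaled by the mouse truth effect for that set,
    with a sign matching (concordant), opposing (discordant) or absent
    (null) relative to the mouse direction — so set-level rank agreement
    grows with effect size.  Three replicates per group by default.  Sets
    with no mapped orthologs are skipped with a warning.
    """
    if isinstance(intersections, GeneSetCollection):
        items = [(name, genes) for name, genes in intersections.sets.items()]
    else:
        items = [(s.id, list(s.genes)) for s in intersections]
    ids = {name for name, _ in items}
    bad = sorted(set(concordance_spec) - ids)
    if bad:
        raise TruthError(f"concordance spec references unknown sets: {bad}")
    for name, cls in concordance_spec.items():
        if cls not in ("concordant", "discordant", "null"):
            raise TruthError(f"unknown concordance class {cls!r} for {name!r}")

    to_human = dict(zip(ortholog_map.iloc[:, 0], ortholog_map.iloc[:, 1]))
    rng = np.random.default_rng(seed)

    gene_effect: dict[str, float] = {}
    human_genes: list[str] = []
    for name, genes in items:
        mapped = [to_human[g] for g in genes if g in to_human]
        if not mapped:
            warnings.warn(f"set {name!r} has no mapped orthologs; skipped", stacklevel=2)
            continue
        cls = concordance_spec.get(name, "null")
        mouse_delta = mouse_truth.get(name, 0.0)
        if cls == "concordant":
            eff = effect_log2 * mouse_delta
        elif cls == "discordant":
            eff = -effect_log2 * mouse_delta
        else:
            eff = 0.0
        for h in mapped:
            if h not in gene_effect:
                gene_effect[h] = eff
                human_genes.append(h)

    # unaffected background genes anchor the size-factor normalization
    for i in range(n_background_genes):
        h = f"HS_BG{i + 1:05d}"
        gene_effect[h] = 0.0
        human_genes.append(h)

    n_per_group = n_replicates
    sample_ids = [f"org_t{i+1}" for i in range(n_per_group)] + [
        f"org_u{i+1}" for i in range(n_per_group)
    ]
    treatment = pd.Series(
        ["treated"] * n_per_group + ["untreated"] * n_per_group,
        index=sample_ids,
        name="treatment",
    )
    lo, hi = np.log(base_mean_range[0]), np.log(base_mean_range[1])
    base = rng.uniform(lo, hi, size=len(human_genes))
    eff = np.array([gene_effect[h] for h in human_genes])
    treated = (treatment == "treated").to_numpy()
    log_mu = np.tile(base[:, None], (1, len(sample_ids)))
    log_mu[:, treated] += (eff * LN2)[:, None]
    mu = np.exp(log_mu)
    r = 1.0 / nb_dispersion
    counts = rng.negative_binomial(r, r / (r + mu))
    return pd.DataFrame(counts, index=human_genes, columns=sample_ids), treatment
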
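"""Generator contracts: determinism, design arithmetic, effect injection."""

import numpy as np
import pandas as pd
import pytest

from haplodomain import (
    CohortDesign,
    DtuTruth,
    EffectTruth,
    simulate_cohort,
    simulate_counts,
    simulate_exon_counts,
    simulate_organoid,
    study_cohort_design,
)
from haplodomain.containers import HAPLOTYPE_OF_GENOTYPE
from haplodomain.genesets import GeneSetCollection, build_intersections, set_mean_expression
from haplodomain.normalize import size_factors, vst
from haplodomain.simulate import (
    DesignError,
    TruthError,
    exon_gene_ids,
    simulate_gene_sets,
    simulate_gene_universe,
    simulate_intersecting_collections,
    simulate_ortholog_map,
)


class TestCohort:
    def test_sample_count_is_product_of_cells(self):
        design = CohortDesign(n_per_cell=1)
        assert len(simulate_cohort(design)) == 5 * 2 * 2  # genotypes x sexes x ages

    def test_same_seed_gives_identical_tables(self):
        a = simulate_cohort(CohortDesign(n_per_cell=3, seed=5))
        b = simulate_cohort(CohortDesign(n_per_cell=3, seed=5))
        assert a.to_csv() == b.to_csv()

    def test_group_sizes_equal_cell_sums(self):
        # direct-summation oracle over the single-age study-style design
        design = study_cohort_design("12mo")
        expected = {"FC": 0, "WT": 0, "VS": 0}
        for (genotype, _, _), n in design.n_per_cell.items():
            expected[HAPLOTYPE_OF_GENOTYPE[genotype]] += n
        samples = simulate_cohort(design)
        observed = samples["haplotype_group"].value_counts().to_dict()
        assert observed == expected
        assert design.group_sizes() == expected

    def test_batches_assigned_round_robin_within_cells(self):
        design = CohortDesign(n_per_cell=5, n_batches=3, ages=("12mo",))
        samples = simulate_cohort(design)
        cell = samples[(samples.genotype == "WT/WT") & (samples.sex == "F")]
        assert cell["batch"].tolist() == ["b1", "b2", "b3", "b1", "b2"]

    @pytest.mark.parametrize("field", ["genotypes", "ages", "sexes"])
    def test_empty_factor_list_rejected(self, field):
        with pytest.raises(DesignError):
            CohortDesign(**{field: ()})

    def test_haplotype_group_derivation(self):
        samples = simulate_cohort(CohortDesign(n_per_cell=1))
        derived = samples["genotype"].map(HAPLOTYPE_OF_GENOTYPE)
        assert (samples["haplotype_group"] == derived).all()


class TestCounts:
    def test_unknown_truth_set_rejected(self, small_cohort):
        with pytest.raises(TruthError):
            simulate_counts(small_cohort, {"s1": ["G00001"]},
                            [EffectTruth("nope", 1.0)], n_genes=50)

    def test_nonpositive_dispersion_rejected(self, small_cohort):
        with pytest.raises(ValueError):
            simulate_counts(small_cohort, {}, [], n_genes=50, nb_dispersion=0.0)

    def test_same_seed_gives_identical_counts(self, small_cohort):
        a = simulate_counts(small_cohort, {}, [], n_genes=100, seed=3)
        b = simulate_counts(small_cohort, {}, [], n_genes=100, seed=3)
        pd.testing.assert_frame_equal(a, b)

    def test_null_truth_group_means_differ_only_by_noise(self, carriers):
        counts = simulate_counts(carriers, {}, [], n_genes=400, seed=9,
                                 batch_sd=0.0, include_sex_markers=False)
        expr = vst(counts, size_factors(counts)).data
        groups = carriers["haplotype_group"]
        diff = expr.loc[:, (groups == "VS").to_numpy()].mean(axis=1) - \
            expr.loc[:, (groups == "FC").to_numpy()].mean(axis=1)
        # standardized per-gene differences should center on zero
        assert abs(diff.mean()) < 0.02

    def test_planted_delta_recovered_and_age_restricted(self, rng):
        """Standardized set-mean difference matches delta in the old cohort
        and is ~0 in the young cohort (generator's own mean formula)."""
        design = CohortDesign(n_per_cell=5, n_batches=1, seed=2)
        samples = simulate_cohort(design)
        sets = simulate_gene_sets(400, 1, set_size=15, seed=4)
        sid = next(iter(sets.sets))
        truth = [EffectTruth(sid, delta=1.0, age_restricted=True)]
        rec_old, rec_young = [], []
        for k in range(50):
            counts = simulate_counts(samples, sets, truth, n_genes=400,
                                     batch_sd=0.0, seed=100 + k,
                                     include_sex_markers=False)
            expr = vst(counts, size_factors(counts)).data
            m = set_mean_expression(expr, sets.sets[sid])
            for age, sink in [("12mo", rec_old), ("4mo", rec_young)]:
                sub = samples[samples.age_cohort == age]
                g = sub["haplotype_group"]
                mm = m[sub.index]
                d = mm[(g == "VS").to_numpy()].mean() - mm[(g == "FC").to_numpy()].mean()
                sd = np.sqrt(np.mean([mm[(g == lev).to_numpy()].var(ddof=1)
                                      for lev in ("FC", "WT", "VS")]))
                sink.append(d / sd)
        se_old = np.std(rec_old, ddof=1) / np.sqrt(len(rec_old))
        se_young = np.std(rec_young, ddof=1) / np.sqrt(len(rec_young))
        assert abs(np.mean(rec_old) - 1.0) < 3 * se_old
        assert abs(np.mean(rec_young)) < 3 * se_young

    def test_additive_coding_gives_heterozygotes_half_effect(self, carriers):
        deltas = {"WT/FC": [], "FC/FC": []}
        sets = simulate_gene_sets(300, 1, set_size=20, seed=4)
        sid = next(iter(sets.sets))
        for k in range(30):
            counts = simulate_counts(
                carriers, sets, [EffectTruth(sid, 4.0, coding="additive")],
                n_genes=300, batch_sd=0.0, seed=500 + k, include_sex_markers=False)
            expr = vst(counts, size_factors(counts)).data
            m = set_mean_expression(expr, sets.sets[sid])
            wt = m[(carriers.genotype == "WT/WT").to_numpy()].mean()
            for gt in deltas:
                deltas[gt].append(m[(carriers.genotype == gt).to_numpy()].mean() - wt)
        ratio = np.mean(deltas["WT/FC"]) / np.mean(deltas["FC/FC"])
        assert ratio == pytest.approx(0.5, abs=0.15)

    def test_sex_markers_present_with_sex_dependent_expression(self, small_cohort):
        counts = simulate_counts(small_cohort, {}, [], n_genes=50, seed=1)
        for marker in ("Xist", "Eif2s3y", "Ddx3y"):
            assert marker in counts.index
        is_f = (small_cohort.sex == "F").to_numpy()
        assert counts.loc["Xist"].to_numpy()[is_f].mean() > \
            counts.loc["Xist"].to_numpy()[~is_f].mean()
        assert counts.loc["Ddx3y"].to_numpy()[~is_f].mean() > \
            counts.loc["Ddx3y"].to_numpy()[is_f].mean()


class TestExonCounts:
    def test_same_seed_gives_identical_tables(self, carriers):
        a = simulate_exon_counts(carriers, [], n_genes=5, seed=3)
        b = simulate_exon_counts(carriers, [], n_genes=5, seed=3)
        pd.testing.assert_frame_equal(a, b)

    def test_planted_shift_recovered_in_usage_proportions(self, carriers):
        truth = [DtuTruth(g, 0, 0.2, precision=200.0) for g in exon_gene_ids(10)]
        table = simulate_exon_counts(carriers, truth, n_genes=10, depth=500, seed=5)
        diffs = []
        g = carriers["haplotype_group"]
        for gid in exon_gene_ids(10):
            block = table.loc[gid]
            usage = block / block.sum(axis=0)
            first = usage.iloc[0]
            diffs.append(first[(g == "VS").to_numpy()].mean()
                         - first[(g == "FC").to_numpy()].mean())
        assert np.mean(diffs) == pytest.approx(0.2, abs=0.03)

    def test_infeasible_shift_rejected_not_clipped(self, carriers):
        with pytest.raises(TruthError):
            simulate_exon_counts(
                carriers, [DtuTruth("EG0001", 0, 1.2)], n_genes=2, seed=1)

    def test_dm_variance_exceeds_multinomial_and_converges(self, carriers):
        """Finite gamma inflates feature-count variance; gamma -> inf
        approaches the multinomial variance."""
        var = {}
        for gamma in (5.0, np.inf):
            reps = []
            for k in range(30):
                t = simulate_exon_counts(
                    carriers.iloc[:5], [], n_genes=1, features_per_gene=2,
                    depth=1000, seed=200 + k, default_gamma=gamma)
                reps.extend(t.iloc[0].tolist())
            reps = np.asarray(reps, dtype=float)
            var[gamma] = reps.var(ddof=1)
        # multinomial variance with p ~ first-feature proportion, n = 1000
        assert var[5.0] > 2 * var[np.inf]


@pytest.fixture(scope="module")
def parts():
    kegg, bio, ids = simulate_intersecting_collections(6, n_genes=500, seed=8)
    inter = build_intersections(kegg, bio, 10)
    ortho = simulate_ortholog_map(simulate_gene_universe(500), seed=9)
    mouse = {i: 1.0 for i in ids}
    return inter, ortho, mouse, ids


class TestOrganoid:

    def test_default_three_replicates_per_group(self, parts):
        inter, ortho, mouse, ids = parts
        counts, treatment = simulate_organoid(inter, {}, ortho, mouse, seed=1)
        assert treatment.value_counts().to_dict() == {"treated": 3, "untreated": 3}

    def test_unknown_set_in_spec_rejected(self, parts):
        inter, ortho, mouse, ids = parts
        with pytest.raises(TruthError):
            simulate_organoid(inter, {"missing": "concordant"}, ortho, mouse, seed=1)

    def test_unmapped_set_skipped_with_warning(self, parts):
        inter, _, mouse, ids = parts
        empty_map = pd.DataFrame({"mouse_id": [], "human_id": []})
        with pytest.warns(UserWarning, match="no mapped orthologs"):
            counts, _ = simulate_organoid(inter, {}, empty_map, mouse,
                                          n_background_genes=10, seed=1)
        assert len(counts) == 10  # background only

    def test_same_seed_gives_identical_output(self, parts):
        inter, ortho, mouse, ids = parts
        spec = {ids[0]: "concordant"}
        a, _ = simulate_organoid(inter, spec, ortho, mouse, seed=4)
        b, _ = simulate_organoid(inter, spec, ortho, mouse, seed=4)
        pd.testing.assert_frame_equal(a, b)


class TestGeneSetHelpers:
    def test_intersecting_collections_have_planted_cores(self):
        kegg, bio, ids = simulate_intersecting_collections(5, n_genes=400, seed=3)
        inter = build_intersections(kegg, bio, 10)
        assert [s.id for s in inter] == ids

    def test_hierarchical_sets_have_valid_parents(self):
        coll = simulate_gene_sets(300, 8, seed=2, hierarchy_arity=4)
        assert len(coll.subdomains) == 8
        for sub, parent in coll.hierarchy.items():
            assert set(coll.sets[sub]) <= set(coll.sets[parent])
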
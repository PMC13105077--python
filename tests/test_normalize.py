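"""Normalization chain: size factors, vst, residualization, sex validation."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from haplodomain import simulate_cohort, simulate_counts, CohortDesign
from haplodomain.containers import ExpressionMatrix, SampleTableError, validate_samples
from haplodomain.normalize import (
    SexMarkerSpec,
    residualize,
    size_factors,
    validate_sex,
    vst,
)


def _toy_counts(values, samples=("s1", "s2", "s3")):
    return pd.DataFrame(values, index=[f"g{i}" for i in range(len(values))],
                        columns=samples)


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self):
        counts = _toy_counts([[5, 5, 5], [9, 9, 9], [2, 2, 2]])
        np.testing.assert_allclose(size_factors(counts), 1.0)

    def test_doubled_column_gets_double_factor(self):
        counts = _toy_counts([[10, 10, 20], [4, 4, 8], [7, 7, 14]])
        f = size_factors(counts)
        assert f["s3"] / f["s1"] == pytest.approx(2.0)
        assert f["s1"] == pytest.approx(f["s2"])

    def test_matches_median_of_ratios_oracle(self):
        # brute-force oracle: per-gene geometric means, per-sample ratio
        # medians (odd gene count, so the median is an actual ratio and the
        # log/linear median conventions coincide)
        values = [[10, 20, 30], [20, 10, 40], [5, 5, 5], [100, 50, 25], [8, 16, 8]]
        counts = _toy_counts(values)
        arr = np.array(values, dtype=float)
        ref = np.exp(np.log(arr).mean(axis=1))
        medians = np.median(arr / ref[:, None], axis=0)
        expected = medians / np.exp(np.log(medians).mean())
        np.testing.assert_allclose(size_factors(counts), expected, rtol=1e-12)

    def test_geometric_mean_of_factors_is_one(self, rng):
        counts = pd.DataFrame(rng.integers(1, 1000, size=(50, 8)),
                              columns=[f"s{i}" for i in range(8)])
        f = size_factors(counts)
        assert np.exp(np.log(f).mean()) == pytest.approx(1.0)

    def test_invariant_to_gene_and_sample_order(self, rng):
        counts = pd.DataFrame(rng.integers(0, 500, size=(40, 6)),
                              index=[f"g{i}" for i in range(40)],
                              columns=[f"s{i}" for i in range(6)])
        counts.iloc[0] += 1  # ensure at least one all-nonzero gene
        f = size_factors(counts)
        shuffled = counts.sample(frac=1, axis=0, random_state=1).sample(
            frac=1, axis=1, random_state=2)
        f2 = size_factors(shuffled)
        pd.testing.assert_series_equal(f.sort_index(), f2.sort_index())

    def test_fallback_when_no_gene_covers_all_samples(self, caplog):
        counts = _toy_counts([[0, 5, 5], [5, 0, 5], [5, 5, 0], [3, 4, 0]])
        with caplog.at_level("WARNING"):
            f = size_factors(counts)
        assert "falling back" in caplog.text
        assert (f > 0).all()

    def test_dead_sample_rejected(self):
        counts = _toy_counts([[1, 2, 0], [3, 4, 0]])
        with pytest.raises(ValueError, match="no nonzero count"):
            size_factors(counts)


class TestVst:
    def test_all_zero_gene_maps_to_log2_pseudocount(self):
        counts = _toy_counts([[0, 0, 0], [4, 4, 4]])
        expr = vst(counts, pd.Series(1.0, index=counts.columns))
        np.testing.assert_allclose(expr.data.loc["g0"], 0.0)

    def test_strictly_increasing_in_counts(self):
        counts = _toy_counts([[1, 10, 100]])
        expr = vst(counts, pd.Series(1.0, index=counts.columns))
        row = expr.data.iloc[0].to_numpy()
        assert (np.diff(row) > 0).all()

    def test_negative_counts_rejected(self):
        counts = _toy_counts([[1, -2, 3]])
        with pytest.raises(ValueError):
            vst(counts, pd.Series(1.0, index=counts.columns))

    def test_reduces_mean_sd_dependence_on_nb_data(self, rng):
        mu = np.exp(rng.uniform(np.log(20), np.log(2000), size=400))
        phi = 0.05
        r = 1 / phi
        raw = rng.negative_binomial(r, r / (r + mu[:, None]), size=(400, 30))
        counts = pd.DataFrame(raw, columns=[f"s{i}" for i in range(30)])
        before = scipy.stats.spearmanr(raw.mean(axis=1), raw.std(axis=1)).statistic
        expr = vst(counts, size_factors(counts)).data.to_numpy()
        after = scipy.stats.spearmanr(expr.mean(axis=1), expr.std(axis=1)).statistic
        # variance must no longer increase systematically with the mean
        assert after < before
        assert after < 0.3

    def test_scaling_a_sample_leaves_transform_unchanged_in_large_count_limit(self):
        counts = _toy_counts([[1000, 2000, 1500], [4000, 8000, 6000],
                              [2000, 4000, 3000]])
        f = size_factors(counts)
        scaled = counts.copy()
        scaled["s1"] *= 4
        f2 = size_factors(scaled)
        # scaling multiplies the sample's factor by 4 relative to the others
        assert (f2["s1"] / f2["s2"]) / (f["s1"] / f["s2"]) == pytest.approx(4.0, rel=1e-9)
        # transformed values change only by the global recentering constant
        a = vst(counts, f).data
        b = vst(scaled, f2).data
        diff = (b - a).to_numpy()
        assert diff.max() - diff.min() < 5e-3


@pytest.fixture(scope="module")
def cohort():
    return simulate_cohort(CohortDesign(n_per_cell=3, n_batches=3, seed=5))


class TestResidualize:

    def test_orthogonal_covariate_leaves_gene_unchanged(self, cohort):
        # expression orthogonal to batch indicators by construction
        batches = cohort["batch"]
        y = pd.Series(0.0, index=cohort.index)
        for b in batches.unique():
            idx = cohort.index[batches == b]
            vals = np.linspace(-1, 1, len(idx))
            y[idx] = vals - vals.mean()
        expr = ExpressionMatrix(pd.DataFrame([y], index=["g"]))
        out = residualize(expr, cohort, ["batch"])
        np.testing.assert_allclose(out.data.loc["g"], y, atol=1e-10)

    def test_pure_batch_offset_removed_exactly(self, cohort):
        offsets = {b: i * 2.5 for i, b in enumerate(sorted(cohort["batch"].unique()))}
        y = cohort["batch"].map(offsets).astype(float)
        expr = ExpressionMatrix(pd.DataFrame([y], index=["g"]))
        out = residualize(expr, cohort, ["batch"])
        np.testing.assert_allclose(out.data.loc["g"], y.mean(), atol=1e-10)

    def test_idempotent(self, cohort, rng):
        data = pd.DataFrame(rng.normal(size=(20, len(cohort))),
                            columns=cohort.index)
        once = residualize(ExpressionMatrix(data), cohort, ["batch", "sex"])
        twice = residualize(once, cohort, ["batch", "sex"])
        assert np.abs(once.data - twice.data).to_numpy().max() < 1e-10

    def test_single_level_covariate_named_in_error(self, cohort):
        one_batch = cohort.copy()
        one_batch["batch"] = "b1"
        expr = ExpressionMatrix(
            pd.DataFrame(np.zeros((2, len(cohort))), columns=cohort.index))
        with pytest.raises(ValueError, match="batch"):
            residualize(expr, one_batch, ["batch"])

    def test_batch_association_removed_completely(self):
        """With batch_sd = 0.5, residualization leaves no linear batch
        association: per-gene batch F statistics collapse to zero and the
        fitted batch-indicator slopes are below 1e-8."""
        samples = simulate_cohort(CohortDesign(n_per_cell=4, n_batches=3, seed=8))
        counts = simulate_counts(samples, {}, [], n_genes=600, batch_sd=0.5,
                                 seed=9, include_sex_markers=False)
        expr = vst(counts, size_factors(counts))
        before = expr.data.to_numpy()
        out = residualize(expr, samples, ["batch"]).data.to_numpy()
        batches = samples["batch"].to_numpy()
        levels = np.unique(batches)
        f_before = np.array([
            scipy.stats.f_oneway(*[before[i, batches == b] for b in levels]).statistic
            for i in range(before.shape[0])
        ])
        f_after = np.array([
            scipy.stats.f_oneway(*[out[i, batches == b] for b in levels]).statistic
            for i in range(out.shape[0])
        ])
        assert np.median(f_before) > 10  # injected batch structure was real
        assert f_after.max() < 1e-10
        # fitted indicator slopes on the residuals vanish
        for b in levels[1:]:
            x = (batches == b).astype(float)
            xc = x - x.mean()
            slopes = out @ xc / (xc @ xc)
            assert np.abs(slopes).max() < 1e-8

    def test_provenance_records_covariates(self, cohort, rng):
        data = pd.DataFrame(rng.normal(size=(3, len(cohort))), columns=cohort.index)
        out = residualize(ExpressionMatrix(data), cohort, ["batch"])
        out = residualize(out, cohort, ["sex"])
        assert out.residualized == ["batch", "sex"]


@pytest.fixture(scope="module")
def cohort_counts():
    samples = simulate_cohort(CohortDesign(n_per_cell=3, seed=21))
    counts = simulate_counts(samples, {}, [], n_genes=60, seed=22)
    return samples, counts


class TestValidateSex:

    def test_consistent_annotations_all_pass(self, cohort_counts):
        samples, counts = cohort_counts
        flags = validate_sex(counts, samples)
        assert flags["passed"].all()

    def test_swapped_sample_is_flagged_exactly(self, cohort_counts):
        samples, counts = cohort_counts
        bad = samples.copy()
        victim = bad.index[4]
        bad.loc[victim, "sex"] = "M" if bad.loc[victim, "sex"] == "F" else "F"
        flags = validate_sex(counts, bad)
        assert flags.index[~flags["passed"]].tolist() == [victim]

    def test_missing_marker_gene_reported(self, cohort_counts):
        samples, counts = cohort_counts
        spec = SexMarkerSpec(female=("NotAGene",))
        with pytest.raises(KeyError, match="NotAGene"):
            validate_sex(counts, samples, spec)

    def test_ensembl_ids_resolve_when_present(self, cohort_counts):
        samples, counts = cohort_counts
        renamed = counts.rename(index={
            "Xist": "ENSMUSG00000086503",
            "Eif2s3y": "ENSMUSG00000069049",
            "Ddx3y": "ENSMUSG00000069045",
        })
        flags = validate_sex(renamed, samples)
        assert flags["passed"].all()


class TestSampleValidation:
    def test_duplicate_ids_rejected(self):
        df = pd.DataFrame({
            "sample_id": ["a", "a"], "genotype": ["WT/WT", "WT/WT"],
            "sex": ["F", "M"], "age_cohort": ["4mo", "4mo"], "batch": ["b1", "b1"],
        })
        with pytest.raises(SampleTableError, match="duplicate"):
            validate_samples(df)

    def test_inconsistent_haplotype_group_rejected(self):
        df = pd.DataFrame({
            "sample_id": ["a"], "genotype": ["WT/FC"], "haplotype_group": ["VS"],
            "sex": ["F"], "age_cohort": ["4mo"], "batch": ["b1"],
        })
        with pytest.raises(SampleTableError, match="inconsistent"):
            validate_samples(df)
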
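"""Cohort tables, variance decomposition, sphere census, exponential fit."""

import numpy as np
import pytest
import scipy.stats

from seqorder import (
    BaseComposition,
    cohort_table,
    fit_shifted_exponential,
    insphere_test,
    s_h_correlation,
    sphere_census,
    variance_decomposition,
)
from seqorder.cohort import GC_CORRECTIONS, PLASMID_IDS
from seqorder.synthetic import CohortSpec, generate_cohort


def comp_cohort(members):
    return cohort_table([(m.id, m.composition) for m in members])


class TestCohortTable:
    def test_sequence_records(self):
        table = cohort_table([("g1", "GGCC"), ("g2", "ACGTACGT")])
        assert table.loc["g1", "gc"] == pytest.approx(1.0)
        assert table.loc["g2", "s"] == pytest.approx(0.25)
        assert bool(table.loc["g2", "inside"]) is True
        assert table.loc["g2", "length"] == 8

    def test_uniform_toy_records(self):
        table = cohort_table(
            [("u1", BaseComposition.uniform()), ("u2", BaseComposition.uniform())]
        )
        assert (table["s"] == 0.25).all()
        assert table["inside"].all()

    def test_duplicate_id_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            cohort_table([("g1", "ACGT"), ("g1", "GGCC")])

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            cohort_table([])


class TestVarianceDecomposition:
    def test_pure_z_variation(self):
        pts = [(0.0, 0.0, z) for z in np.linspace(-0.4, 0.4, 9)]
        dec = variance_decomposition(np.array(pts))
        assert dec.fractions_by_coordinate == pytest.approx((0, 0, 1), abs=1e-12)
        assert dec.pca_eigenfractions[0] == pytest.approx(1.0, abs=1e-9)

    def test_exact_pr2_cohort_puts_all_variance_on_z(self):
        members = generate_cohort(
            CohortSpec(n=50, gc_low=0.3, gc_high=0.7, skew_scale=0.0, seed=11)
        )
        table = comp_cohort(members)
        assert np.allclose(table[["x", "y"]], 0.0)
        dec = variance_decomposition(table)
        assert dec.fractions_by_coordinate[2] == pytest.approx(1.0)

    def test_isotropic_cloud_splits_evenly(self):
        rng = np.random.default_rng(5)
        pts = rng.normal(0.0, 0.1, size=(10_000, 3))
        dec = variance_decomposition(pts)
        for frac in dec.fractions_by_coordinate:
            assert frac == pytest.approx(1 / 3, abs=0.02)
        assert sum(dec.fractions_by_coordinate) == pytest.approx(1.0, abs=1e-9)
        assert sum(dec.pca_eigenfractions) == pytest.approx(1.0, abs=1e-9)

    def test_leading_eigenfraction_dominates_coordinate_fractions(self):
        rng = np.random.default_rng(6)
        # correlated cloud: PCA must concentrate more than any single axis
        base = rng.normal(size=(500, 1))
        pts = np.hstack([base, base, rng.normal(size=(500, 1))]) * 0.05
        dec = variance_decomposition(pts)
        assert dec.pca_eigenfractions[0] >= max(dec.fractions_by_coordinate) - 1e-12
        assert list(dec.pca_eigenfractions) == sorted(
            dec.pca_eigenfractions, reverse=True
        )

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            variance_decomposition(np.zeros((2, 3)))
        with pytest.raises(ValueError):
            variance_decomposition(np.zeros((10, 3)))


class TestSphereCensus:
    def test_single_outside_record(self):
        table = cohort_table([("bad", BaseComposition(0.5, 0.5, 0, 0))])
        census = sphere_census(table)
        assert census.n_outside == 1
        assert census.outside_fraction == 1.0

    def test_all_uniform_inside(self):
        table = cohort_table(
            [(f"u{i}", BaseComposition.uniform()) for i in range(5)]
        )
        assert sphere_census(table).n_outside == 0

    def test_wrong_radius_never_decreases_outside_count(self):
        members = generate_cohort(
            CohortSpec(n=100, gc_low=0.25, gc_high=0.75, skew_scale=0.005, seed=3)
        )
        table = comp_cohort(members)
        correct = sphere_census(table, radius_override=1 / 3)
        wrong = sphere_census(table, radius_override=1 / 4)
        assert wrong.n_outside >= correct.n_outside

    def test_census_agrees_with_insphere_test_per_record(self):
        members = generate_cohort(
            CohortSpec(n=40, gc_low=0.25, gc_high=0.75, skew_scale=0.02, seed=8)
        )
        table = comp_cohort(members)
        census = sphere_census(table)
        verdicts = [insphere_test(m.composition).inside for m in members]
        assert census.n_inside == sum(verdicts)
        assert (table["inside"] == np.array(verdicts)).all()

    def test_invalid_radius_rejected(self):
        table = cohort_table([("u", BaseComposition.uniform())])
        with pytest.raises(ValueError):
            sphere_census(table, radius_override=0.0)


class TestShiftedExponentialFit:
    def test_mean_excess_reciprocal(self):
        fit = fit_shifted_exponential([0.26, 0.27, 0.28])  # mean 0.27
        assert fit.lambda_hat == pytest.approx(50.0)
        assert fit.lower_bound == 0.25

    def test_parameter_recovery_and_scipy_oracle(self):
        rng = np.random.default_rng(12)
        sample = 0.25 + rng.exponential(1 / 50, size=10_000)
        fit = fit_shifted_exponential(sample)
        assert fit.lambda_hat == pytest.approx(50.0, rel=0.05)
        # independent oracle: scipy's exponential MLE with fixed location
        loc, scale = scipy.stats.expon.fit(sample, floc=0.25)
        assert fit.lambda_hat == pytest.approx(1 / scale, rel=1e-9)

    def test_values_below_support_rejected(self):
        with pytest.raises(ValueError):
            fit_shifted_exponential([0.2, 0.3])

    def test_degenerate_sample_rejected(self):
        with pytest.raises(ValueError):
            fit_shifted_exponential([0.25, 0.25])


class TestSHCorrelation:
    def test_synthetic_cohort_strongly_negative(self):
        members = generate_cohort(
            CohortSpec(n=200, gc_low=0.25, gc_high=0.75, skew_scale=0.005, seed=2)
        )
        assert s_h_correlation(comp_cohort(members)) < -0.9

    def test_two_point_cohort_is_minus_one(self):
        table = cohort_table(
            [
                ("low", BaseComposition(0.25, 0.25, 0.25, 0.25)),
                ("high", BaseComposition(0.4, 0.1, 0.1, 0.4)),
            ]
        )
        assert s_h_correlation(table) == pytest.approx(-1.0)

    def test_constant_cohort_rejected(self):
        table = cohort_table(
            [(f"u{i}", BaseComposition.uniform()) for i in range(4)]
        )
        with pytest.raises(ValueError):
            s_h_correlation(table)

    def test_matches_scipy_pearson(self):
        members = generate_cohort(
            CohortSpec(n=50, gc_low=0.3, gc_high=0.7, skew_scale=0.01, seed=9)
        )
        table = comp_cohort(members)
        r, _ = scipy.stats.pearsonr(table["s"], table["h"])
        assert s_h_correlation(table) == pytest.approx(r, abs=1e-12)


def test_published_cohort_audit_metadata():
    """The 235-genome audit metadata: 18 plasmid accessions to exclude and
    the two corrected GC contents, usable only with downloaded genomes."""
    assert len(PLASMID_IDS) == 18
    assert all(acc.startswith("NC_") for acc in PLASMID_IDS)
    assert GC_CORRECTIONS["NC_006347"] == 43.27
    assert GC_CORRECTIONS["NC_003030"] == 30.93
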
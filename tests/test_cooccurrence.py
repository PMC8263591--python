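"""SparCC-style compositional correlation and its summary statistics."""

import numpy as np
import pandas as pd
import pytest

from gyntransloc import (
    CohortError,
    bootstrap_pvalues,
    cross_site_block,
    paired_joint_table,
    sign_conservation,
    sparcc_correlation,
    spearman_correlation,
    strong_pairs,
)
from gyntransloc.cohort_io import SampleRecord
from gyntransloc.synthetic import CohortParams, simulate_paired_cohort


def lognormal_counts(rho=0.0, n_subjects=200, n_taxa=10, depth=20000, seed=0):
    """Counts from a log-normal basis with a planted correlation between the
    first two components; the basis is the known truth."""
    rng = np.random.default_rng(seed)
    cov = np.eye(n_taxa)
    cov[0, 1] = cov[1, 0] = rho
    basis = np.exp(rng.multivariate_normal(np.full(n_taxa, 3.0), cov,
                                           size=n_subjects))
    frac = basis / basis.sum(axis=1, keepdims=True)
    return np.vstack([rng.multinomial(depth, f) for f in frac]).T


class TestSparcc:
    def test_unit_diagonal_symmetric_bounded(self):
        rng = np.random.default_rng(1)
        for seed in range(5):
            counts = lognormal_counts(0.0, n_subjects=40, seed=seed)
            r = sparcc_correlation(counts, seed=seed).to_numpy()
            assert np.allclose(np.diag(r), 1.0)
            assert np.allclose(r, r.T)
            assert np.all((r >= -1) & (r <= 1))

    def test_independent_basis_near_zero(self):
        counts = lognormal_counts(0.0, seed=2)
        r = sparcc_correlation(counts, seed=3).to_numpy()
        off = np.abs(r[np.triu_indices(r.shape[0], 1)])
        assert np.median(off) <= 0.1

    def test_planted_pair_recovered(self):
        counts = lognormal_counts(0.8, seed=4)
        r = sparcc_correlation(counts, seed=5).to_numpy()
        assert r[0, 1] > 0
        assert abs(r[0, 1] - 0.8) <= 0.2

    def test_scale_invariance_deterministic_mode(self):
        counts = lognormal_counts(0.5, n_subjects=60, seed=6)
        scales = np.random.default_rng(7).uniform(0.25, 4.0, counts.shape[1])
        a = sparcc_correlation(counts, n_inner_iterations=1)
        b = sparcc_correlation(counts * scales, n_inner_iterations=1)
        assert np.abs(a.to_numpy() - b.to_numpy()).max() < 1e-9

    def test_subject_count_gates(self):
        counts = lognormal_counts(0.0, n_subjects=4, seed=8)
        with pytest.raises(CohortError, match="at least 5"):
            sparcc_correlation(counts)
        counts = lognormal_counts(0.0, n_subjects=10, seed=9)
        with pytest.warns(UserWarning, match="unstable"):
            sparcc_correlation(counts, seed=0)

    def test_spearman_agrees_on_strong_pair_sign(self):
        counts = lognormal_counts(0.9, seed=10)
        r_sp = spearman_correlation(counts).to_numpy()
        r_sc = sparcc_correlation(counts, seed=11).to_numpy()
        assert np.sign(r_sp[0, 1]) == np.sign(r_sc[0, 1]) == 1.0


class TestBootstrapPvalues:
    def test_planted_pair_minimal_p(self):
        counts = lognormal_counts(0.9, n_subjects=100, seed=12)
        r = sparcc_correlation(counts, n_inner_iterations=1)
        p = bootstrap_pvalues(counts, r, n_boot=20 if False else 49, seed=13,
                              n_inner_iterations=1)
        assert p.iloc[0, 1] == pytest.approx(1 / 50)

    def test_same_seed_identical(self):
        counts = lognormal_counts(0.3, n_subjects=40, seed=14)
        r = sparcc_correlation(counts, n_inner_iterations=1)
        p1 = bootstrap_pvalues(counts, r, n_boot=25, seed=9,
                               n_inner_iterations=1)
        p2 = bootstrap_pvalues(counts, r, n_boot=25, seed=9,
                               n_inner_iterations=1)
        assert p1.equals(p2)

    def test_small_boot_errors(self):
        counts = lognormal_counts(0.0, n_subjects=30, seed=15)
        with pytest.raises(CohortError, match="n_boot"):
            bootstrap_pvalues(counts, np.eye(10), n_boot=10)


class TestSignConservation:
    def test_identity_and_negation(self):
        h = np.array([0.5, -0.3, 0.2])
        same, total, _ = sign_conservation(h, h.copy())
        assert (same, total) == (3, 3)
        same, total, _ = sign_conservation(h, -h)
        assert (same, total) == (0, 3)

    def test_hand_example_two_of_three(self):
        h = np.array([0.5, -0.3, 0.2])
        d = np.array([0.1, 0.4, 0.6])
        same, total, flags = sign_conservation(h, d)
        assert same == 2 and total == 3
        assert list(flags) == ["same", "discordant", "same"]

    def test_categories_partition_total(self):
        rng = np.random.default_rng(16)
        h = np.round(rng.uniform(-1, 1, 50), 1)
        d = np.round(rng.uniform(-1, 1, 50), 1)
        same, total, flags = sign_conservation(h, d)
        counts = {k: int((flags == k).sum()) for k in ("same", "discordant", "zero")}
        assert sum(counts.values()) == total == 50
        assert counts["same"] == same


class TestStrongPairs:
    def corr(self, vals):
        taxa = [f"t{i}" for i in range(len(vals))]
        return pd.DataFrame(vals, index=taxa, columns=taxa)

    def test_strict_threshold(self):
        m = np.eye(3)
        m[0, 1] = m[1, 0] = 0.4    # exactly at the boundary: excluded
        m[0, 2] = m[2, 0] = -0.41  # just above in magnitude: included
        pairs = strong_pairs(self.corr(m), 0.4)
        assert pairs == [("t0", "t2", -0.41)]

    def test_sorted_by_magnitude_then_lexicographic(self):
        m = np.eye(4)
        m[0, 1] = m[1, 0] = 0.5
        m[2, 3] = m[3, 2] = -0.5
        m[0, 3] = m[3, 0] = 0.9
        pairs = strong_pairs(self.corr(m), 0.4)
        assert [p[:2] for p in pairs] == [("t0", "t3"), ("t0", "t1"), ("t2", "t3")]

    def test_empty_result_no_error(self):
        assert strong_pairs(self.corr(np.eye(3) * 0.0 + np.eye(3)), 0.9) == []

    def test_threshold_validation(self):
        with pytest.raises(CohortError):
            strong_pairs(self.corr(np.eye(2)), 1.5)


class TestCrossSitePlumbing:
    def test_joint_table_and_block(self):
        params = CohortParams(n_subjects=8, n_taxa=6, seed=17,
                              depth_per_sample=1000)
        tab, recs, _ = simulate_paired_cohort(params)
        joint = paired_joint_table(tab, recs)
        assert joint.shape == (12, 8)
        assert all(i.startswith(("uterus:", "vagina:")) for i in joint.index)
        corr = spearman_correlation(joint)
        block = cross_site_block(corr)
        assert block.shape == (6, 6)
        assert list(block.index) == list(tab.taxon_ids)

    def test_group_restriction(self):
        params = CohortParams(n_subjects=8, n_taxa=6, seed=18,
                              depth_per_sample=1000)
        tab, recs, _ = simulate_paired_cohort(params)
        n_healthy = sum(r.group == "healthy" for r in recs) // 2
        joint = paired_joint_table(tab, recs, group="healthy")
        assert joint.shape[1] == n_healthy
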
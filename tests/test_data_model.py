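"""Dataset initialization, contingency conversion and the mutation operator."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sp_stats

from epiforge import (
    ContingencyTable,
    GenotypeDataset,
    evaluate,
    init_counts,
    init_dataset,
    mutate,
    to_contingency,
)
from epiforge.objectives import ObjectiveSpec


class TestInitDataset:
    def test_balanced_assignment(self, rng):
        d = init_dataset(3000, 3, rng)
        assert d.n_subjects == 3000 and d.n_snps == 3
        assert int(d.status.sum()) == 1500

    def test_smallest_balanced_dataset(self, rng):
        d = init_dataset(2, 1, rng)
        assert sorted(d.status.tolist()) == [0, 1]

    def test_heterozygote_fraction_near_half(self):
        # 10,000 genotypes at P(het) = 0.5: binomial 99% bounds
        d = init_dataset(2500, 4, np.random.default_rng(0))
        n_het = int((d.genotypes == 1).sum())
        lo, hi = sp_stats.binom.interval(0.99, 10_000, 0.5)
        assert lo <= n_het <= hi

    @pytest.mark.parametrize("n", [1, 3, 999, 0, -2])
    def test_odd_or_nonpositive_subjects_rejected(self, rng, n):
        with pytest.raises(ValueError, match="even"):
            init_dataset(n, 3, rng)

    def test_count_level_init_matches_matrix_distribution(self, rng):
        # multinomial shortcut and matrix tabulation give the same
        # per-cell count distribution (two-sample KS on a marginal cell)
        reps = 2000
        counts = init_counts(reps, 50, 2, rng)
        matrix_counts = np.array(
            [
                to_contingency(init_dataset(50, 2, rng)).case_counts
                for _ in range(reps)
            ]
        )
        for cell in (0, 4, 8):
            p = sp_stats.ks_2samp(counts[:, 0, cell], matrix_counts[:, cell]).pvalue
            assert p > 1e-4


class TestContingency:
    def test_direct_enumeration_example(self):
        d = GenotypeDataset(np.array([[0], [0], [1], [2]]), np.array([1, 0, 1, 0]))
        t = to_contingency(d)
        assert t.case_counts.tolist() == [1, 1, 0]
        assert t.control_counts.tolist() == [1, 0, 1]

    def test_empty_cell_is_zero(self):
        d = GenotypeDataset(np.array([[0], [1]]), np.array([1, 0]))
        t = to_contingency(d)
        assert t.case_counts[2] == 0 and t.control_counts[2] == 0

    def test_counts_sum_to_subjects(self, rng):
        d = init_dataset(100, 3, rng)
        t = to_contingency(d)
        assert t.n_subjects == 100 and t.is_balanced

    def test_roundtrip_through_canonical_matrix(self, rng):
        for _ in range(20):
            t = to_contingency(init_dataset(40, 3, rng))
            t2 = to_contingency(t.to_dataset())
            assert np.array_equal(t.case_counts, t2.case_counts)
            assert np.array_equal(t.control_counts, t2.control_counts)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            ContingencyTable(np.array([-1, 1, 0]), np.array([0, 0, 0]), 1)


class TestMutate:
    def test_rate_zero_is_identity(self, rng):
        d = init_dataset(50, 3, rng)
        m = mutate(d, 0.0, rng)
        assert np.array_equal(m.genotypes, d.genotypes)
        t = to_contingency(d)
        mt = mutate(t, 0.0, rng)
        assert np.array_equal(mt.case_counts, t.case_counts)
        assert np.array_equal(mt.control_counts, t.control_counts)

    def test_rate_one_changes_every_entry(self, rng):
        d = init_dataset(50, 3, rng)
        m = mutate(d, 1.0, rng)
        assert (m.genotypes != d.genotypes).all()

    def test_status_untouched(self, rng):
        d = init_dataset(50, 3, rng)
        m = mutate(d, 0.5, rng)
        assert np.array_equal(m.status, d.status)

    def test_invalid_rate_rejected(self, rng):
        d = init_dataset(10, 2, rng)
        for bad in (-0.1, 1.5):
            with pytest.raises(ValueError, match="rate"):
                mutate(d, bad, rng)

    def test_mean_changed_entries_matches_binomial(self, rng):
        # n=3000, k=3, rate=0.001: Binomial(9000, 0.001) mean = 9
        d = init_dataset(3000, 3, rng)
        reps = 1000
        changed = np.empty(reps)
        for i in range(reps):
            changed[i] = (mutate(d, 0.001, rng).genotypes != d.genotypes).sum()
        se = np.sqrt(9000 * 0.001 * 0.999 / reps)
        assert abs(changed.mean() - 9.0) <= 3 * se

    def test_table_mutation_conserves_totals(self, rng):
        t = to_contingency(init_dataset(100, 3, rng))
        m = mutate(t, 0.05, rng)
        assert m.case_counts.sum() == 50 and m.control_counts.sum() == 50
        assert (m.case_counts >= 0).all() and (m.control_counts >= 0).all()

    def test_matrix_and_table_paths_distributionally_equal(self, rng):
        # same parent, 2000 mutated replicates per path: the objective
        # vectors must come from one distribution
        parent = init_dataset(50, 2, rng)
        table = to_contingency(parent)
        spec = ObjectiveSpec(2, (1,))
        reps = 2000
        a = np.array(
            [
                evaluate(to_contingency(mutate(parent, 0.02, rng)), spec).values
                for _ in range(reps)
            ]
        )
        b = np.array(
            [evaluate(mutate(table, 0.02, rng), spec).values for _ in range(reps)]
        )
        for j in range(a.shape[1]):
            assert sp_stats.ks_2samp(a[:, j], b[:, j]).pvalue > 1e-4


@settings(derandomize=True, max_examples=25, deadline=None)
@given(
    half=st.integers(min_value=1, max_value=40),
    k=st.integers(min_value=1, max_value=4),
    rate=st.floats(min_value=0.0, max_value=1.0),
    seed=st.integers(min_value=0, max_value=2**20),
)
def test_mutation_preserves_invariants(half, k, rate, seed):
    """Balance and the genotype domain survive any mutation rate."""
    rng = np.random.default_rng(seed)
    d = init_dataset(2 * half, k, rng)
    m = mutate(d, rate, rng)
    assert int(m.status.sum()) == half
    assert np.isin(m.genotypes, (0, 1, 2)).all()
    t = mutate(to_contingency(d), rate, rng)
    assert t.case_counts.sum() == half and t.control_counts.sum() == half
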
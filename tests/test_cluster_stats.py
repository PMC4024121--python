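import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from graphpac import (
    GraphPACError,
    InsufficientMutationsError,
    MutationCounts,
    PathOrder,
    all_pairs_scan,
    bonferroni_factor,
    mc_cluster_pvalue_oracle,
    order_statistics,
    pair_cluster_pvalue,
    unmap_cluster,
)


def _counts(d):
    return MutationCounts(counts=d, n_total=sum(d.values()), n_samples=len(d))


def _identity(n):
    return PathOrder(np.arange(n), "identity")


class TestOrderStatistics:
    def test_counts_expand_to_sorted_positions(self):
        os_ = order_statistics(_counts({5: 2, 9: 1}), _identity(100))
        np.testing.assert_array_equal(os_.positions, [5, 5, 9])
        assert os_.n == 3 and os_.N == 100

    def test_path_permutation_applied_before_sorting(self):
        # a path placing residue 9 at rank 2 and residue 5 at rank 7
        order = [0, 8, 1, 2, 3, 5, 4, 6, 7, 9]
        path = PathOrder(np.array(order), "x")
        assert path.positions()[8] == 2 and path.positions()[4] == 7
        os_ = order_statistics(_counts({5: 2, 9: 1}), path)
        np.testing.assert_array_equal(os_.positions, [2, 7, 7])

    def test_single_mutation_insufficient(self):
        with pytest.raises(InsufficientMutationsError):
            order_statistics(_counts({3: 1}), _identity(10))


class TestPairPvalue:
    def test_uniform_gap_closed_form(self):
        # n=2: Pr(Beta(1,1+2-2+1) <= 0.5) = 1-(1-c)^2 = 0.75
        assert pair_cluster_pvalue(1, 2, 1, 5, 2, 10) == pytest.approx(0.75)

    def test_beta_2_2_closed_form(self):
        # n=3, (1,3): 3c^2 - 2c^3 at c = 0.1
        assert pair_cluster_pvalue(1, 3, 1, 10, 3, 100) == pytest.approx(0.028)

    def test_full_span_is_one(self):
        assert pair_cluster_pvalue(1, 4, 1, 50, 5, 50) == pytest.approx(1.0)

    def test_exclusive_convention_is_literal_gap(self):
        assert pair_cluster_pvalue(1, 2, 1, 6, 2, 10, "exclusive") == pytest.approx(0.75)
        # zero gap degenerates to p = 0 under the exclusive convention only
        assert pair_cluster_pvalue(1, 2, 4, 4, 2, 10, "exclusive") == 0.0
        assert pair_cluster_pvalue(1, 2, 4, 4, 2, 10, "inclusive") > 0.0

    def test_invalid_indices_rejected(self):
        with pytest.raises(GraphPACError):
            pair_cluster_pvalue(2, 2, 1, 5, 3, 10)
        with pytest.raises(GraphPACError):
            pair_cluster_pvalue(1, 2, 7, 5, 2, 10)

    @given(st.integers(1, 99), st.integers(1, 99))
    def test_monotone_in_span(self, a, b):
        lo, hi = sorted((a, b))
        p_lo = pair_cluster_pvalue(1, 3, 1, lo, 5, 100)
        p_hi = pair_cluster_pvalue(1, 3, 1, hi, 5, 100)
        assert p_lo <= p_hi + 1e-12

    @given(st.integers(2, 9))
    def test_more_mutations_in_same_span_more_significant(self, k):
        # at fixed span and n, growing k-i shrinks the p-value
        p_k = pair_cluster_pvalue(1, k, 10, 19, 10, 100)
        p_k1 = pair_cluster_pvalue(1, k + 1, 10, 19, 10, 100)
        assert p_k1 <= p_k + 1e-12


class TestAllPairsScan:
    def test_three_mutations_three_pairs(self):
        os_ = order_statistics(_counts({5: 2, 9: 1}), _identity(100))
        clusters = all_pairs_scan(os_)
        assert len(clusters) == 3
        by_pair = {(c.i, c.k): c for c in clusters}
        # closed forms: (1,2) Beta(1,3) at c=0.01; (2,3) Beta(1,3) at 0.05;
        # (1,3) Beta(2,2) at 0.05 -- the tightest despite the wider span,
        # because it holds all three mutations
        assert by_pair[(1, 2)].p_raw == pytest.approx(1 - 0.99**3)
        assert by_pair[(2, 3)].p_raw == pytest.approx(1 - 0.95**3)
        assert by_pair[(1, 3)].p_raw == pytest.approx(3 * 0.05**2 - 2 * 0.05**3)
        best = min(clusters, key=lambda c: c.p_raw)
        assert (best.i, best.k) == (1, 3)

    def test_bonferroni_capped_at_one(self):
        os_ = order_statistics(_counts({10: 1, 60: 1, 95: 1}), _identity(100))
        for c in all_pairs_scan(os_):
            assert c.p_bonf == pytest.approx(min(1.0, c.p_raw * 3))
        assert any(c.p_bonf == 1.0 for c in all_pairs_scan(os_))

    def test_reversal_leaves_pvalue_multiset_unchanged(self):
        counts = _counts({3: 2, 17: 1, 40: 3, 77: 1})
        fwd = all_pairs_scan(order_statistics(counts, _identity(100)))
        rev_path = PathOrder(np.arange(100)[::-1].copy(), "x")
        rev = all_pairs_scan(order_statistics(counts, rev_path))
        assert sorted(c.p_raw for c in fwd) == pytest.approx(
            sorted(c.p_raw for c in rev)
        )

    def test_bonferroni_factor(self):
        assert bonferroni_factor(2) == 1
        assert bonferroni_factor(5) == 10
        assert bonferroni_factor(60) == 1770


class TestMonteCarloOracle:
    def test_full_support_estimates_one(self):
        est = mc_cluster_pvalue_oracle(1, 3, 1.0, 3, 50, reps=2000, seed=1)
        assert est.estimate == pytest.approx(1.0)

    def test_se_is_binomial(self):
        est = mc_cluster_pvalue_oracle(1, 3, 0.2, 3, 100, reps=10_000, seed=2)
        assert est.se == pytest.approx(
            np.sqrt(est.estimate * (1 - est.estimate) / 10_000)
        )

    def test_beta_never_understates_discrete_null(self):
        """The closed form is conservative: it may exceed the discrete-null
        probability (by O(1/N)) but never undershoots it beyond MC noise."""
        for (i, k, n, N, c) in [
            (1, 3, 3, 100, 0.1),
            (1, 2, 5, 100, 0.1),
            (2, 4, 5, 200, 0.2),
            (1, 10, 10, 200, 0.3),
        ]:
            beta = pair_cluster_pvalue(i, k, 1, int(round(c * N)), n, N)
            c_obs = (int(round(c * N)) - 1 + 1) / N
            est = mc_cluster_pvalue_oracle(i, k, c_obs, n, N, reps=50_000, seed=7)
            assert beta >= est.estimate - 4 * est.se

    def test_agreement_where_the_limit_applies(self):
        """For spans holding several mutations (k - i >= 2) on a large
        residue grid, the Beta tail matches the simulated null closely."""
        for (i, k, n, N, c) in [
            (1, 5, 5, 200, 0.2),
            (1, 10, 10, 200, 0.5),
            (2, 9, 10, 200, 0.2),
        ]:
            beta = pair_cluster_pvalue(i, k, 1, int(round(c * N)), n, N)
            est = mc_cluster_pvalue_oracle(i, k, c, n, N, reps=100_000, seed=11)
            assert beta == pytest.approx(est.estimate, abs=4 * max(est.se, 1e-4))

    def test_without_replacement_option(self):
        est = mc_cluster_pvalue_oracle(
            1, 3, 0.2, 3, 50, reps=5000, seed=3, with_replacement=False
        )
        assert 0.0 <= est.estimate <= 1.0


class TestUnmap:
    def test_identity_path_endpoints(self):
        os_ = order_statistics(_counts({5: 1, 9: 2}), _identity(20))
        rc = all_pairs_scan(os_)[0]
        report = unmap_cluster(rc, _identity(20), None, os_)
        assert (report.start_residue, report.end_residue) == (5, 9)
        assert report.members == [5, 9]

    def test_sequence_distant_residues_adjacent_on_path(self):
        # a path placing canonical residues 12 and 61 at consecutive ranks
        order = [11, 60] + [v for v in range(70) if v not in (11, 60)]
        path = PathOrder(np.array(order), "x")
        os_ = order_statistics(_counts({12: 1, 61: 1}), path)
        np.testing.assert_array_equal(os_.positions, [1, 2])
        rc = all_pairs_scan(os_)[0]
        report = unmap_cluster(rc, path, None, os_)
        assert (report.start_residue, report.end_residue) == (12, 61)

    def test_single_position_cluster(self):
        os_ = order_statistics(_counts({7: 2}), _identity(10))
        rc = all_pairs_scan(os_)[0]
        report = unmap_cluster(rc, _identity(10), None, os_)
        assert report.start_residue == report.end_residue == 7
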
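"""Tests of the permutation F-test machinery: statistic arithmetic,
p-value counting, FDR step-up, permutation-null correctness against
brute-force oracles, and determinism."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fpcatest import (
    ExpressionMatrix,
    bh_adjust,
    f_statistic,
    fit_multi_group,
    fit_one_group,
    make_bins,
    multi_group_test,
    one_group_test,
    permute_multi_group,
    permute_one_group,
    pvalues_genewise,
    pvalues_pooled,
    simulate_one_group,
    simulate_two_group,
)
from fpcatest.fpca import CenteredMatrix, EigenSystem, trapezoid_weights
from fpcatest.significance import PermutationNull, _per_timepoint_scheme


class TestFStatistic:
    def test_arithmetic(self):
        np.testing.assert_allclose(f_statistic(2.0, 1.0, 0.01), 1.0 / 1.01)
        assert f_statistic(3.0, 3.0, 0.01) == 0.0
        np.testing.assert_allclose(f_statistic(3.0, 0.0, 0.01), 300.0)

    def test_rejects_negative_rss(self):
        with pytest.raises(ValueError):
            f_statistic(-1.0, 1.0, 0.01)
        with pytest.raises(ValueError):
            f_statistic(1.0, 1.0, 0.0)


class TestPValues:
    def test_genewise_counting(self):
        null = PermutationNull(stats=np.array([[5.0], [1.0], [0.0], [2.0]]), B=4)
        np.testing.assert_allclose(pvalues_genewise([2.0], null), [0.5])
        np.testing.assert_allclose(pvalues_genewise([6.0], null), [0.0])
        np.testing.assert_allclose(pvalues_genewise([0.0], null), [1.0])

    def test_pooled_counting(self):
        null = PermutationNull(stats=np.array([[3.0, 2.0], [1.0, 0.0]]), B=2)
        np.testing.assert_allclose(
            pvalues_pooled([2.5, 0.5], null), [1 / 4, 3 / 4]
        )

    def test_pooled_ties_get_equal_p(self):
        null = PermutationNull(stats=np.random.default_rng(0).random((5, 3)), B=5)
        p = pvalues_pooled([0.5, 0.5, 0.5], null)
        assert len(set(p)) == 1

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(st.integers(0, 2**32 - 1))
    def test_pooled_preserves_ordering(self, seed):
        rng = np.random.default_rng(seed)
        null = PermutationNull(stats=rng.normal(size=(7, 9)), B=7)
        f = rng.normal(size=9)
        p = pvalues_pooled(f, null)
        order = np.argsort(f)
        assert np.all(np.diff(p[order]) <= 0)


class TestBHAdjust:
    def test_step_up_example(self):
        p = np.array([0.001, 0.02, 0.04, 0.8])
        adj, rejected = bh_adjust(p, 0.05)
        assert rejected.tolist() == [True, True, False, False]

    def test_degenerate_cases(self):
        adj, rej = bh_adjust(np.zeros(4), 0.05)
        assert rej.all() and np.all(adj == 0)
        adj, rej = bh_adjust(np.ones(4), 0.05)
        assert not rej.any()

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(st.integers(0, 2**32 - 1))
    def test_matches_threshold_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.random(20)
        level = 0.1
        adj, rejected = bh_adjust(p, level)
        # independent step-up oracle: largest k with p_(k) <= k * level / m
        order = np.argsort(p, kind="stable")
        m = len(p)
        ks = np.nonzero(p[order] <= (np.arange(1, m + 1) * level / m))[0]
        expect = np.zeros(m, bool)
        if ks.size:
            expect[order[: ks[-1] + 1]] = True
        assert np.array_equal(rejected, expect)
        assert np.all(adj >= p - 1e-12)


def _toy_eigensystem(times, n_components=1):
    k = len(times)
    w = trapezoid_weights(times)
    rng = np.random.default_rng(0)
    m = rng.normal(size=(k, k))
    from fpcatest import eigendecompose

    eig = eigendecompose(m @ m.T, times)
    eig.L = n_components
    return eig


class TestOneGroupPermutation:
    def test_identity_permutation_recovers_observed_f(self):
        ds = simulate_one_group(n=50, pi0=0.5, seed=21)
        fit = fit_one_group(ds.data)
        ident = np.arange(ds.data.n_times)[None, :]
        null = permute_one_group(
            fit.fpca.centered, fit.fpca.eig, fit.delta, B=1, permutations=ident
        )
        np.testing.assert_allclose(null.stats[0], fit.f, atol=1e-10)

    def test_exhaustive_enumeration_matches_brute_force(self):
        # K = 3: compare against a from-scratch recomputation per permutation
        from itertools import permutations as iterperms

        times = np.array([0.0, 1.0, 2.0])
        rng = np.random.default_rng(5)
        values = rng.normal(size=(6, 3))
        means = values.mean(1)
        centered = values - means[:, None]
        cm = CenteredMatrix(means, centered, np.ones_like(values, bool), times,
                            [f"g{i}" for i in range(6)])
        eig = _toy_eigensystem(times, 1)
        delta = 0.02
        perms = np.array(list(iterperms(range(3))))
        null = permute_one_group(cm, eig, delta, B=6, permutations=perms)
        w = trapezoid_weights(times)
        phi = eig.eigenfunctions[:1]
        for b, pm in enumerate(perms):
            cp = centered[:, pm]
            xi = cp @ (phi[0] * w)
            rss1 = ((cp - xi[:, None] * phi[0]) ** 2).sum(1)
            rss0 = (cp**2).sum(1)
            expect = (rss0 / 3 - rss1 / 3) / (rss1 / 3 + delta)
            np.testing.assert_allclose(null.stats[b], expect, atol=1e-12)

    def test_exactly_constant_gene_has_p_one(self):
        ds = simulate_one_group(n=40, pi0=0.2, seed=23)
        vals = ds.data.values.copy()
        vals[0] = 2.5  # exactly flat gene
        data = ExpressionMatrix(ds.data.gene_ids, ds.data.times, vals)
        result = one_group_test(data, B=200, seed=1, pvalue_mode="genewise")
        assert result.f[0] == 0.0
        assert result.p[0] == 1.0

    def test_duplicated_gene_exchangeability(self):
        ds = simulate_one_group(n=5, pi0=1.0, seed=31)
        vals = np.tile(ds.data.values[0], (30, 1))
        data = ExpressionMatrix([f"g{i}" for i in range(30)], ds.data.times, vals)
        result = one_group_test(data, B=300, seed=2, pvalue_mode="pooled",
                                per_gene_permutation=False)
        assert len(set(result.f)) == 1
        assert len(set(result.p)) == 1

    def test_determinism(self):
        ds = simulate_one_group(n=60, pi0=0.3, seed=41)
        r1 = one_group_test(ds.data, B=200, seed=77)
        r2 = one_group_test(ds.data, B=200, seed=77)
        assert np.array_equal(r1.f, r2.f)
        assert np.array_equal(r1.p, r2.p)
        assert np.array_equal(r1.rejected, r2.rejected)


class TestBins:
    def _two_groups(self, t1, t2):
        rng = np.random.default_rng(0)
        ids = ["a", "b", "c"]
        g1 = ExpressionMatrix(ids, t1, rng.normal(size=(3, len(t1))))
        g2 = ExpressionMatrix(ids, t2, rng.normal(size=(3, len(t2))))
        return [g1, g2]

    def test_narrow_bins_reduce_to_per_timepoint(self):
        t = np.array([0.0, 10.0, 20.0, 30.0])
        groups = self._two_groups(t, t)
        scheme = make_bins(groups, 5.0)
        occupied = sorted(set(scheme.assignment[0]))
        assert len(occupied) == 4  # one occupied bin per time point
        assert np.array_equal(scheme.assignment[0], scheme.assignment[1])

    def test_fully_empty_bin_dropped_silently(self):
        t1 = np.array([100.0, 110.0, 135.0, 150.0])
        t2 = np.array([105.0, 115.0, 138.0, 155.0])
        scheme = make_bins(self._two_groups(t1, t2), 10.0)
        # [120, 130) holds no observation from either group
        dropped_edges = [scheme.edges[d] for d in scheme.dropped_bins]
        assert 120.0 in dropped_edges

    def test_partially_covered_bin_dropped_with_warning(self, caplog):
        t1 = np.array([100.0, 110.0, 121.0, 150.0])
        t2 = np.array([105.0, 115.0, 138.0, 155.0])
        with caplog.at_level("WARNING"):
            scheme = make_bins(self._two_groups(t1, t2), 10.0)
        assert any("no observations from group" in r.message for r in caplog.records)
        assert scheme.assignment[0][2] == -1  # t=121 sits in a dropped bin

    def test_all_bins_dropped_raises(self):
        t1 = np.array([100.0, 101.0, 102.0, 103.0])
        t2 = np.array([150.0, 151.0, 152.0, 153.0])
        with pytest.raises(ValueError):
            make_bins(self._two_groups(t1, t2), 10.0)


class TestMultiGroup:
    def test_identity_partition_recovers_observed_f(self):
        ds = simulate_two_group(n=40, pi0=0.5, seed=51)
        fit = fit_multi_group(ds.groups)
        scheme = make_bins(ds.groups, 10.0)
        ident = fit.col_group[None, :]
        null = permute_multi_group(fit, scheme, B=1, permutations=ident)
        np.testing.assert_allclose(null.stats[0], fit.f, atol=1e-9)

    def test_exhaustive_partition_oracle(self):
        # 2 groups on identical 5-point grids: per-time-point permutation has
        # 2^5 equally likely label patterns; sampled stats must all lie in the
        # exhaustively enumerated support
        from itertools import product

        k_t = 5
        t = np.arange(k_t, dtype=float)
        rng = np.random.default_rng(7)
        ids = [f"g{i}" for i in range(5)]
        g1 = ExpressionMatrix(ids, t, rng.normal(size=(5, k_t)))
        g2 = ExpressionMatrix(ids, t, rng.normal(size=(5, k_t)))
        fit = fit_multi_group([g1, g2])
        scheme = _per_timepoint_scheme([g1, g2])
        # enumerate all label assignments: per time point, swap or keep
        labels = []
        base = fit.col_group
        for swaps in product([0, 1], repeat=k_t):
            lab = base.copy()
            for k, s in enumerate(swaps):
                if s:
                    lab[k], lab[k_t + k] = base[k_t + k], base[k]
            labels.append(lab)
        exact = permute_multi_group(fit, scheme, B=len(labels),
                                    permutations=np.array(labels))
        sampled = permute_multi_group(fit, scheme, B=400, seed=3,
                                      per_gene=False)
        support = {tuple(np.round(row, 9)) for row in exact.stats}
        for row in sampled.stats:
            assert tuple(np.round(row, 9)) in support

    def test_duplicated_group_degeneracy(self):
        # group 2 an exact copy of group 1 including noise: every permutation
        # swaps identical values, so the null distribution is degenerate at
        # the observed F and pooled p-values reduce to within-sample ranks
        ds = simulate_two_group(n=30, pi0=0.5, seed=61,
                                times=(np.linspace(100, 244, 12),) * 2)
        g1 = ds.groups[0]
        g2 = ExpressionMatrix(list(g1.gene_ids), g1.times, g1.values.copy())
        fit = fit_multi_group([g1, g2])
        scheme = _per_timepoint_scheme([g1, g2])
        null = permute_multi_group(fit, scheme, B=50, seed=4)
        assert np.max(np.abs(null.stats - fit.f[None, :])) < 1e-9
        p = pvalues_pooled(fit.f, null)
        n = len(fit.f)
        rank_fraction = np.array([(fit.f >= fi).sum() / n for fi in fit.f])
        np.testing.assert_allclose(p, rank_fraction, atol=1.0 / n)
        assert np.all(p[fit.f <= np.median(fit.f)] > 0.45)

    def test_mismatched_gene_sets_rejected(self):
        ds = simulate_two_group(n=10, pi0=0.0, seed=71)
        g2 = ExpressionMatrix([f"x{i}" for i in range(10)],
                              ds.groups[1].times, ds.groups[1].values)
        with pytest.raises(ValueError, match="gene_id"):
            fit_multi_group([ds.groups[0], g2])

    def test_determinism(self):
        ds = simulate_two_group(n=30, pi0=0.3, seed=81)
        r1 = multi_group_test(ds.groups, B=100, seed=9, bin_width=10.0)
        r2 = multi_group_test(ds.groups, B=100, seed=9, bin_width=10.0)
        assert np.array_equal(r1.f, r2.f)
        assert np.array_equal(r1.p, r2.p)
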
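import numpy as np
import pandas as pd
import pytest

from mhc_escape.core_io import GeneSet, GeneSetCollection
from mhc_escape.enrichment import (
    EnrichmentParams,
    ScoreMatrix,
    preranked_gsea,
    ssgsea_matrix,
    ssgsea_sample,
    zscore_by_set,
)


def brute_force_ssgsea(values, gene_ids, gene_set, alpha):
    """Independent per-position evaluation of the weighted ECDF sum."""
    order = sorted(range(len(gene_ids)), key=lambda i: (-values[i], gene_ids[i]))
    members = set(gene_set)
    n = len(gene_ids)
    weights = []
    for pos, i in enumerate(order):
        rank = n - pos  # top position has rank N
        weights.append(rank**alpha if gene_ids[i] in members else 0.0)
    wsum = sum(weights)
    n_out = sum(1 for i in order if gene_ids[i] not in members)
    es, cum_in, cum_out = 0.0, 0.0, 0.0
    for pos, i in enumerate(order):
        cum_in += weights[pos] / wsum
        if gene_ids[i] not in members:
            cum_out += 1.0 / n_out
        es += cum_in - cum_out
    return es


def brute_force_gsea_es(stats, gene_ids, gene_set):
    """Exhaustive running-sum evaluation of the weighted KS statistic."""
    order = sorted(range(len(gene_ids)), key=lambda i: (-stats[i], gene_ids[i]))
    members = set(gene_set)
    in_flags = [gene_ids[i] in members for i in order]
    n_in = sum(in_flags)
    total = sum(abs(stats[i]) for i in order if gene_ids[i] in members)
    running, best = 0.0, 0.0
    for pos, i in enumerate(order):
        if in_flags[pos]:
            running += abs(stats[i]) / total
        else:
            running -= 1.0 / (len(gene_ids) - n_in)
        if abs(running) > abs(best):
            best = running
    return best


class TestSsgseaSample:
    def test_top_gene_singleton_alpha_zero(self):
        # 3-gene universe, set = top gene: positions contribute 1, 0.5, 0
        es = ssgsea_sample(
            np.array([3.0, 2.0, 1.0]), ["A", "B", "C"], {"A"},
            EnrichmentParams(alpha=0.0),
        )
        assert es == pytest.approx(1.5, abs=1e-12)

    def test_bottom_gene_singleton_alpha_zero(self):
        es = ssgsea_sample(
            np.array([3.0, 2.0, 1.0]), ["A", "B", "C"], {"C"},
            EnrichmentParams(alpha=0.0),
        )
        assert es == pytest.approx(-1.5, abs=1e-12)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(size=20)
        ids = [f"G{i:02d}" for i in range(20)]
        gene_set = {"G03", "G07", "G11"}
        es1 = ssgsea_sample(vals, ids, gene_set)
        es2 = ssgsea_sample(np.exp(3 * vals) + 7, ids, gene_set)
        assert es1 == pytest.approx(es2, abs=1e-12)

    def test_empty_intersection_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            ssgsea_sample(np.array([1.0, 2.0]), ["A", "B"], {"Z"})

    def test_whole_universe_rejected(self):
        with pytest.raises(ValueError, match="universe"):
            ssgsea_sample(np.array([1.0, 2.0]), ["A", "B"], {"A", "B"})

    def test_antisymmetric_under_order_reversal_singletons(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            vals = rng.normal(size=9)
            ids = [f"G{i}" for i in range(9)]
            pick = {ids[rng.integers(9)]}
            p = EnrichmentParams(alpha=0.0)
            es_fwd = ssgsea_sample(vals, ids, pick, p)
            es_rev = ssgsea_sample(-vals, ids, pick, p)
            assert es_fwd == pytest.approx(-es_rev, abs=1e-10)

    def test_random_set_expected_es_unbiased_at_alpha_zero(self):
        # with unweighted steps the in/out ECDF race is exchangeable, so
        # the random-set ES has mean zero
        rng = np.random.default_rng(9)
        ids = [f"G{i:03d}" for i in range(100)]
        params = EnrichmentParams(alpha=0.0)
        total = 0.0
        reps = 2000
        for _ in range(reps):
            vals = rng.normal(size=100)
            pick = set(rng.choice(ids, size=10, replace=False))
            total += ssgsea_sample(vals, ids, pick, params)
        assert abs(total / reps) < 0.5  # null sd ~ 5.5 -> se of mean ~ 0.12

    def test_random_set_mean_matches_combinatorial_expectation(self):
        # for alpha > 0 the rank-position weighting makes the random-set ES
        # positively biased; its mean follows the closed-form expectation of
        # the weighted ECDF race computed here independently
        n, k, alpha = 100, 10, 0.25
        ranks = np.arange(n, 0, -1, dtype=float) ** alpha
        # hypergeometric expectation of cum_in(i): each position is in-set
        # with probability k/n, so E[W(i)]/E[W(n)] approximates via the
        # linearity over uniformly random subsets (exact for the mean of a
        # ratio of sums with common random subset only asymptotically; use
        # Monte Carlo with a distinct generator as the oracle)
        oracle_rng = np.random.default_rng(20260926)
        oracle_total = 0.0
        reps = 3000
        for _ in range(reps):
            pos = oracle_rng.choice(n, size=k, replace=False)
            in_set = np.zeros(n, dtype=bool)
            in_set[pos] = True
            w = np.where(in_set, ranks, 0.0)
            cum_in = np.cumsum(w) / w.sum()
            cum_out = np.cumsum(~in_set) / (n - k)
            oracle_total += np.sum(cum_in - cum_out)
        oracle_mean = oracle_total / reps

        rng = np.random.default_rng(9)
        ids = [f"G{i:03d}" for i in range(n)]
        params = EnrichmentParams(alpha=alpha)
        total = 0.0
        reps2 = 2000
        for _ in range(reps2):
            vals = rng.normal(size=n)
            pick = set(rng.choice(ids, size=k, replace=False))
            total += ssgsea_sample(vals, ids, pick, params)
        assert total / reps2 == pytest.approx(oracle_mean, abs=0.5)


class TestSsgseaMatrix:
    def test_matches_brute_force_per_cell(self):
        rng = np.random.default_rng(1)
        n_genes, n_samples = 60, 50
        ids = [f"G{i:03d}" for i in range(n_genes)]
        vals = rng.normal(size=(n_genes, n_samples))
        sets = [
            GeneSet(f"SET{k:02d}", "", sorted(
                rng.choice(ids, size=rng.integers(3, 12), replace=False)
            ))
            for k in range(20)
        ]
        from mhc_escape.normalization import ExpressionMatrix

        expr = ExpressionMatrix(ids, [f"S{j}" for j in range(n_samples)], vals)
        sm = ssgsea_matrix(expr, GeneSetCollection(sets))
        for k, s in enumerate(sets):
            for j in range(n_samples):
                expected = brute_force_ssgsea(vals[:, j], ids, s.genes, 0.25)
                assert sm.values[k, j] == pytest.approx(expected, abs=1e-9)

    def test_sample_permutation_equivariance(self, expr_from_array):
        rng = np.random.default_rng(2)
        expr = expr_from_array(rng.normal(size=(30, 8)))
        coll = GeneSetCollection([GeneSet("S", "", ["G1", "G5", "G9"])])
        sm = ssgsea_matrix(expr, coll)
        perm = rng.permutation(8)
        expr_p = expr_from_array(
            expr.values[:, perm], sample_ids=[f"S{j}" for j in perm]
        )
        sm_p = ssgsea_matrix(expr_p, coll)
        np.testing.assert_allclose(sm_p.values[0], sm.values[0][perm], atol=1e-12)

    def test_no_overlap_set_dropped_with_warning(self, expr_from_array):
        expr = expr_from_array(np.random.default_rng(0).normal(size=(10, 4)))
        coll = GeneSetCollection(
            [GeneSet("GOOD", "", ["G1", "G2"]), GeneSet("BAD", "", ["ZZZ"])]
        )
        with pytest.warns(UserWarning, match="BAD"):
            sm = ssgsea_matrix(expr, coll)
        assert sm.set_names == ["GOOD"]

    def test_all_sets_dropped_is_error(self, expr_from_array):
        expr = expr_from_array(np.random.default_rng(0).normal(size=(5, 3)))
        coll = GeneSetCollection([GeneSet("BAD", "", ["ZZZ"])])
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError, match="dropped"):
                ssgsea_matrix(expr, coll)


class TestZscore:
    def test_two_sample_hand_values(self):
        sm = ScoreMatrix(["S"], ["a", "b"], np.array([[1.0, 3.0]]))
        z = zscore_by_set(sm)
        np.testing.assert_allclose(
            z.values[0], [-1 / np.sqrt(2), 1 / np.sqrt(2)], atol=1e-12
        )

    def test_idempotent_on_standardized_rows(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(size=(4, 10))
        z1 = zscore_by_set(ScoreMatrix([f"S{i}" for i in range(4)],
                                       [f"c{j}" for j in range(10)], vals))
        z2 = zscore_by_set(z1)
        np.testing.assert_allclose(z1.values, z2.values, atol=1e-10)
        assert np.all(np.abs(z1.values.mean(axis=1)) < 1e-10)
        np.testing.assert_allclose(z1.values.std(axis=1, ddof=1), 1.0, atol=1e-10)

    def test_zero_variance_set_named(self):
        sm = ScoreMatrix(["FLAT"], ["a", "b"], np.array([[2.0, 2.0]]))
        with pytest.raises(ValueError, match="FLAT"):
            zscore_by_set(sm)


class TestPrerankedGsea:
    def _stats(self, n=10, seed=0):
        rng = np.random.default_rng(seed)
        return pd.Series(rng.normal(size=n), index=[f"G{i:02d}" for i in range(n)])

    def test_top_genes_positive_es(self):
        stats = pd.Series(
            np.arange(10, 0, -1, dtype=float), index=[f"G{i}" for i in range(10)]
        )
        coll = GeneSetCollection([GeneSet("TOP", "", ["G0", "G1", "G2"])])
        out = preranked_gsea(stats, coll, EnrichmentParams(n_permutations=100, seed=0))
        assert out.loc[0, "ES"] > 0
        assert np.sign(out.loc[0, "NES"]) == np.sign(out.loc[0, "ES"])

    def test_determinism_same_seed(self):
        stats = self._stats(30, seed=5)
        coll = GeneSetCollection(
            [GeneSet("A", "", ["G01", "G05", "G09"]),
             GeneSet("B", "", ["G20", "G21"])]
        )
        p = EnrichmentParams(n_permutations=200, seed=7)
        out1 = preranked_gsea(stats, coll, p)
        out2 = preranked_gsea(stats, coll, p)
        pd.testing.assert_frame_equal(out1, out2)

    def test_es_matches_brute_force_oracle(self):
        rng = np.random.default_rng(8)
        for trial in range(20):
            stats = self._stats(10, seed=trial)
            members = sorted(rng.choice(stats.index, size=3, replace=False))
            coll = GeneSetCollection([GeneSet("S", "", members)])
            out = preranked_gsea(
                stats, coll, EnrichmentParams(n_permutations=100, seed=0)
            )
            expected = brute_force_gsea_es(
                stats.to_numpy(), list(stats.index), members
            )
            assert out.loc[0, "ES"] == pytest.approx(expected, abs=1e-12)

    def test_oversized_set_rejected(self):
        stats = self._stats(5)
        coll = GeneSetCollection([GeneSet("BIG", "", [f"X{i}" for i in range(9)])])
        with pytest.raises(ValueError):
            preranked_gsea(stats, coll)

    def test_duplicate_gene_rejected(self):
        stats = pd.Series([1.0, 2.0, 1.5], index=["A", "A", "B"])
        coll = GeneSetCollection([GeneSet("S", "", ["A"])])
        with pytest.raises(ValueError, match="duplicate"):
            preranked_gsea(stats, coll)

    def test_null_pvalues_roughly_uniform(self):
        # moderate-size version of the null-calibration property
        from scipy.stats import kstest

        rng = np.random.default_rng(123)
        ids = [f"G{i:03d}" for i in range(120)]
        stats = pd.Series(rng.normal(size=120), index=ids)
        pvals = []
        for b in range(200):
            members = sorted(rng.choice(ids, size=8, replace=False))
            coll = GeneSetCollection([GeneSet("S", "", members)])
            out = preranked_gsea(
                stats, coll, EnrichmentParams(n_permutations=200, seed=b)
            )
            pvals.append(out.loc[0, "p"])
        assert kstest(pvals, "uniform").pvalue > 0.01
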
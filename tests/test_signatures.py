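import numpy as np
import pandas as pd
import pytest
from scipy import stats

from atlaskit import signatures as sig


def brute_force_es(scores: dict, gene_set, weight: float = 1.0) -> float:
    """Independent O(n * |set|) running-sum oracle for the enrichment score."""
    items = sorted(scores.items(), key=lambda kv: -kv[1])
    in_set = [g in gene_set for g, _ in items]
    n_miss = len(items) - sum(in_set)
    denom = sum(abs(s) ** weight for (g, s), h in zip(items, in_set) if h)
    if denom == 0:
        denom = sum(in_set)
    best = 0.0
    run = 0.0
    for (g, s), h in zip(items, in_set):
        if h:
            run += (abs(s) ** weight if denom else 1.0) / denom
        else:
            run -= 1.0 / n_miss
        if abs(run) > abs(best):
            best = run
    return best


class TestSelectSignatureGenes:
    def _de(self, rows):
        return pd.DataFrame(rows, columns=["gene", "adj_p", "log2fc", "ave_expr"])

    def test_threshold_conjunction(self):
        de = {
            ("JEJ", "T"): self._de([("gA", 0.04, 1.2, 2.5), ("gB", 0.04, 0.9, 2.5),
                                    ("gC", 0.5, 1.5, 2.5)]),
            ("BLO", "T"): self._de([("gA", 0.9, 0.0, 2.0), ("gB", 0.9, 0.0, 2.0),
                                    ("gC", 0.9, 0.0, 2.0)]),
        }
        z = sig.select_signature_genes(de)
        assert list(z.index) == ["gA"]  # gB fails lfc, gC fails adj_p

    def test_zscores_are_standardized_per_gene(self):
        rng = np.random.default_rng(0)
        de = {}
        for j in range(4):
            de[("T", f"g{j}")] = self._de(
                [(f"gene{i}", 0.01, 2.0, rng.uniform(2, 6)) for i in range(10)])
        z = sig.select_signature_genes(de)
        np.testing.assert_allclose(z.mean(axis=1), 0, atol=1e-9)
        np.testing.assert_allclose(z.std(axis=1, ddof=0), 1, atol=1e-9)

    def test_empty_selection_suggests_thresholds(self):
        de = {("JEJ", "T"): self._de([("gA", 0.5, 0.1, 0.5)])}
        with pytest.raises(ValueError, match="relaxing"):
            sig.select_signature_genes(de)


class TestClusterSignatureGenes:
    def test_planted_blocks_recovered_exactly(self):
        rng = np.random.default_rng(0)
        block1 = rng.normal(0, 0.1, size=(20, 6)) + [3, 3, 3, 0, 0, 0]
        block2 = rng.normal(0, 0.1, size=(20, 6)) + [0, 0, 0, 3, 3, 3]
        z = pd.DataFrame(np.vstack([block1, block2]),
                         index=[f"g{i}" for i in range(40)])
        cs = sig.cluster_signature_genes(z, n_clusters=2)
        assert len(cs.clusters) == 2
        sizes = sorted(len(v) for v in cs.clusters.values())
        assert sizes == [20, 20]
        one = set(cs.clusters[1])
        assert one in ({f"g{i}" for i in range(20)},
                       {f"g{i}" for i in range(20, 40)})

    def test_duplicate_rows_cocluster_and_order_invariance(self):
        rng = np.random.default_rng(1)
        z = pd.DataFrame(rng.normal(size=(15, 4)), index=[f"g{i}" for i in range(15)])
        z.loc["g1"] = z.loc["g0"]
        cs = sig.cluster_signature_genes(z, n_clusters=3)
        cl_of = {g: c for c, gs in cs.clusters.items() for g in gs}
        assert cl_of["g0"] == cl_of["g1"]
        perm = rng.permutation(15)
        cs_p = sig.cluster_signature_genes(z.iloc[perm], n_clusters=3)
        cl_of_p = {g: c for c, gs in cs_p.clusters.items() for g in gs}
        part1 = {}
        for g, c in cl_of.items():
            part1.setdefault(c, set()).add(g)
        part2 = {}
        for g, c in cl_of_p.items():
            part2.setdefault(c, set()).add(g)
        assert {frozenset(s) for s in part1.values()} == \
            {frozenset(s) for s in part2.values()}

    def test_too_few_clusters_rejected(self):
        z = pd.DataFrame(np.eye(5), index=list("abcde"))
        with pytest.raises(ValueError, match="n_clusters"):
            sig.cluster_signature_genes(z, n_clusters=1)


class TestGSEA:
    def test_matches_brute_force_oracle_on_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = int(rng.integers(20, 200))
            scores = {f"g{i}": float(rng.normal()) for i in range(n)}
            k = int(rng.integers(2, max(3, n // 4)))
            gene_set = list(rng.choice(n, k, replace=False))
            gene_set = [f"g{i}" for i in gene_set]
            ranking = pd.Series(scores)
            res = sig.gsea_preranked(ranking, gene_set, n_perm=100, seed=0)
            oracle = brute_force_es(scores, set(gene_set))
            assert res.es == pytest.approx(oracle, abs=1e-12)

    def test_top_of_ranking_scores_high(self):
        rng = np.random.default_rng(1)
        ranking = pd.Series(np.sort(rng.normal(size=1000))[::-1],
                            index=[f"g{i}" for i in range(1000)])
        res = sig.gsea_preranked(ranking, [f"g{i}" for i in range(10)],
                                 n_perm=200, seed=0)
        assert res.es > 0.9
        assert res.p_value < 0.05

    def test_antisymmetry_under_score_negation(self):
        rng = np.random.default_rng(2)
        ranking = pd.Series(rng.normal(size=100), index=[f"g{i}" for i in range(100)])
        gene_set = [f"g{i}" for i in range(0, 40, 4)]
        es_pos = sig.gsea_preranked(ranking, gene_set, n_perm=100, seed=0).es
        es_neg = sig.gsea_preranked(-ranking, gene_set, n_perm=100, seed=0).es
        assert es_pos == pytest.approx(-es_neg, abs=1e-9)

    def test_null_sets_give_uniform_p(self):
        rng = np.random.default_rng(3)
        ranking = pd.Series(rng.normal(size=300), index=[f"g{i}" for i in range(300)])
        pvals = []
        for rep in range(60):
            gene_set = [f"g{i}" for i in rng.choice(300, 25, replace=False)]
            res = sig.gsea_preranked(ranking, gene_set, n_perm=100, seed=rep)
            pvals.append(res.p_value)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_disjoint_set_rejected(self):
        ranking = pd.Series([1.0, 2.0], index=["a", "b"])
        with pytest.raises(ValueError, match="no overlap"):
            sig.gsea_preranked(ranking, ["zzz"], n_perm=100, seed=0)


class TestWilcoxon:
    def test_exact_p_on_separated_triples(self):
        stat, p = stats.mannwhitneyu([1, 2, 3], [4, 5, 6],
                                     alternative="two-sided", method="exact")
        assert stat == 0
        assert p == pytest.approx(0.1)

    def test_adt_differential_planted_shift(self):
        rng = np.random.default_rng(0)
        n = 120
        counts = rng.poisson(20, size=(2 * n, 3))
        counts[:n, 0] = rng.poisson(150, size=n)  # marker 0 shifted in group A
        groups = np.array(["A"] * n + ["B"] * n)
        donors = np.tile([f"d{i}" for i in range(2)], n)
        res = sig.adt_differential(counts, ["m0", "m1", "m2"], groups,
                                   donor_labels=donors, min_cells=30,
                                   min_donors=2, seed=0)
        m0 = res[res["marker"] == "m0"]
        assert (m0["p_value"] < 0.01).all()
        assert (m0["mean_diff"] > 0).all()

    def test_adt_differential_null_is_calibrated(self):
        from scipy import stats as sps

        rng = np.random.default_rng(1)
        pvals = []
        for seed in range(60):
            counts = rng.poisson(50, size=(160, 3))
            groups = np.array(["A"] * 80 + ["B"] * 80)
            res = sig.adt_differential(counts, ["m0", "m1", "m2"], groups,
                                       per_donor=False, min_cells=30,
                                       min_donors=1, seed=seed)
            # markers within one draw share the depth normalization; keep one
            pvals.append(float(res.loc[res["marker"] == "m0", "p_value"].iloc[0]))
        assert sps.kstest(pvals, "uniform").pvalue > 0.01

    def test_adt_differential_skips_without_donors(self):
        counts = np.ones((40, 2), dtype=int)
        groups = np.array(["A", "B"] * 20)
        res = sig.adt_differential(counts, ["m0", "m1"], groups,
                                   donor_labels=np.zeros(40), min_cells=10,
                                   min_donors=4, seed=0)
        assert res is None
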
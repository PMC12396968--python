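import numpy as np
import pytest

from atlaskit import counterfactual as cf
from atlaskit.synthetic import EffectConfig, simulate_effect_matrix


def youden_oracle(scores, labels):
    """Exhaustive enumeration of J over all cutoffs and both orientations."""
    best = (-np.inf, None, None)
    uniq = np.unique(scores)
    for c in (uniq[:-1] + uniq[1:]) / 2:
        for orientation in ("ge", "le"):
            pred = scores >= c if orientation == "ge" else scores <= c
            sens = (pred & labels).sum() / labels.sum()
            spec = (~pred & ~labels).sum() / (~labels).sum()
            if sens + spec - 1 > best[0]:
                best = (sens + spec - 1, c, orientation)
    return best


def _effect(effects, embedding=None, **kw):
    effects = np.asarray(effects, dtype=float)
    n, g = effects.shape
    defaults = dict(
        embedding=np.random.default_rng(0).normal(size=(n, 2))
        if embedding is None else embedding,
        gene_names=np.array([f"g{i}" for i in range(g)], dtype=object),
        raw_mean_expr=np.full(g, 1.0),
        cell_sample_counts=np.full(n, 5),
    )
    defaults.update(kw)
    return cf.EffectMatrix(effects=effects, **defaults)


class TestFilters:
    def test_low_expression_gene_dropped(self):
        E = _effect(np.full((20, 2), 0.5), raw_mean_expr=np.array([0.005, 0.5]))
        out = cf.filter_effect_genes(E)
        assert list(out.gene_names) == ["g1"]

    def test_weak_effect_gene_dropped_constant_zero(self):
        eff = np.zeros((40, 2))
        eff[:, 1] = np.random.default_rng(0).normal(0, 0.5, 40)
        out = cf.filter_effect_genes(_effect(eff))
        assert list(out.gene_names) == ["g1"]

    def test_rare_cells_dropped(self):
        E = _effect(np.full((10, 1), 0.5),
                    cell_sample_counts=np.array([1] * 4 + [5] * 6))
        out = cf.filter_effect_genes(E)
        assert out.effects.shape[0] == 6

    def test_all_genes_removed_raises(self):
        E = _effect(np.zeros((10, 2)))
        with pytest.raises(ValueError, match="relax"):
            cf.filter_effect_genes(E)


class TestSmoothing:
    def test_constant_column_gives_twice_constant(self):
        E = _effect(np.full((30, 3), [1.0, -2.0, 0.5]))
        S = cf.smooth_effects(E, k=5)
        np.testing.assert_allclose(S.effects, 2 * E.effects, atol=1e-12)

    def test_linearity(self):
        rng = np.random.default_rng(0)
        emb = rng.normal(size=(25, 2))
        E1 = _effect(rng.normal(size=(25, 4)), embedding=emb)
        E2 = _effect(rng.normal(size=(25, 4)), embedding=emb)
        combo = _effect(3 * E1.effects - 2 * E2.effects, embedding=emb)
        S = cf.smooth_effects(combo, k=6).effects
        S12 = 3 * cf.smooth_effects(E1, k=6).effects \
            - 2 * cf.smooth_effects(E2, k=6).effects
        np.testing.assert_allclose(S, S12, atol=1e-10)

    def test_smoothing_reduces_within_module_variance(self):
        for seed in range(5):
            E, truth = simulate_effect_matrix(
                EffectConfig(n_cells=400, n_genes=60, noise_sd=0.3), seed=seed)
            S = cf.smooth_effects(E, k=15)
            mask = truth["module_mask"]
            up = np.isin(E.gene_names, truth["up_genes"])
            var_before = E.effects[np.ix_(mask, up)].var()
            var_after = S.effects[np.ix_(mask, up)].var()
            assert var_after < var_before

    def test_near_complete_graph_averages_everything(self):
        rng = np.random.default_rng(1)
        E = _effect(rng.normal(size=(20, 3)), embedding=rng.normal(size=(20, 2)))
        S = cf.smooth_effects(E, k=19).effects
        # every row mixes 19 of 20 cells: rows nearly identical
        assert np.abs(S - S.mean(axis=0)).max() < \
            0.25 * np.abs(E.effects).max()


class TestCoclustering:
    def test_planted_blocks_recovered(self):
        rng = np.random.default_rng(0)
        X = rng.normal(0, 0.05, size=(60, 40))
        X[:30, :20] += 2.0
        X[30:, 20:] -= 2.0
        E = _effect(X)
        assign = cf.cocluster_effects(E, 2, 2, seed=0)
        cell_true = np.repeat([0, 1], 30)
        gene_true = np.repeat([0, 1], 20)
        from sklearn.metrics import adjusted_rand_score

        assert adjusted_rand_score(cell_true, assign.cell_labels) == 1.0
        assert adjusted_rand_score(gene_true, assign.gene_labels) == 1.0

    def test_constant_matrix_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            cf.cocluster_effects(_effect(np.full((10, 5), 1.0)), 2, 2, seed=0)


class TestScores:
    def _assignment(self, n_cells=10, n_up=30, n_other=10):
        g = n_up + n_other
        eff = np.zeros((n_cells, g))
        eff[:, :n_up] = 0.5
        E = _effect(eff)
        assign = cf.ModuleAssignment(
            gene_labels=np.array([0] * n_up + [1] * n_other),
            cell_labels=np.zeros(n_cells, dtype=int),
            n_gene_modules=2, n_cell_modules=1)
        return E, assign

    def test_sum_lfc_worked_example(self):
        E, assign = self._assignment()
        assign = cf.score_modules(assign, E, top_n_markers=30)
        assert assign.scores[0].iloc[0] == pytest.approx(15.0)  # 30 x 0.5

    def test_negating_effects_negates_scores_for_fixed_markers(self):
        rng = np.random.default_rng(0)
        eff = rng.normal(size=(20, 15))
        E = _effect(eff)
        Eneg = _effect(-eff)
        labels = cf.ModuleAssignment(
            gene_labels=np.zeros(15, dtype=int),
            cell_labels=np.zeros(20, dtype=int),
            n_gene_modules=1, n_cell_modules=1)
        fitted = cf.score_modules(labels, E)
        s_pos = fitted.scores
        # scoring the negated matrix against the same (fixed) markers
        s_neg = cf.score_modules(fitted, Eneg).scores
        np.testing.assert_allclose(s_pos.to_numpy(), -s_neg.to_numpy(), atol=1e-12)

    def test_zero_effects_score_zero_under_both_rules(self):
        E, assign = self._assignment()
        E.effects[:] = 0.0
        for rule in ("sum_lfc", "weighted_sign_mean"):
            out = cf.score_modules(
                cf.ModuleAssignment(
                    gene_labels=assign.gene_labels,
                    cell_labels=assign.cell_labels,
                    n_gene_modules=2, n_cell_modules=1),
                E, score_rule=rule)
            assert not out.markers  # no nonzero markers survive


class TestYouden:
    def test_exhaustive_enumeration_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n = int(rng.integers(10, 60))
            scores = rng.normal(size=n).round(2)
            labels = rng.random(n) < 0.4
            if labels.all() or not labels.any() or np.unique(scores).size < 2:
                continue
            thr, orient, J = cf.youden_cutoff(scores, labels)
            J_oracle, _, _ = youden_oracle(scores, labels)
            assert J == pytest.approx(J_oracle, abs=1e-12)

    def test_separated_triples(self):
        scores = np.array([1.0, 2, 3, 4, 5, 6])
        labels = np.array([True] * 3 + [False] * 3)
        thr, orient, J = cf.youden_cutoff(scores, labels)
        assert J == pytest.approx(1.0)
        assert thr == pytest.approx(3.5)
        assert orient == "le"  # in-module cells sit below the cutoff

    def test_identical_distributions_give_low_J(self):
        rng = np.random.default_rng(1)
        scores = np.tile(rng.normal(size=100), 2)
        labels = np.array([True] * 100 + [False] * 100)
        _, _, J = cf.youden_cutoff(scores, labels)
        assert J < 0.1

    def test_transfer_applies_same_threshold(self):
        scores = np.array([0.0, 1, 2, 10, 11, 12])
        labels = np.array([False] * 3 + [True] * 3)
        thr, orient, J, masks = cf.youden_cutoff_and_transfer(
            scores, labels, {"lung": np.array([5.0, 20.0])})
        assert J == 1.0
        np.testing.assert_array_equal(masks["lung"], [False, True])

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            cf.youden_cutoff(np.array([1.0, 2.0]), np.array([True, True]))


class TestGeneThreshold:
    def test_named_gene_rule(self):
        eff = np.array([[-0.1, 0.2], [0.0, 0.2], [-0.04, 0.2]])
        E = _effect(eff, gene_names=np.array(["IL17A", "other"], dtype=object))
        mask = cf.gene_threshold_mask(E, "IL17A", -0.05, below=True)
        np.testing.assert_array_equal(mask, [True, False, False])
        with pytest.raises(KeyError):
            cf.gene_threshold_mask(E, "missing", 0.0)


class TestEndToEnd:
    def test_planted_module_recovery_f1_and_marker_recall(self):
        for seed in range(5):
            E, truth = simulate_effect_matrix(EffectConfig(), seed=seed)
            E2 = cf.filter_effect_genes(E)
            S = cf.smooth_effects(E2)
            assign = cf.score_modules(
                cf.cocluster_effects(S, 2, 2, seed=seed), S)
            mask = truth["module_mask"]
            planted = set(truth["up_genes"]) | set(truth["down_genes"])
            # the affected module is the one with the strongest markers
            strength = {m: mk["mean_lfc"].abs().mean()
                        for m, mk in assign.markers.items()}
            m = max(strength, key=strength.get)
            sc = assign.scores[m].to_numpy()
            thr, orient, J = cf.youden_cutoff(sc, mask)
            pred = sc >= thr if orient == "ge" else sc <= thr
            f1 = 2 * (pred & mask).sum() / (pred.sum() + mask.sum())
            recall = len(set(assign.markers[m]["gene"]) & planted) / 50
            assert f1 >= 0.85
            assert recall >= 0.7
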
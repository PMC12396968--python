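import numpy as np
import pandas as pd
import pytest
from scipy.optimize import linear_sum_assignment

from atlaskit import factors as fac


def planted_counts(G=100, N=300, K=3, seed=0, block=True):
    """Gamma-Poisson data with K planted gene programs (genes x cells)."""
    rng = np.random.default_rng(seed)
    if block:
        W = np.full((G, K), 0.05)
        size = G // K
        for k in range(K):
            W[k * size:(k + 1) * size, k] = rng.gamma(4.0, 1.0, size=size)
    else:
        W = rng.gamma(0.8, 1.0, size=(G, K)) + 0.05
    H = rng.gamma(0.8, 2.0, size=(K, N)) + 0.05
    X = rng.poisson(W @ H)
    X[X.sum(axis=1) == 0, 0] += 1
    X[0, X.sum(axis=0) == 0] += 1
    return X, W, H


def matched_loading_correlations(W_true, W_est):
    C = np.corrcoef(W_true.T, W_est.T)[:W_true.shape[1], W_true.shape[1]:]
    r, c = linear_sum_assignment(-C)
    return C[r, c]


class TestPoissonFactorization:
    def test_deviance_monotone_and_planted_recovery(self):
        X, W, _ = planted_counts(seed=0)
        best = min(
            (fac.fit_poisson_factorization(X, K=3, seed=s, max_iter=150)
             for s in range(3)),
            key=lambda m: m.final_deviance,
        )
        assert (np.diff(best.deviance_trace) <= 1e-6).all()
        assert matched_loading_correlations(W, best.gene_scores).min() >= 0.8
        assert (best.gene_scores >= 0).all() and (best.cell_scores >= 0).all()

    def test_gene_scores_column_normalized(self):
        X, _, _ = planted_counts(seed=1)
        m = fac.fit_poisson_factorization(X, K=3, seed=0, max_iter=50)
        np.testing.assert_allclose(m.gene_scores.sum(axis=0), 1.0, atol=1e-9)

    def test_zero_rows_rejected(self):
        X = np.ones((5, 5))
        X[2] = 0
        with pytest.raises(ValueError, match="prefilter"):
            fac.fit_poisson_factorization(X, K=2, seed=0)


class TestConsensus:
    def test_recovers_planted_rank_with_provenance(self):
        X, W, _ = planted_counts(G=90, N=250, K=3, seed=2)
        model = fac.consensus_factorize(
            X, K_range=range(2, 6), runs_per_K=3, top_models_per_K=2,
            seed=0, max_iter=80)
        assert model.K == 3
        for prov in model.provenance:
            assert len({m for m, _ in prov}) >= 2
        assert matched_loading_correlations(W, model.gene_scores).min() >= 0.8

    def test_no_recurrence_raises(self):
        rng = np.random.default_rng(0)
        X = rng.poisson(1.0, size=(30, 60)) + 1
        with pytest.raises(ValueError, match="recurrent"):
            fac.consensus_factorize(X, K_range=[2], runs_per_K=2,
                                    top_models_per_K=2, seed=0, max_iter=30,
                                    similarity_threshold=0.999999)


class TestNuisanceFlags:
    def _model(self, top_genes):
        G = 40
        names = np.array([f"g{i}" for i in range(G)], dtype=object)
        W = np.zeros((G, 1))
        W[:len(top_genes), 0] = np.arange(len(top_genes), 0, -1)
        names[:len(top_genes)] = top_genes
        return fac.FactorModel(gene_scores=W, cell_scores=np.zeros((1, 2)),
                               K=1, seed=0, n_iter=0,
                               deviance_trace=np.array([0.0]), gene_names=names)

    def test_ribosomal_strict_boundary(self):
        ribo = [f"RPS{i}" for i in range(11)]
        model = self._model(ribo)
        lists = {"ribosomal": set(ribo)}
        flags = fac.flag_nuisance_factors(model, lists)
        assert flags.loc[0, "nuisance"]  # 11 > 10
        model10 = self._model(ribo[:10])
        flags10 = fac.flag_nuisance_factors(model10, {"ribosomal": set(ribo)})
        assert not flags10.loc[0, "nuisance"]  # exactly 10 is not flagged

    def test_single_hemoglobin_gene_flags(self):
        model = self._model(["HBB"])
        flags = fac.flag_nuisance_factors(model, {"hemoglobin": {"HBB"}})
        assert flags.loc[0, "nuisance"]

    def test_missing_list_warns_and_skips(self):
        model = self._model(["HBB"])
        with pytest.warns(UserWarning, match="heat_shock"):
            flags = fac.flag_nuisance_factors(
                model, {"hemoglobin": set()},
                thresholds={"heat_shock": 1, "hemoglobin": 0})
        assert not flags.loc[0, "nuisance"]


class TestTissueSpecificity:
    @pytest.mark.parametrize("means,expected", [
        ((1.9, 1.0, 1.0), "A"),
        ((1.8, 1.0, 1.0), "A"),  # inclusive: exactly 80% higher selects
        ((1.2, 1.0, 1.0), None),
    ])
    def test_ratio_rule(self, means, expected):
        labels = np.repeat(["A", "B", "C"], 50)
        scores = np.concatenate([np.full(50, m) for m in means])[None, :]
        model = fac.FactorModel(gene_scores=np.zeros((2, 1)), cell_scores=scores,
                                K=1, seed=0, n_iter=0,
                                deviance_trace=np.array([0.0]))
        out = fac.select_tissue_specific_factors(model, labels)
        assert out[0] == expected


class TestCrossLineageModules:
    def test_fisher_threshold_decreases_with_genes(self):
        ts = [fac.fisher_z_threshold(m) for m in (50, 500, 5000)]
        assert ts[0] > ts[1] > ts[2]

    def test_null_pairs_admitted_at_about_five_percent(self):
        rng = np.random.default_rng(0)
        M, F = 2000, 40
        table = pd.DataFrame(rng.normal(size=(M, F)),
                             columns=[f"f{i}" for i in range(F)])
        thr = fac.fisher_z_threshold(M)
        corr = table.corr().to_numpy()
        iu = np.triu_indices(F, 1)
        frac = (np.abs(corr[iu]) > thr).mean()
        n_pairs = len(iu[0])
        ci = 3 * np.sqrt(0.05 * 0.95 / n_pairs)
        assert abs(frac - 0.05) < ci + 0.01

    def test_shared_planted_programs_group_across_lineages(self):
        # two distinct residency-like programs, each shared by three models
        rng = np.random.default_rng(0)
        M = 300
        progs = {
            "resid": rng.gamma(3, 1, size=M) * (rng.random(M) < 0.1),
            "ifn": rng.gamma(3, 1, size=M) * (rng.random(M) < 0.1),
        }
        cols, model_of = {}, {}
        for lin in ("cd4", "cd8", "mac"):
            for pname, p in progs.items():
                cols[f"{lin}_{pname}"] = p + rng.normal(0, 0.05, M).clip(0)
                model_of[f"{lin}_{pname}"] = lin
            cols[f"{lin}_noise"] = rng.gamma(3, 1, size=M) * (rng.random(M) < 0.1)
            model_of[f"{lin}_noise"] = lin
        table = pd.DataFrame(cols)
        assignment, corr, thr = fac.detect_cross_lineage_modules(
            table, model_of, n_modules=2)
        for pname in progs:
            members = [f"{lin}_{pname}" for lin in ("cd4", "cd8", "mac")]
            assert set(members) <= set(assignment.index)
            assert assignment[members].nunique() == 1
        assert (assignment[[f"{lin}_resid" for lin in ("cd4", "cd8", "mac")]].iloc[0]
                != assignment[[f"{lin}_ifn" for lin in ("cd4", "cd8", "mac")]].iloc[0])


class TestAssociation:
    def _scores_meta(self, effect=0.0, seed=0, n_donors=12, cells=40):
        rng = np.random.default_rng(seed)
        donors = np.repeat([f"d{i}" for i in range(n_donors)], cells)
        age = np.repeat(["young", "old"] * (n_donors // 2), cells)
        sex = np.repeat(["M", "F"] * (n_donors // 2), cells)
        n = len(donors)
        base = rng.gamma(2, 1, size=n) + rng.normal(0, 0.2, n)
        scores = np.vstack([
            base + effect * (age == "old"),
            rng.gamma(2, 1, size=n),
        ])
        meta = pd.DataFrame({"donor_id": donors, "age_group": age, "sex": sex})
        model = fac.FactorModel(gene_scores=np.zeros((2, 2)), cell_scores=scores,
                                K=2, seed=0, n_iter=0,
                                deviance_trace=np.array([0.0]))
        return model, meta

    def test_planted_effect_detected_with_correct_sign(self):
        hits = 0
        for seed in range(5):
            model, meta = self._scores_meta(effect=1.0, seed=seed)
            res = fac.associate_factors_with_covariate(
                model, meta, fixed=("sex",), tissue_type_key=None)
            row = res.set_index("factor").loc[0]
            if row["adj_p"] < 0.05 and row["coef"] > 0:
                hits += 1
        assert hits >= 4

    def test_null_factor_not_flagged(self):
        model, meta = self._scores_meta(effect=0.0, seed=1)
        res = fac.associate_factors_with_covariate(
            model, meta, fixed=("sex",), tissue_type_key=None)
        assert (res["adj_p"] > 0.05).all()


class TestProjection:
    def test_self_projection_consistency(self):
        X, W, H = planted_counts(G=80, N=200, K=3, seed=3)
        model = fac.fit_poisson_factorization(X, K=3, seed=0, max_iter=150)
        proj = fac.project_onto_factors(model, X, seed=0)
        for k in range(3):
            r = np.corrcoef(proj[k], model.cell_scores[k])[0, 1]
            assert r >= 0.9

    def test_all_zero_cell_gets_zero_scores(self):
        X, _, _ = planted_counts(G=80, N=100, K=3, seed=4)
        model = fac.fit_poisson_factorization(X, K=3, seed=0, max_iter=80)
        Xnew = X.copy()
        Xnew[:, 0] = 0
        proj = fac.project_onto_factors(model, Xnew, seed=0)
        assert (proj[:, 0] == 0).all()

    def test_low_overlap_rejected(self):
        X, _, _ = planted_counts(G=80, N=100, K=3, seed=5)
        names = np.array([f"g{i}" for i in range(80)])
        model = fac.fit_poisson_factorization(X, K=3, seed=0, max_iter=50,
                                              gene_names=names)
        with pytest.raises(ValueError, match="overlap"):
            fac.project_onto_factors(model, X[:10], gene_names=names[:10], seed=0)
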
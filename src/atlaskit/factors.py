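"""Poisson matrix factorization with consensus over restarts and ranks.

Gene expression programs are modeled as a nonnegative factorization of the
count matrix under a Poisson likelihood, X[g, c] ~ Poisson((W @ H)[g, c]),
fit by multiplicative updates that monotonically decrease the generalized
Kullback-Leibler deviance (a light-weight stand-in for hierarchical Poisson
factorization; acceptance is planted-structure recovery).  A consensus
model is built by running the factorization several times over a range of
ranks, clustering the resulting gene-score vectors (random-walk community
detection, walktrap-style, with a deterministic agglomerative fallback),
keeping clusters recurrent across at least two models, and refitting from
the cluster medoids.

Downstream utilities flag nuisance factors (heat-shock, ribosomal,
metallothionein, hemoglobin, dissociation-stress gene lists among the top
30 weighted genes), select tissue-specific factors (mean cell score at
least 80% higher in one tissue group than the average of the rest), detect
cross-lineage modules via a Fisher-z correlation threshold, associate
factor cell scores with covariates by mixed models, and project new cells
onto fixed gene scores.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats

from atlaskit.pseudobulk import bh_adjust

logger = logging.getLogger(__name__)

__all__ = [
    "FactorModel",
    "ConsensusFactorModel",
    "prefilter_genes",
    "fit_poisson_factorization",
    "consensus_factorize",
    "flag_nuisance_factors",
    "select_tissue_specific_factors",
    "fisher_z_threshold",
    "detect_cross_lineage_modules",
    "associate_factors_with_covariate",
    "project_onto_factors",
]

#: Coarse tissue types used as fixed covariates in factor-covariate models.
TISSUE_TYPE_MAP = {
    "BLO": "blood_rich", "BM": "blood_rich", "SPL": "blood_rich",
    "LN": "ln", "LNG": "mucosal", "JEJ": "mucosal",
}


@dataclass
class FactorModel:
    """Nonnegative factorization: gene_scores (M x K) @ cell_scores (K x N)."""

    gene_scores: np.ndarray
    cell_scores: np.ndarray
    K: int
    seed: int
    n_iter: int
    deviance_trace: np.ndarray
    gene_names: np.ndarray | None = None

    @property
    def final_deviance(self) -> float:
        return float(self.deviance_trace[-1])


@dataclass
class ConsensusFactorModel(FactorModel):
    provenance: list = field(default_factory=list)  # per factor: [(model_id, col)]
    nuisance_flags: pd.DataFrame | None = None
    tissue_labels: dict = field(default_factory=dict)
    association: pd.DataFrame | None = None

    def validate(self) -> None:
        for prov in self.provenance:
            models = {m for m, _ in prov}
            if len(models) < 2:
                raise ValueError("every consensus factor must cite >= 2 models")


def prefilter_genes(counts, min_cell_fraction: float = 0.01,
                    coding_mask=None) -> np.ndarray:
    """Keep genes detected in at least 1% of cells (and optionally coding)."""
    X = sp.csr_matrix(counts)
    detected = X.getnnz(axis=0) / X.shape[0]
    keep = detected >= min_cell_fraction
    if coding_mask is not None:
        keep &= np.asarray(coding_mask, dtype=bool)
    return keep


def _gkl_deviance(X: sp.csr_matrix, W: np.ndarray, H: np.ndarray) -> float:
    """Generalized KL divergence D(X || WH), computed sparsely."""
    coo = X.tocoo()
    wh_nz = np.einsum("ij,ji->i", W[coo.row], H[:, coo.col])
    wh_nz = np.maximum(wh_nz, 1e-12)
    x = coo.data
    term = np.sum(x * np.log(x / wh_nz) - x)
    return float(term + (W @ H.sum(axis=1)).sum())


def _mu_update(X: sp.csr_matrix, W: np.ndarray, H: np.ndarray):
    """One round of multiplicative updates for generalized-KL NMF."""
    coo = X.tocoo()
    wh_nz = np.maximum(np.einsum("ij,ji->i", W[coo.row], H[:, coo.col]), 1e-12)
    R = sp.coo_matrix((coo.data / wh_nz, (coo.row, coo.col)), shape=X.shape).tocsr()
    W *= (R @ H.T) / np.maximum(np.outer(np.ones(X.shape[0]), H.sum(axis=1)), 1e-12)
    wh_nz = np.maximum(np.einsum("ij,ji->i", W[coo.row], H[:, coo.col]), 1e-12)
    R = sp.coo_matrix((coo.data / wh_nz, (coo.row, coo.col)), shape=X.shape).tocsr()
    H *= (W.T @ R) / np.maximum(np.outer(W.sum(axis=0), np.ones(X.shape[1])), 1e-12)
    return W, H


def fit_poisson_factorization(
    counts,
    K: int,
    seed: int = 0,
    max_iter: int = 200,
    tol: float = 1e-5,
    gene_names=None,
    W_init: np.ndarray | None = None,
    update_gene_scores: bool = True,
) -> FactorModel:
    """Fit Poisson NMF by multiplicative updates on a genes x cells matrix.

    ``counts`` may be cells x genes (the package convention); pass it
    transposed or rely on ``gene_names`` length to disambiguate -- here the
    input is taken as genes x cells when square-ambiguous.  Deviance is
    tracked per iteration and is non-increasing; convergence is a relative
    deviance change below ``tol``.  Gene scores are column-normalized to
    sum 1 (scale fixed into the cell scores).
    """
    if K < 2:
        raise ValueError("K must be >= 2")
    X = sp.csr_matrix(counts, dtype=float)
    if X.getnnz(axis=1).min() == 0 or X.getnnz(axis=0).min() == 0:
        raise ValueError(
            "all-zero gene or cell rows present; prefilter with prefilter_genes"
        )
    G, N = X.shape
    rng = np.random.default_rng(seed)
    scale = np.sqrt(X.sum() / (G * N * K))
    W = W_init.copy() if W_init is not None else rng.gamma(1.0, scale, size=(G, K))
    H = rng.gamma(1.0, scale, size=(K, N))
    W = np.maximum(W, 1e-10)

    trace = [_gkl_deviance(X, W, H)]
    for it in range(max_iter):
        if update_gene_scores:
            W, H = _mu_update(X, W, H)
        else:
            coo = X.tocoo()
            wh_nz = np.maximum(np.einsum("ij,ji->i", W[coo.row], H[:, coo.col]), 1e-12)
            R = sp.coo_matrix((coo.data / wh_nz, (coo.row, coo.col)), shape=X.shape).tocsr()
            H *= (W.T @ R) / np.maximum(np.outer(W.sum(axis=0), np.ones(N)), 1e-12)
        d = _gkl_deviance(X, W, H)
        trace.append(d)
        if abs(trace[-2] - d) / max(abs(trace[-2]), 1e-12) < tol:
            break
    # fixed normalization: gene-score columns sum to 1
    col = W.sum(axis=0)
    col[col == 0] = 1.0
    W = W / col
    H = H * col[:, None]
    return FactorModel(
        gene_scores=W, cell_scores=H, K=K, seed=seed, n_iter=len(trace) - 1,
        deviance_trace=np.asarray(trace),
        gene_names=None if gene_names is None else np.asarray(gene_names),
    )


def _walktrap_communities(sim: np.ndarray, threshold: float) -> list:
    """Random-walk community detection on the thresholded similarity graph."""
    edges = []
    weights = []
    n = sim.shape[0]
    for i in range(n):
        for j in range(i + 1, n):
            if sim[i, j] > threshold:
                edges.append((i, j))
                weights.append(sim[i, j])
    try:
        import igraph as ig

        g = ig.Graph(n=n, edges=edges)
        g.es["weight"] = weights
        comms = g.community_walktrap(weights="weight").as_clustering()
        return [list(c) for c in comms]
    except ImportError:  # deterministic agglomerative fallback
        import scipy.cluster.hierarchy as sch

        adj = np.zeros((n, n))
        for (i, j), w in zip(edges, weights):
            adj[i, j] = adj[j, i] = w
        D = 1 - np.clip(sim, -1, 1)
        np.fill_diagonal(D, 0.0)
        from scipy.spatial.distance import squareform

        Z = sch.linkage(squareform(D, checks=False), method="average")
        labels = sch.fcluster(Z, t=1 - threshold, criterion="distance")
        return [np.flatnonzero(labels == c).tolist() for c in np.unique(labels)]


def consensus_factorize(
    counts,
    K_range=range(15, 31),
    runs_per_K: int = 5,
    top_models_per_K: int = 3,
    seed: int = 0,
    similarity_threshold: float = 0.6,
    max_iter: int = 150,
    tol: float = 1e-5,
    gene_names=None,
) -> ConsensusFactorModel:
    """Consensus Poisson factorization over repeated fits at several ranks.

    For each K, ``runs_per_K`` fits are ranked by final deviance and the top
    ``top_models_per_K`` retained.  Factors (gene-score columns) from all
    retained models form a similarity graph (Pearson correlation above
    ``similarity_threshold``); communities with members from at least two
    distinct models become consensus factors, whose medoid gene-score
    vectors seed a final refit at the consensus rank.
    """
    X = sp.csr_matrix(counts, dtype=float)
    rng = np.random.default_rng(seed)
    kept = []  # (model_id, FactorModel)
    model_id = 0
    for K in K_range:
        fits = []
        for _ in range(runs_per_K):
            s = int(rng.integers(2 ** 31))
            fits.append(fit_poisson_factorization(
                X, K, seed=s, max_iter=max_iter, tol=tol))
        fits.sort(key=lambda m: m.final_deviance)
        for m in fits[:top_models_per_K]:
            kept.append((model_id, m))
            model_id += 1

    cols = []
    owners = []
    for mid, m in kept:
        for k in range(m.K):
            cols.append(m.gene_scores[:, k])
            owners.append((mid, k))
    F = np.column_stack(cols)
    sim = np.corrcoef(F.T)
    comms = _walktrap_communities(sim, similarity_threshold)

    clusters = []
    for c in comms:
        models_in = {owners[i][0] for i in c}
        if len(models_in) >= 2:
            clusters.append(c)
    if not clusters:
        raise ValueError(
            "no recurrent factor clusters found; widen K_range or lower "
            "similarity_threshold"
        )

    medoid_cols = []
    provenance = []
    for c in clusters:
        submat = sim[np.ix_(c, c)]
        medoid = c[int(np.argmax(submat.sum(axis=1)))]
        medoid_cols.append(F[:, medoid])
        provenance.append([owners[i] for i in c])
    W0 = np.column_stack(medoid_cols)
    W0 = W0 * (X.sum() / max(W0.sum(), 1e-12))  # rescale to data magnitude
    final = fit_poisson_factorization(
        X, K=len(clusters), seed=int(rng.integers(2 ** 31)),
        max_iter=max_iter, tol=tol, W_init=np.maximum(W0, 1e-10),
    )
    model = ConsensusFactorModel(
        gene_scores=final.gene_scores,
        cell_scores=final.cell_scores,
        K=final.K,
        seed=seed,
        n_iter=final.n_iter,
        deviance_trace=final.deviance_trace,
        gene_names=None if gene_names is None else np.asarray(gene_names),
        provenance=provenance,
    )
    model.validate()
    return model


NUISANCE_THRESHOLDS = {
    "heat_shock": 1,
    "ribosomal": 10,
    "metallothionein": 1,
    "hemoglobin": 0,
    "stress": 7,
}


def flag_nuisance_factors(
    model: FactorModel,
    nuisance_lists: dict,
    top_n: int = 30,
    thresholds: dict | None = None,
) -> pd.DataFrame:
    """Flag factors whose top genes are dominated by nuisance gene lists.

    A factor is flagged when, among its ``top_n`` genes by gene score, the
    number belonging to a list strictly exceeds that list's threshold
    (heat-shock > 1, ribosomal > 10, metallothionein > 1, hemoglobin > 0,
    dissociation-stress > 7).
    """
    if model.gene_names is None:
        raise ValueError("model needs gene_names for nuisance flagging")
    thresholds = dict(NUISANCE_THRESHOLDS if thresholds is None else thresholds)
    rows = []
    for k in range(model.K):
        top = model.gene_names[np.argsort(-model.gene_scores[:, k])[:top_n]]
        top_set = set(top)
        rec = {"factor": k}
        flagged = False
        for name, thr in thresholds.items():
            if name not in nuisance_lists:
                warnings.warn(f"nuisance list {name!r} missing; rule skipped")
                continue
            count = len(top_set & set(nuisance_lists[name]))
            rec[f"n_{name}"] = count
            if count > thr:
                flagged = True
        rec["nuisance"] = flagged
        rows.append(rec)
    return pd.DataFrame(rows)


def select_tissue_specific_factors(
    model: FactorModel,
    tissue_labels,
    ratio: float = 1.8,
    exclude=(),
) -> dict:
    """Label factors whose mean cell score is >= ``ratio`` x the mean of the
    other tissue groups (inclusive boundary: exactly 80% higher selects).

    Returns {factor index: tissue group or None}.
    """
    labels = np.asarray(tissue_labels)
    groups = [g for g in pd.unique(labels)]
    counts = {g: (labels == g).sum() for g in groups}
    groups = [g for g in groups if counts[g] > 0]
    if len(groups) < 2:
        raise ValueError("need >= 2 tissue groups with cells")
    out = {}
    for k in range(model.K):
        if k in exclude:
            out[k] = None
            continue
        means = {g: model.cell_scores[k, labels == g].mean() for g in groups}
        out[k] = None
        for g in groups:
            others = [means[h] for h in groups if h != g]
            if means[g] >= ratio * np.mean(others):
                out[k] = g
                break
    return out


def fisher_z_threshold(n_genes: int, ci: float = 0.95) -> float:
    """Two-sided null bound for a Pearson r with M gene pairs (Fisher z)."""
    if n_genes <= 3:
        raise ValueError("need more than 3 genes")
    z = stats.norm.ppf(1 - (1 - ci) / 2)
    return float(np.tanh(z / np.sqrt(n_genes - 3)))


def detect_cross_lineage_modules(
    gene_score_table: pd.DataFrame,
    model_of_factor: dict,
    correlation_ci: float = 0.95,
    min_partners: int = 2,
    n_modules: int = 2,
):
    """Group factors from different models into shared gene modules.

    ``gene_score_table`` is genes x factors (columns = factor names);
    ``model_of_factor`` maps factor name -> source model id.  Pairwise
    Pearson correlations above the Fisher-z two-sided ``correlation_ci``
    bound define partners; factors with at least ``min_partners`` partners
    are retained and Ward-clustered (Euclidean distance of correlation
    rows) into ``n_modules`` modules.

    Returns ``(module assignment Series, retained correlation matrix,
    threshold)``; the assignment is empty when fewer than 3 factors are
    retained.
    """
    M = len(gene_score_table)
    thr = fisher_z_threshold(M, correlation_ci)
    corr = gene_score_table.corr()
    partners = (corr > thr).sum(axis=0) - 1  # exclude self-correlation
    retained = partners[partners >= min_partners].index
    if len(retained) < 3:
        return pd.Series(dtype=int), corr.loc[retained, retained], thr
    sub = corr.loc[retained, retained]
    import scipy.cluster.hierarchy as sch

    Z = sch.linkage(sub.to_numpy(), method="ward", metric="euclidean")
    labels = sch.fcluster(Z, t=min(n_modules, len(retained)), criterion="maxclust")
    assignment = pd.Series(labels, index=retained, name="module")
    # report whether modules mix lineages/models
    return assignment, sub, thr


def associate_factors_with_covariate(
    model: FactorModel,
    cell_meta: pd.DataFrame,
    covariate: str = "age_group",
    fixed=("chemistry", "sex", "site", "cmv"),
    random_effect: str = "donor_id",
    tissue_type_key: str | None = "tissue_group",
    reference_level=None,
) -> pd.DataFrame:
    """Mixed-model association of factor cell scores with a covariate.

    Per factor: score ~ covariate + fixed covariates (+ two tissue-type
    dummies, mucosal and LN vs blood-rich) with a donor random intercept.
    Returns coefficient, p and BH-adjusted p per factor, plus
    covariate-adjusted (partial-regression) cell scores: the covariate's
    fitted contribution plus the residual.
    """
    import statsmodels.api as sm

    meta = cell_meta.reset_index(drop=True)
    cov_vals = meta[covariate].astype(str)
    levels = sorted(cov_vals.unique())
    if len(levels) != 2:
        raise ValueError("covariate must be binary")
    if reference_level is None:
        # positive coefficient = higher in the non-reference (e.g. older) group
        reference_level = "young" if "young" in levels else levels[0]
    ind = (cov_vals != reference_level).to_numpy(float)

    cols = [np.ones(len(meta)), ind]
    names = ["intercept", covariate]
    for cov in fixed:
        if cov not in meta.columns or meta[cov].nunique() < 2:
            continue
        for lv in sorted(meta[cov].astype(str).unique())[1:]:
            cols.append((meta[cov].astype(str) == lv).to_numpy(float))
            names.append(f"{cov}[{lv}]")
    if tissue_type_key and tissue_type_key in meta.columns:
        ttype = meta[tissue_type_key].map(TISSUE_TYPE_MAP).fillna("blood_rich")
        for lv in ("mucosal", "ln"):
            if (ttype == lv).any():
                cols.append((ttype == lv).to_numpy(float))
                names.append(f"tissue_type[{lv}]")
    X = np.column_stack(cols)
    keep = [0, 1]
    for j in range(2, X.shape[1]):
        if np.linalg.matrix_rank(X[:, keep + [j]]) == len(keep) + 1:
            keep.append(j)
    X = X[:, keep]
    groups = meta[random_effect].to_numpy()

    rows = []
    adjusted = {}
    for k in range(model.K):
        y = model.cell_scores[k]
        method = "mixed"
        ok = False
        for optimizer in ("lbfgs", None):  # None = statsmodels default
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    mod = sm.MixedLM(y, X, groups=groups)
                    res = (mod.fit(reml=True, method=optimizer, maxiter=100)
                           if optimizer else mod.fit(reml=True))
                coef = res.fe_params[1]
                pval = res.pvalues[1]
                fitted = res.fittedvalues
                ok = np.isfinite(coef) and np.isfinite(pval)
            except Exception:
                ok = False
            if ok:
                break
        if not ok:
            # boundary donor variance (or singular fit): fixed-effects fallback
            method = "ols"
            try:
                res = sm.OLS(y, X).fit()
                coef = res.params[1]
                pval = res.pvalues[1]
                fitted = res.fittedvalues
                ok = np.isfinite(coef) and np.isfinite(pval)
            except Exception:
                ok = False
        if not ok:
            rows.append({"factor": k, "coef": np.nan, "p_value": np.nan,
                         "method": method, "skipped": True})
            continue
        adjusted[k] = X[:, 1] * coef + (y - fitted)
        rows.append({"factor": k, "coef": float(coef),
                     "p_value": float(pval), "method": method,
                     "skipped": False})
    out = pd.DataFrame(rows)
    out["adj_p"] = bh_adjust(out["p_value"].to_numpy())
    out.attrs["adjusted_scores"] = pd.DataFrame(adjusted)
    out.attrs["reference_level"] = reference_level
    return out


def project_onto_factors(
    model: FactorModel,
    new_counts,
    gene_names=None,
    seed: int = 0,
    max_iter: int = 150,
    tol: float = 1e-5,
    min_overlap: float = 0.5,
) -> np.ndarray:
    """Cell scores for new cells with gene scores held fixed.

    ``new_counts`` is genes x cells on the model's gene universe; when
    ``gene_names`` is given, genes are matched by name and the overlap must
    cover at least ``min_overlap`` of the model's genes.
    """
    X = sp.csr_matrix(new_counts, dtype=float)
    W = model.gene_scores
    if gene_names is not None and model.gene_names is not None:
        idx = pd.Index(gene_names).get_indexer(model.gene_names)
        found = idx >= 0
        if found.mean() < min_overlap:
            raise ValueError(
                f"gene overlap {found.mean():.0%} below floor {min_overlap:.0%}"
            )
        logger.info("projecting with %.0f%% gene overlap", 100 * found.mean())
        rows = idx[found]
        X = X[rows]
        W = W[found]
    nonzero = np.asarray(X.sum(axis=0)).ravel() > 0
    H = np.zeros((model.K, X.shape[1]))
    if nonzero.any():
        W_init = np.maximum(W, 1e-10)
        sub = sp.csr_matrix(X[:, nonzero])
        fit = fit_poisson_factorization(
            sub, K=model.K, seed=seed, max_iter=max_iter, tol=tol,
            W_init=W_init, update_gene_scores=False,
        )
        # the fit normalizes gene-score columns to sum 1 and folds the scale
        # into the cell scores; divide it back out so scores are on the scale
        # of the model's (fixed) gene scores
        col = W_init.sum(axis=0)
        H[:, nonzero] = fit.cell_scores / col[:, None]
    return H
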
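"""Counterfactual effect-module discovery from per-cell predicted log2FC.

Input is an :class:`EffectMatrix`: a dense cells x genes matrix of per-cell
predicted log2 fold changes for one covariate (for example, the decoded
old-vs-young effect from a multi-resolution variational model) together
with a cell embedding for neighborhood operations.  The pipeline filters
weakly expressed / weakly affected genes, smooths effects over a kNN
affinity graph, spectrally co-clusters cells x genes into a module grid,
scores each cell against module markers, picks a module-positive cutoff by
Youden's J and transfers it to other tissues, and validates modules by
relaxed pseudobulk differential expression plus marker-set enrichment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "EffectMatrix",
    "ModuleAssignment",
    "filter_effect_genes",
    "smooth_effects",
    "cocluster_effects",
    "score_modules",
    "youden_cutoff",
    "youden_cutoff_and_transfer",
    "gene_threshold_mask",
    "validate_module",
]


@dataclass
class EffectMatrix:
    """Per-cell x per-gene predicted log2FC for one covariate."""

    effects: np.ndarray  # cells x genes
    embedding: np.ndarray  # cells x d
    gene_names: np.ndarray
    raw_mean_expr: np.ndarray  # per gene, raw-count mean expression
    cell_sample_counts: np.ndarray  # per cell: number of samples it appears in

    def __post_init__(self) -> None:
        self.effects = np.asarray(self.effects, dtype=float)
        self.embedding = np.asarray(self.embedding, dtype=float)
        self.gene_names = np.asarray(self.gene_names)
        self.raw_mean_expr = np.asarray(self.raw_mean_expr, dtype=float)
        self.cell_sample_counts = np.asarray(self.cell_sample_counts)
        if not np.isfinite(self.effects).all():
            raise ValueError("effects must be finite")
        if self.embedding.shape[0] != self.effects.shape[0]:
            raise ValueError("embedding rows must align with effects rows")
        if self.gene_names.shape[0] != self.effects.shape[1]:
            raise ValueError("gene_names must align with effects columns")


@dataclass
class ModuleAssignment:
    """Co-clustering grid plus per-module markers and per-cell scores."""

    gene_labels: np.ndarray  # per filtered gene
    cell_labels: np.ndarray  # per filtered cell
    n_gene_modules: int
    n_cell_modules: int
    markers: dict = field(default_factory=dict)  # module -> DataFrame(gene, mean_lfc)
    scores: pd.DataFrame | None = None  # cells x modules


def filter_effect_genes(
    E: EffectMatrix,
    min_raw_expr: float = 0.01,
    lfc_quantile: float = 0.95,
    lfc_floor: float = 0.1,
    min_samples: int = 3,
) -> EffectMatrix:
    """Drop weakly expressed or weakly affected genes and rare cells.

    Genes are removed when raw mean expression < ``min_raw_expr`` OR the
    95th percentile of |log2FC| across cells falls below ``lfc_floor``;
    cells represented in fewer than ``min_samples`` samples are removed.
    """
    if not 0 < lfc_quantile < 1:
        raise ValueError("lfc_quantile must be in (0, 1)")
    cell_keep = E.cell_sample_counts >= min_samples
    eff = E.effects[cell_keep]
    q = np.quantile(np.abs(eff), lfc_quantile, axis=0)
    gene_keep = (E.raw_mean_expr >= min_raw_expr) & (q >= lfc_floor)
    if not gene_keep.any():
        raise ValueError(
            "all genes removed by effect-gene filters; relax min_raw_expr or lfc_floor"
        )
    return EffectMatrix(
        effects=eff[:, gene_keep],
        embedding=E.embedding[cell_keep],
        gene_names=E.gene_names[gene_keep],
        raw_mean_expr=E.raw_mean_expr[gene_keep],
        cell_sample_counts=E.cell_sample_counts[cell_keep],
    )


def knn_affinity(embedding: np.ndarray, k: int = 15):
    """Row-stochastic kNN affinity (self included among neighbors)."""
    from sklearn.neighbors import NearestNeighbors
    import scipy.sparse as sp

    n = embedding.shape[0]
    if k >= n:
        raise ValueError("k must be smaller than the number of cells")
    nn = NearestNeighbors(n_neighbors=k).fit(embedding)
    A = nn.kneighbors_graph(embedding, mode="connectivity")
    A = sp.csr_matrix(A, dtype=float)
    A = A.multiply(1.0 / A.sum(axis=1))
    return sp.csr_matrix(A)


def smooth_effects(E: EffectMatrix, k: int = 15, scale: float = 2.0) -> EffectMatrix:
    """Neighborhood smoothing: S = scale * A @ effects, A the row-normalized
    kNN affinity over the embedding.

    The default ``scale=2`` applies the affinity-smoothed effects doubled,
    matching the procedure this stage reimplements; set ``scale=1`` for a
    plain average (module scores are threshold-calibrated downstream either
    way).
    """
    A = knn_affinity(E.embedding, k=k)
    S = scale * (A @ E.effects)
    return EffectMatrix(
        effects=np.asarray(S),
        embedding=E.embedding,
        gene_names=E.gene_names,
        raw_mean_expr=E.raw_mean_expr,
        cell_sample_counts=E.cell_sample_counts,
    )


def cocluster_effects(
    E: EffectMatrix,
    n_gene_modules: int = 4,
    n_cell_modules: int = 4,
    seed: int = 0,
    minibatch: bool = True,
) -> ModuleAssignment:
    """Spectral co-clustering of the (smoothed) effect matrix.

    Effects are signed, so the matrix is shifted to nonnegative
    (``X - min``) before the bistochastic normalization the spectral
    method relies on; the shift is rank-preserving per entry and does not
    change the block structure.
    """
    X = E.effects
    if np.allclose(X, X.flat[0]):
        raise ValueError("degenerate constant effect matrix cannot be co-clustered")
    Xs = X - X.min() + 1e-9
    from sklearn.cluster import SpectralBiclustering, SpectralCoclustering

    if n_gene_modules == n_cell_modules:
        model = SpectralCoclustering(
            n_clusters=n_cell_modules, mini_batch=minibatch, random_state=seed
        )
    else:
        model = SpectralBiclustering(
            n_clusters=(n_cell_modules, n_gene_modules),
            mini_batch=minibatch,
            random_state=seed,
        )
    model.fit(Xs)
    return ModuleAssignment(
        gene_labels=np.asarray(model.column_labels_),
        cell_labels=np.asarray(model.row_labels_),
        n_gene_modules=n_gene_modules,
        n_cell_modules=n_cell_modules,
    )


def score_modules(
    assignment: ModuleAssignment,
    E: EffectMatrix,
    score_rule: str = "sum_lfc",
    top_n_markers: int = 50,
) -> ModuleAssignment:
    """Derive module markers and per-cell module scores.

    Markers of module ``m`` are the top ``top_n_markers`` filtered genes
    ranked by |mean log2FC| across cells of cell module ``m`` (sign
    retained; up- and down-regulated genes both qualify).  Scores per cell:

    - ``sum_lfc``: sum of lfc over up-markers minus sum over down-markers;
    - ``weighted_sign_mean``: mean over markers of sign(marker) * lfc.
    """
    if score_rule not in ("sum_lfc", "weighted_sign_mean"):
        raise ValueError(f"unknown score_rule {score_rule!r}")
    reuse = bool(assignment.markers)  # e.g. scoring another tissue's effects
    scores = {}
    gene_pos = {g: i for i, g in enumerate(E.gene_names)}
    for m in range(assignment.n_cell_modules):
        if reuse:
            if m not in assignment.markers:
                continue
            marker_df = assignment.markers[m]
            gidx = np.array([gene_pos[g] for g in marker_df["gene"]])
        else:
            cells = assignment.cell_labels == m
            if not cells.any():
                continue
            mean_lfc = E.effects[cells].mean(axis=0)
            gidx = np.argsort(-np.abs(mean_lfc))[:top_n_markers]
            marker_df = pd.DataFrame({
                "gene": E.gene_names[gidx],
                "mean_lfc": mean_lfc[gidx],
            })
            nonzero = marker_df["mean_lfc"] != 0
            marker_df = marker_df.loc[nonzero.to_numpy()].reset_index(drop=True)
            gidx = gidx[nonzero.to_numpy()]
            if marker_df.empty:  # module with no informative marker: skipped
                continue
            assignment.markers[m] = marker_df
        signs = np.sign(marker_df["mean_lfc"].to_numpy())
        sub = E.effects[:, gidx]
        if score_rule == "sum_lfc":
            scores[m] = sub @ signs
        else:
            scores[m] = (sub * signs).mean(axis=1)
    assignment.scores = pd.DataFrame(scores, index=np.arange(E.effects.shape[0]))
    return assignment


def youden_cutoff(scores: np.ndarray, labels: np.ndarray):
    """Best cutoff by Youden's J over midpoints of sorted unique scores.

    Orientation (whether positives lie above or below the cutoff) is chosen
    to maximize J.  Returns ``(threshold, orientation, J)`` with
    orientation in {"ge", "le"}.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if labels.all() or (~labels).any() is False or not labels.any():
        raise ValueError("Youden cutoff needs both classes in the source")
    uniq = np.unique(scores)
    if uniq.size < 2:
        raise ValueError("scores are constant")
    cuts = (uniq[:-1] + uniq[1:]) / 2
    n_pos = labels.sum()
    n_neg = (~labels).sum()
    best = (-np.inf, None, None)
    for c in cuts:
        for orientation in ("ge", "le"):
            pred = scores >= c if orientation == "ge" else scores <= c
            sens = (pred & labels).sum() / n_pos
            spec = (~pred & ~labels).sum() / n_neg
            J = sens + spec - 1
            if J > best[0]:
                best = (J, float(c), orientation)
    J, thr, orientation = best
    return thr, orientation, float(J)


def youden_cutoff_and_transfer(
    scores_source: np.ndarray,
    labels_source: np.ndarray,
    scores_targets: dict,
):
    """Fit the cutoff on the source tissue, apply unchanged to all targets.

    Returns ``(threshold, orientation, J, masks)`` with one boolean mask
    per target key.
    """
    thr, orientation, J = youden_cutoff(scores_source, labels_source)
    masks = {}
    for key, sc in scores_targets.items():
        sc = np.asarray(sc, dtype=float)
        masks[key] = sc >= thr if orientation == "ge" else sc <= thr
    return thr, orientation, J, masks


def gene_threshold_mask(E: EffectMatrix, gene: str, cutoff: float,
                        below: bool = True) -> np.ndarray:
    """Select cells by one gene's predicted log2FC (e.g. IL17A < -0.05)."""
    idx = np.flatnonzero(E.gene_names == gene)
    if idx.size == 0:
        raise KeyError(f"gene {gene!r} not in effect matrix")
    vals = E.effects[:, idx[0]]
    return vals < cutoff if below else vals > cutoff


def validate_module(
    mask: np.ndarray,
    matrix,
    marker_genes,
    n_perm: int = 200,
    seed: int = 0,
):
    """Relaxed pseudobulk age DE on module-positive cells + marker GSEA.

    Pseudobulk samples need at least 5 module-positive cells and 1,000
    total counts; genes need at least 3 total counts.  The marker gene set
    is then tested by pre-ranked GSEA against the log2FC ranking.

    Returns ``(DEResult table, EnrichmentResult)`` or ``(None, None)`` when
    fewer than two donors per age arm carry module-positive cells.
    """
    from atlaskit.pseudobulk import (
        fit_differential_expression,
        filter_pseudobulk,
        pseudobulk_aggregate,
    )
    from atlaskit.signatures import gsea_preranked

    mask = np.asarray(mask, dtype=bool)
    sub_meta = matrix.cell_meta.loc[mask]
    donors_per_arm = sub_meta.groupby("age_group", observed=True)["donor_id"].nunique()
    if len(donors_per_arm) < 2 or (donors_per_arm < 2).any():
        return None, None

    import scipy.sparse as sp

    from atlaskit.core import CellMatrix

    sub = CellMatrix(
        gex_counts=sp.csr_matrix(matrix.gex_counts[mask]),
        cell_meta=sub_meta.reset_index(drop=True),
        gene_meta=matrix.gene_meta,
    )
    table = pseudobulk_aggregate(sub, unit_key=None)
    table = filter_pseudobulk(
        table, min_cells=5, min_counts=1000, gene_min_count=3,
        gene_min_fraction=0.0, gene_total_mode=True, min_samples_per_arm=2,
        arm_key="age_group",
    )
    de = fit_differential_expression(table, contrast=("age_group", "old", "young"))
    if de is None or de.empty:
        return None, None
    ranking = de.set_index("gene")["log2fc"]
    markers = [g for g in marker_genes if g in ranking.index]
    if not markers:
        return de, None
    enr = gsea_preranked(ranking, markers, n_perm=n_perm, seed=seed)
    return de, enr
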
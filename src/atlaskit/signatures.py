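"""Tissue signature genes, gene clusters, pre-ranked GSEA and
composition-vs-expression disentanglement.

Lineage-level DE across tissues yields signature genes (adjusted p < 0.05,
log2FC > 1, average expression > 2 in at least one tissue x lineage
combination); their per-combination mean expression is z-scored per gene
and Ward/Euclidean clustered into discrete gene clusters.  Pre-ranked GSEA
(weighted Kolmogorov-Smirnov running sum, gene-label permutation null,
sign-stratified normalization) then tests each cluster against subset-level
DE rankings, and a thresholded heuristic summarizes whether a cluster's
tissue association is driven by subset composition or within-subset
expression.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy import stats

from atlaskit.core import downsample_equal_depth, normalize_counts
from atlaskit.pseudobulk import bh_adjust

__all__ = [
    "GeneClusterSet",
    "EnrichmentResult",
    "select_signature_genes",
    "cluster_signature_genes",
    "gsea_preranked",
    "gsea_table",
    "summarize_composition_vs_expression",
    "adt_differential",
]


@dataclass
class GeneClusterSet:
    clusters: dict  # cluster id -> list of genes
    zmatrix: pd.DataFrame  # gene x (tissue, lineage) z-scores
    linkage: np.ndarray

    def __post_init__(self) -> None:
        all_genes = [g for gs in self.clusters.values() for g in gs]
        if len(all_genes) != len(set(all_genes)):
            raise ValueError("clusters must partition the genes")
        if any(len(gs) == 0 for gs in self.clusters.values()):
            raise ValueError("empty cluster")


@dataclass
class EnrichmentResult:
    term: str
    es: float
    nes: float
    p_value: float
    fdr_q: float
    leading_edge: list = field(default_factory=list)
    size: int = 0
    subset: str | None = None
    tissue_group: str | None = None


def mean_expression_by_group(table, unit_key: str = "lineage") -> dict:
    """Per-(tissue, unit) mean log2-CPM from a pseudobulk table."""
    from atlaskit.pseudobulk import log2_cpm

    Y = log2_cpm(table.counts)
    out = {}
    meta = table.sample_meta
    for (tg, unit), grp in meta.groupby(["tissue_group", unit_key], observed=True):
        rows = grp.index.to_numpy()
        out[(tg, unit)] = pd.Series(Y[rows].mean(axis=0),
                                    index=table.counts.columns)
    return out


def select_signature_genes(
    lineage_de: dict,
    mean_expr: dict | None = None,
    adj_p_max: float = 0.05,
    min_log2fc: float = 1.0,
    min_ave_expr: float = 2.0,
) -> pd.DataFrame:
    """Signature genes from lineage-level one-vs-rest DE across tissues.

    ``lineage_de`` maps (tissue, lineage) -> DEResult table.  A gene is
    selected when it passes all three thresholds (adjusted p, log2FC,
    average expression) in at least one combination.  The returned matrix
    holds per-combination mean expression -- from ``mean_expr`` (as built
    by :func:`mean_expression_by_group`, keys matching ``lineage_de``) when
    given, otherwise the DE tables' ``ave_expr`` -- z-scored per gene
    (mean 0, sd 1 across combinations).
    """
    selected = set()
    expr = {}
    for key, de in lineage_de.items():
        de = de.set_index("gene")
        hits = de[(de["adj_p"] < adj_p_max)
                  & (de["log2fc"] > min_log2fc)
                  & (de["ave_expr"] > min_ave_expr)]
        selected.update(hits.index)
        expr[key] = mean_expr[key] if mean_expr is not None else de["ave_expr"]
    if not selected:
        raise ValueError(
            "no genes pass the signature thresholds; consider relaxing "
            f"adj_p_max={adj_p_max}, min_log2fc={min_log2fc}, "
            f"min_ave_expr={min_ave_expr}"
        )
    mat = pd.DataFrame(expr).loc[sorted(selected)].dropna()
    z = mat.sub(mat.mean(axis=1), axis=0)
    sd = mat.std(axis=1, ddof=0).replace(0, 1.0)
    return z.div(sd, axis=0)


def cluster_signature_genes(zmatrix: pd.DataFrame, n_clusters: int) -> GeneClusterSet:
    """Ward/Euclidean agglomerative clustering cut to exactly n_clusters."""
    if n_clusters < 2:
        raise ValueError("n_clusters must be >= 2")
    if len(zmatrix) < n_clusters:
        raise ValueError("fewer genes than requested clusters")
    Z = sch.linkage(zmatrix.to_numpy(), method="ward", metric="euclidean")
    labels = sch.fcluster(Z, t=n_clusters, criterion="maxclust")
    clusters = {
        int(c): zmatrix.index[labels == c].tolist() for c in np.unique(labels)
    }
    return GeneClusterSet(clusters=clusters, zmatrix=zmatrix, linkage=Z)


# ---------------------------------------------------------------------------
# Pre-ranked GSEA
# ---------------------------------------------------------------------------

def _running_es(scores_sorted: np.ndarray, hit: np.ndarray, weight: float):
    """Weighted-KS running-sum enrichment score on a pre-sorted ranking."""
    n = scores_sorted.size
    n_hit = int(hit.sum())
    w = np.abs(scores_sorted) ** weight
    w_hit = np.where(hit, w, 0.0)
    denom_hit = w_hit.sum()
    if denom_hit == 0:  # all hit scores zero: fall back to unweighted
        w_hit = hit.astype(float)
        denom_hit = n_hit
    p_hit = np.cumsum(w_hit) / denom_hit
    p_miss = np.cumsum(~hit) / max(n - n_hit, 1)
    run = p_hit - p_miss
    i = int(np.argmax(np.abs(run)))
    return float(run[i]), i, run


def gsea_preranked(
    ranking: pd.Series,
    gene_set,
    n_perm: int = 1000,
    seed: int = 0,
    weight: float = 1.0,
    term: str = "set",
) -> EnrichmentResult:
    """Pre-ranked GSEA of one gene set against a gene -> score ranking.

    The enrichment score is the extremum of the weighted KS running sum on
    the ranking sorted by decreasing score.  The null is gene-label
    permutation (random sets of the same size); NES normalizes ES by the
    mean |null ES| of the same sign, and the nominal p is the same-sign
    null exceedance fraction.  The leading edge is the set members at or
    before (after, for negative ES) the running-sum extremum.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    ranking = ranking.dropna()
    genes = ranking.index.to_numpy()
    members = set(gene_set) & set(genes)
    if not members:
        raise ValueError("gene set has no overlap with the ranking")
    order = np.argsort(-ranking.to_numpy(), kind="stable")
    scores = ranking.to_numpy()[order]
    names = genes[order]
    hit = np.isin(names, list(members))
    es, i_ext, _ = _running_es(scores, hit, weight)

    rng = np.random.default_rng(seed)
    n = scores.size
    k = int(hit.sum())
    null = np.empty(n_perm)
    for b in range(n_perm):
        idx = rng.choice(n, k, replace=False)
        h = np.zeros(n, dtype=bool)
        h[idx] = True
        null[b], _, _ = _running_es(scores, h, weight)
    same = null[np.sign(null) == np.sign(es)] if es != 0 else null
    if same.size == 0:
        nes = 0.0
        p = 1.0 / (n_perm + 1)
    else:
        nes = es / np.mean(np.abs(same))
        p = (np.sum(np.abs(same) >= abs(es)) + 1) / (same.size + 1)

    if es >= 0:
        lead = names[: i_ext + 1][hit[: i_ext + 1]].tolist()
    else:
        lead = names[i_ext:][hit[i_ext:]].tolist()
    return EnrichmentResult(
        term=term, es=es, nes=float(nes), p_value=float(p), fdr_q=float(p),
        leading_edge=lead, size=k,
    )


def gsea_table(ranking: pd.Series, gene_sets: dict, n_perm: int = 1000,
               seed: int = 0, weight: float = 1.0) -> pd.DataFrame:
    """GSEA over several terms with BH FDR across terms."""
    results = []
    for j, (term, gs) in enumerate(gene_sets.items()):
        res = gsea_preranked(ranking, gs, n_perm=n_perm, seed=seed + j,
                             weight=weight, term=term)
        results.append(res)
    q = bh_adjust(np.array([r.p_value for r in results]))
    rows = []
    for r, qv in zip(results, q):
        r.fdr_q = float(qv)
        rows.append({
            "Term": r.term, "ES": r.es, "NES": r.nes, "NOM p-val": r.p_value,
            "FDR q-val": r.fdr_q, "Lead_genes": ";".join(r.leading_edge),
            "size": r.size,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Composition vs expression disentanglement
# ---------------------------------------------------------------------------

def summarize_composition_vs_expression(
    cluster_genes,
    matrix,
    lineage: str,
    enrichments: pd.DataFrame | None = None,
    freq_lfc_min: float = 1.0,
    expr_shift_max: float = 0.25,
    freq_lfc_small: float = 0.5,
    nes_q_max: float = 0.05,
) -> pd.DataFrame:
    """Per subset x tissue evidence for a gene cluster's tissue association.

    Emits, for every subset of the lineage in every tissue group: the mean
    within-lineage subset frequency, the log2 fold change of that frequency
    versus the other tissues, the mean normalized cluster expression within
    the subset in-tissue versus out-of-tissue, and (if provided) the GSEA
    NES/q for the cluster in the subset-level DE.  Flags:

    - composition-driven: frequency log2FC >= ``freq_lfc_min`` and
      within-subset expression shift < ``expr_shift_max`` (log2);
    - expression-driven: significant positive enrichment
      (q < ``nes_q_max``) with frequency log2FC < ``freq_lfc_small``.

    The thresholds are explicit artifact heuristics (the underlying
    evidence is always emitted).
    """
    meta = matrix.cell_meta
    lin_mask = (meta["lineage"] == lineage).to_numpy()
    gidx = matrix.gene_index([g for g in cluster_genes
                              if g in set(matrix.gene_meta["symbol"])])
    norm = normalize_counts(matrix.gex_counts)
    cluster_expr = np.asarray(norm.values[:, gidx].mean(axis=1)).ravel()

    # within-lineage frequencies per donor x tissue
    sub = meta.loc[lin_mask, ["donor_id", "tissue_group", "subset"]].copy()
    counts = (sub.groupby(["donor_id", "tissue_group", "subset"], observed=True)
              .size().rename("n").reset_index())
    totals = counts.groupby(["donor_id", "tissue_group"], observed=True)["n"].transform("sum")
    counts["freq"] = counts["n"] / totals

    rows = []
    for subset in sorted(sub["subset"].unique()):
        for tg in sorted(meta["tissue_group"].unique()):
            f_in = counts.loc[(counts["subset"] == subset)
                              & (counts["tissue_group"] == tg), "freq"].mean()
            f_out = counts.loc[(counts["subset"] == subset)
                               & (counts["tissue_group"] != tg), "freq"].mean()
            f_in = 0.0 if np.isnan(f_in) else f_in
            f_out = 0.0 if np.isnan(f_out) else f_out
            freq_lfc = np.log2((f_in + 1e-4) / (f_out + 1e-4))
            cell_in = lin_mask & (meta["subset"] == subset).to_numpy() \
                & (meta["tissue_group"] == tg).to_numpy()
            cell_out = lin_mask & (meta["subset"] == subset).to_numpy() \
                & (meta["tissue_group"] != tg).to_numpy()
            e_in = cluster_expr[cell_in].mean() if cell_in.any() else np.nan
            e_out = cluster_expr[cell_out].mean() if cell_out.any() else np.nan
            shift = (np.log2(e_in + 1e-3) - np.log2(e_out + 1e-3)
                     if np.isfinite(e_in) and np.isfinite(e_out) else np.nan)
            nes = q = np.nan
            if enrichments is not None:
                hit = enrichments[(enrichments["subset"] == subset)
                                  & (enrichments["tissue_group"] == tg)]
                if len(hit):
                    nes = float(hit["NES"].iloc[0])
                    q = float(hit["FDR q-val"].iloc[0])
            comp_flag = (freq_lfc >= freq_lfc_min
                         and np.isfinite(shift) and abs(shift) < expr_shift_max)
            expr_flag = (np.isfinite(q) and q < nes_q_max and nes > 0
                         and freq_lfc < freq_lfc_small)
            rows.append({
                "subset": subset, "tissue_group": tg,
                "frequency": f_in, "freq_log2fc": freq_lfc,
                "expr_in": e_in, "expr_out": e_out, "expr_shift_log2": shift,
                "NES": nes, "q": q,
                "composition_driven": comp_flag,
                "expression_driven": expr_flag,
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# ADT differential abundance (per-donor Wilcoxon)
# ---------------------------------------------------------------------------

def adt_differential(
    adt_counts,
    marker_names,
    group_labels,
    donor_labels=None,
    per_donor: bool = True,
    min_cells: int = 50,
    min_donors: int = 4,
    seed: int = 0,
) -> pd.DataFrame | None:
    """Per-donor two-group ADT comparison with balancing and Wilcoxon test.

    Within each donor, the two groups are subsampled to equal cell numbers,
    depth-equalized (binomial thinning toward the lower group mean depth),
    log-normalized (scale 1,000), and compared per marker by a two-sided
    Wilcoxon rank-sum test with tie correction.  Donors with fewer than
    ``min_cells`` cells in either group are excluded; the analysis is
    skipped (returns None) when fewer than ``min_donors`` donors remain.
    """
    import scipy.sparse as sp

    X = sp.csr_matrix(adt_counts)
    groups = np.asarray(group_labels)
    arms = pd.unique(groups)
    if arms.size != 2:
        raise ValueError("group_labels must have exactly two levels")
    if not per_donor or donor_labels is None:
        donor_labels = np.zeros(X.shape[0], dtype=int)
        min_donors = 1
    donors = np.asarray(donor_labels)
    rng = np.random.default_rng(seed)

    rows = []
    eligible = 0
    for d in pd.unique(donors):
        dmask = donors == d
        idx_a = np.flatnonzero(dmask & (groups == arms[0]))
        idx_b = np.flatnonzero(dmask & (groups == arms[1]))
        if idx_a.size < min_cells or idx_b.size < min_cells:
            continue
        eligible += 1
        n = min(idx_a.size, idx_b.size)
        idx_a = rng.choice(idx_a, n, replace=False)
        idx_b = rng.choice(idx_b, n, replace=False)
        sel = np.concatenate([idx_a, idx_b])
        sub = X[sel]
        lab = np.repeat([0, 1], n)
        sub = downsample_equal_depth(sub, lab, seed=int(rng.integers(2 ** 31)))
        norm = normalize_counts(sub, scale=1_000.0).toarray()
        for m, name in enumerate(marker_names):
            a, b = norm[:n, m], norm[n:, m]
            stat, p = stats.mannwhitneyu(a, b, alternative="two-sided",
                                         method="asymptotic")
            rows.append({
                "donor": d, "marker": name, "U": float(stat),
                "p_value": float(p), "mean_diff": float(a.mean() - b.mean()),
                "n_per_arm": n,
                "group_one": arms[0], "group_two": arms[1],
            })
    if eligible < min_donors:
        return None
    out = pd.DataFrame(rows)
    if len(out):
        out["adj_p"] = bh_adjust(out["p_value"].to_numpy())
    return out
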
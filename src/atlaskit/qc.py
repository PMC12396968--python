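"""Composite per-cell quality scoring and cluster-level filtering.

A cell's quality score is the plain sum of its doublet probabilities
(Scrublet-style and hashing-based), its erythrocyte-gene fraction (0-1
scale) and a set of 0/1 indicator flags: dual TCR+BCR receptor, predicted
erythrocyte, total counts below 2,000 UMIs, fewer than 1,200 unique genes,
fewer than 200 protein counts, and (optionally) more than 20% mitochondrial
counts.  Clusters of cells -- any labeling; a k-means helper on a provided
embedding is bundled -- are removed when their median score reaches 1.0 or
their mean score reaches 0.3 (per-tissue overridable), unless a rescue rule
matches the cluster's subset/tissue.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["compute_quality_scores", "filter_low_quality_clusters", "kmeans_clusters"]

PROB_COMPONENTS = ("scrublet_prob", "hashsolo_prob", "erythro_fraction")
FLAG_COMPONENTS = ("dual_receptor", "erythro_pred")

UMI_MIN = 2_000
GENES_MIN = 1_200
ADT_MIN = 200
MITO_MAX = 0.20


def compute_quality_scores(
    matrix,
    umi_min: int = UMI_MIN,
    genes_min: int = GENES_MIN,
    adt_min: int = ADT_MIN,
    mito_max: float = MITO_MAX,
    include_mito: bool = True,
) -> pd.DataFrame:
    """Per-cell component table plus additive ``total`` column.

    Requires ``matrix.qc_flags`` to carry the upstream probabilities and
    flags; UMI/gene/ADT totals are computed from the count matrices and the
    mitochondrial fraction from ``qc_flags['mito_frac']`` or an ``is_mito``
    column in ``gene_meta``.
    """
    qc = matrix.qc_flags
    if qc is None:
        raise ValueError("qc_flags table required to compute quality scores")
    missing = [c for c in PROB_COMPONENTS + FLAG_COMPONENTS if c not in qc.columns]
    if missing:
        raise ValueError(f"qc_flags missing required columns: {missing}")

    out = pd.DataFrame(index=np.arange(matrix.n_cells))
    for c in PROB_COMPONENTS:
        vals = qc[c].to_numpy(dtype=float)
        if ((vals < 0) | (vals > 1)).any():
            raise ValueError(f"{c} must be on the 0-1 scale")
        out[c] = vals
    for c in FLAG_COMPONENTS:
        out[c] = qc[c].to_numpy(dtype=float)

    umi = np.asarray(matrix.gex_counts.sum(axis=1)).ravel()
    n_genes = matrix.gex_counts.getnnz(axis=1)
    out["low_umi"] = (umi < umi_min).astype(float)
    out["low_genes"] = (n_genes < genes_min).astype(float)
    if matrix.adt_counts is not None:
        adt_tot = np.asarray(matrix.adt_counts.sum(axis=1)).ravel()
        out["low_adt"] = (adt_tot < adt_min).astype(float)
    else:
        out["low_adt"] = 0.0
    if include_mito:
        if "mito_frac" in qc.columns:
            mito = qc["mito_frac"].to_numpy(dtype=float)
        elif "is_mito" in matrix.gene_meta.columns:
            mito_idx = matrix.gene_meta["is_mito"].to_numpy()
            mito = np.asarray(matrix.gex_counts[:, mito_idx].sum(axis=1)).ravel() / np.maximum(umi, 1)
        else:
            raise ValueError("no mito_frac in qc_flags and no is_mito genes")
        out["high_mito"] = (mito > mito_max).astype(float)
    else:
        out["high_mito"] = 0.0
    out["total"] = out.sum(axis=1)
    return out


def filter_low_quality_clusters(
    scores: pd.DataFrame,
    cluster_labels,
    tissue_group=None,
    subset=None,
    median_cutoff: float = 1.0,
    mean_cutoff: float = 0.3,
    mean_cutoff_overrides: dict | None = None,
    rescue_rules=(),
):
    """Per-cell keep mask removing clusters of low-quality cells.

    A cluster is removed when median(total) >= median_cutoff OR
    mean(total) >= the applicable mean cutoff (per-tissue overrides allowed,
    keyed by the cluster's modal tissue), unless a rescue rule
    ``(subset, tissue)`` matches its modal subset/tissue (tissue ``None``
    matches any tissue).

    Returns ``(keep_mask, audit)`` where audit is a per-cluster table.
    """
    total = np.asarray(scores["total"], dtype=float)
    labels = np.asarray(cluster_labels)
    if labels.shape[0] != total.shape[0]:
        raise ValueError("cluster_labels length must match scores")
    overrides = mean_cutoff_overrides or {}
    tissue_group = None if tissue_group is None else np.asarray(tissue_group)
    subset = None if subset is None else np.asarray(subset)

    known_subsets = set() if subset is None else set(np.unique(subset))
    rules = []
    for rule_subset, rule_tissue in rescue_rules:
        if known_subsets and rule_subset not in known_subsets:
            logger.warning("rescue rule names unknown subset %r; ignored", rule_subset)
            continue
        rules.append((rule_subset, rule_tissue))

    keep = np.ones(total.shape[0], dtype=bool)
    audit_rows = []
    for cl in pd.unique(labels):
        mask = labels == cl
        med = float(np.median(total[mask]))
        mean = float(np.mean(total[mask]))
        modal_tissue = None
        modal_subset = None
        if tissue_group is not None:
            modal_tissue = pd.Series(tissue_group[mask]).mode().iloc[0]
        if subset is not None:
            modal_subset = pd.Series(subset[mask]).mode().iloc[0]
        cutoff = overrides.get(modal_tissue, mean_cutoff)
        flagged = med >= median_cutoff or mean >= cutoff
        rescued = False
        if flagged:
            for rule_subset, rule_tissue in rules:
                if modal_subset == rule_subset and rule_tissue in (None, modal_tissue):
                    rescued = True
                    break
        removed = flagged and not rescued
        if removed:
            keep[mask] = False
        audit_rows.append({
            "cluster": cl, "n_cells": int(mask.sum()), "median_score": med,
            "mean_score": mean, "mean_cutoff_used": cutoff,
            "modal_tissue": modal_tissue, "modal_subset": modal_subset,
            "flagged": flagged, "rescued": rescued, "removed": removed,
        })
    return keep, pd.DataFrame(audit_rows)


def kmeans_clusters(embedding: np.ndarray, n_clusters: int, seed: int = 0) -> np.ndarray:
    """k-means helper for fixtures where no upstream clustering exists."""
    from sklearn.cluster import KMeans

    km = KMeans(n_clusters=n_clusters, n_init=10, random_state=seed)
    return km.fit_predict(np.asarray(embedding))
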
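"""DEG-overlap similarity between aging signatures across subsets/tissues.

Each (subset, tissue) entity contributes an up set (unadjusted p < 0.05,
log2FC > 0.1) and a down set (log2FC < -0.1) drawn from genes above a mean
log-normalized expression floor; entities need more than 70 such DEGs and
at least 3 donors per age arm.  Similarity between entities A and B is the
count of concordant overlaps, (|up_A n up_B| + |down_A n down_B|), divided
by the union of all four sets; distance is 1 - similarity.  Entities with
more than 200 DEGs are Ward.D2-clustered on that distance; 2-D embedding
backends are pluggable and not part of the tested artifact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import squareform

__all__ = ["TrendingSets", "build_trending_sets", "deg_overlap_similarity"]


@dataclass
class TrendingSets:
    """Per-entity up/down trending gene sets with eligibility audit."""

    sets: dict  # entity -> {"up": set, "down": set, "n_degs": int}
    audit: pd.DataFrame

    def __post_init__(self) -> None:
        for ent, rec in self.sets.items():
            if rec["up"] & rec["down"]:
                raise ValueError(f"entity {ent}: up and down sets overlap")


def build_trending_sets(
    de_tables: dict,
    donor_counts: dict | None = None,
    p_max: float = 0.05,
    lfc: float = 0.1,
    min_degs: int = 70,
    min_expr: float = 0.05,
    min_donors: int = 3,
    expr_col: str = "mean_lognorm",
) -> TrendingSets:
    """Trending up/down gene sets per entity from age DE tables.

    ``de_tables`` maps entity -> DE table with gene, p_value, log2fc and a
    mean log-normalized expression column (``expr_col``; falls back to
    ``ave_expr`` if absent -- then ``min_expr`` should be on that scale).
    ``donor_counts`` optionally maps entity -> (donors_young, donors_old);
    entities with an arm below ``min_donors`` are excluded.  The DEG-count
    floor is strict: exactly ``min_degs`` DEGs excludes the entity.
    """
    sets = {}
    audit_rows = []
    for ent, de in de_tables.items():
        rec = {"entity": ent}
        if donor_counts is not None:
            dy, do = donor_counts[ent]
            rec.update(donors_young=dy, donors_old=do)
            if dy < min_donors or do < min_donors:
                rec["excluded"] = "donor floor"
                audit_rows.append(rec)
                continue
        col = expr_col if expr_col in de.columns else "ave_expr"
        expr_ok = de[col] > min_expr
        degs = de.loc[expr_ok & (de["p_value"] < p_max)]
        rec["n_degs"] = len(degs)
        if len(degs) <= min_degs:  # strict "more than 70"
            rec["excluded"] = "deg floor"
            audit_rows.append(rec)
            continue
        up = set(degs.loc[degs["log2fc"] > lfc, "gene"])
        down = set(degs.loc[degs["log2fc"] < -lfc, "gene"])
        sets[ent] = {"up": up, "down": down, "n_degs": len(degs)}
        rec["excluded"] = ""
        audit_rows.append(rec)
    return TrendingSets(sets=sets, audit=pd.DataFrame(audit_rows))


def pair_similarity(a: dict, b: dict) -> float:
    """(|up_A n up_B| + |down_A n down_B|) / |union of all four sets|."""
    union = a["up"] | a["down"] | b["up"] | b["down"]
    if not union:
        return 0.0
    inter = len(a["up"] & b["up"]) + len(a["down"] & b["down"])
    return inter / len(union)


def deg_overlap_similarity(
    trending: TrendingSets,
    cluster_min_degs: int = 200,
):
    """Similarity and distance matrices across entities, plus clustering.

    Entities with empty up and down sets are excluded.  Entities with more
    than ``cluster_min_degs`` DEGs are additionally Ward.D2-clustered on
    the distance matrix; the linkage is returned (None when fewer than 3
    such entities).  Returns ``(similarity df, distance df, linkage,
    clustered entity list)``.
    """
    entities = [e for e, r in trending.sets.items() if r["up"] or r["down"]]
    if len(entities) < 2:
        raise ValueError("need at least 2 eligible entities")
    n = len(entities)
    S = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            s = pair_similarity(trending.sets[entities[i]],
                                trending.sets[entities[j]])
            S[i, j] = S[j, i] = s
    sim = pd.DataFrame(S, index=entities, columns=entities)
    dist = 1.0 - sim

    big = [e for e in entities if trending.sets[e]["n_degs"] > cluster_min_degs]
    linkage = None
    if len(big) >= 3:
        D = dist.loc[big, big].to_numpy()
        linkage = sch.linkage(squareform(D, checks=False), method="ward")
    return sim, dist, linkage, big
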
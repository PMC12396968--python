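"""Clonotype grouping and subsampled clonality (1 - Pielou evenness).

Clonotype calling follows the sequential criteria used for droplet VDJ
data: cells are first partitioned by V gene, J gene and CDR3 length on every
chain, then TCR clones require 100% CDR3 nucleotide identity while BCR
clones link cells whose CDR3 amino-acid sequences are at least 85%
identical (normalized Hamming distance), taking connected components.

Clonality of a cell group is 1 - H_s / H_max where H_s is the Shannon
entropy (bits) of clone frequencies in a 100-cell subsample and
H_max = log2(C) for C unique clonotypes in that subsample.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["ClonalityResult", "clonality_score", "clonality_table", "group_clonotypes"]


def _clonality_of_counts(counts: np.ndarray) -> float:
    """1 - Pielou evenness of a clone-size vector; 1.0 by convention at C=1."""
    counts = np.asarray(counts, dtype=float)
    counts = counts[counts > 0]
    C = counts.size
    if C <= 1:
        return 1.0
    p = counts / counts.sum()
    H = -(p * np.log2(p)).sum()
    return float(1.0 - H / np.log2(C))


@dataclass
class ClonalityResult:
    group: object
    C: float  # mean unique clonotypes per subsample draw
    H_s: float  # mean Shannon entropy (bits)
    H_max: float  # mean log2(C)
    evenness: float
    clonality: float
    n_subsampled: int
    n_draws: int
    seed: int
    degenerate: bool = False  # any draw hit C == 1


def clonality_score(clone_ids, subsample_n: int = 100, n_draws: int = 25,
                    seed: int = 0, group=None) -> ClonalityResult | None:
    """Mean subsampled clonality for one group of cells.

    Draws ``n_draws`` subsamples of ``subsample_n`` cells without
    replacement and averages the clonality of each draw (``n_draws=1``
    reproduces the literal single-subsample procedure).  Groups smaller
    than ``subsample_n`` are skipped (returns None, logged).
    """
    ids = np.asarray(clone_ids)
    if ids.size < subsample_n:
        logger.info("group %s skipped: %d < %d cells", group, ids.size, subsample_n)
        return None
    rng = np.random.default_rng(seed)
    Cs, Hs, Hmaxs, clons = [], [], [], []
    degenerate = False
    for _ in range(n_draws):
        take = rng.choice(ids, size=subsample_n, replace=False)
        _, cnt = np.unique(take, return_counts=True)
        C = cnt.size
        if C == 1:
            degenerate = True
            Cs.append(1.0)
            Hs.append(0.0)
            Hmaxs.append(0.0)
            clons.append(1.0)
            continue
        p = cnt / cnt.sum()
        H = float(-(p * np.log2(p)).sum())
        Cs.append(float(C))
        Hs.append(H)
        Hmaxs.append(float(np.log2(C)))
        clons.append(1.0 - H / np.log2(C))
    clon = float(np.mean(clons))
    return ClonalityResult(
        group=group,
        C=float(np.mean(Cs)),
        H_s=float(np.mean(Hs)),
        H_max=float(np.mean(Hmaxs)),
        evenness=1.0 - clon,
        clonality=clon,
        n_subsampled=subsample_n,
        n_draws=n_draws,
        seed=seed,
        degenerate=degenerate,
    )


def clonality_table(df: pd.DataFrame, group_keys, clone_col: str = "clone_id",
                    subsample_n: int = 100, n_draws: int = 25,
                    seed: int = 0) -> pd.DataFrame:
    """Clonality per group (e.g. donor x subset x tissue); skips small groups."""
    rows = []
    for i, (key, sub) in enumerate(df.groupby(list(group_keys), observed=True)):
        res = clonality_score(
            sub[clone_col].to_numpy(), subsample_n=subsample_n,
            n_draws=n_draws, seed=seed + i, group=key,
        )
        if res is None:
            continue
        rec = dict(zip(group_keys, key if isinstance(key, tuple) else (key,)))
        rec.update({
            "C": res.C, "H_s": res.H_s, "H_max": res.H_max,
            "evenness": res.evenness, "clonality": res.clonality,
            "n_subsampled": res.n_subsampled, "n_draws": res.n_draws,
            "degenerate": res.degenerate,
        })
        rows.append(rec)
    return pd.DataFrame(rows)


def _aa_similarity(a: str, b: str) -> float:
    """Fraction of identical positions (normalized Hamming similarity)."""
    if len(a) != len(b):
        return 0.0
    if not a:
        return 1.0
    same = sum(x == y for x, y in zip(a, b))
    return same / len(a)


def group_clonotypes(contigs: pd.DataFrame, bcr_similarity: float = 0.85) -> pd.Series:
    """Assign a clone id to every cell from a minimal contig table.

    ``contigs`` needs columns cell_id, chain, v_gene, j_gene, cdr3_nt,
    cdr3_aa, receptor (TCR or BCR).  Cells are partitioned by the ordered
    tuple of (chain, V, J, CDR3 aa length) over all their chains; within a
    partition TCR clones require exact CDR3 nucleotide identity on every
    chain, and BCR cells are single-linkage clustered with an edge when
    every chain pair reaches ``bcr_similarity`` amino-acid identity
    (inclusive).

    Records whose nucleotide CDR3 length disagrees with the amino-acid
    length (len(nt) != 3 * len(aa)) are rejected and logged.
    """
    required = {"cell_id", "chain", "v_gene", "j_gene", "cdr3_nt", "cdr3_aa", "receptor"}
    missing = required - set(contigs.columns)
    if missing:
        raise ValueError(f"contig table missing columns: {sorted(missing)}")
    ok = contigs["cdr3_nt"].str.len() == 3 * contigs["cdr3_aa"].str.len()
    if (~ok).any():
        logger.warning("rejected %d malformed contigs (nt/aa length mismatch)", (~ok).sum())
    contigs = contigs[ok]

    # collapse each cell to an ordered chain profile
    per_cell = {}
    for cell_id, grp in contigs.groupby("cell_id"):
        grp = grp.sort_values("chain")
        key = tuple(
            (r.chain, r.v_gene, r.j_gene, len(r.cdr3_aa)) for r in grp.itertuples()
        )
        per_cell[cell_id] = {
            "key": key,
            "nt": tuple(grp["cdr3_nt"]),
            "aa": tuple(grp["cdr3_aa"]),
            "receptor": grp["receptor"].iloc[0],
        }

    clone_of = {}
    clone_counter = 0
    partitions = {}
    for cell_id, rec in per_cell.items():
        partitions.setdefault((rec["receptor"], rec["key"]), []).append(cell_id)

    for (receptor, _key), cells in partitions.items():
        if receptor == "TCR":
            by_nt = {}
            for c in cells:
                by_nt.setdefault(per_cell[c]["nt"], []).append(c)
            for members in by_nt.values():
                for c in members:
                    clone_of[c] = f"clone{clone_counter:05d}"
                clone_counter += 1
        else:  # BCR: single-linkage at >= bcr_similarity on every chain
            n = len(cells)
            parent = list(range(n))

            def find(i):
                while parent[i] != i:
                    parent[i] = parent[parent[i]]
                    i = parent[i]
                return i

            for i in range(n):
                for j in range(i + 1, n):
                    ai, aj = per_cell[cells[i]]["aa"], per_cell[cells[j]]["aa"]
                    if all(_aa_similarity(x, y) >= bcr_similarity
                           for x, y in zip(ai, aj)):
                        parent[find(i)] = find(j)
            roots = {}
            for i, c in enumerate(cells):
                r = find(i)
                if r not in roots:
                    roots[r] = f"clone{clone_counter:05d}"
                    clone_counter += 1
                clone_of[c] = roots[r]

    return pd.Series(clone_of, name="clone_id")
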
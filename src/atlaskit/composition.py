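"""Subset-frequency tabulation, covariate-adjusted shift tests, majority-vote
compositional analysis, and simplified ADT landmark registration.

Frequency shifts (subset proportions within a lineage, BCR isotype shares,
or ADT percent positivity) are tested per subset x tissue by generalized
linear models with donor-level covariates (age group, sex, chemistry, CMV,
processing site); the reported effect size is a covariate-aware log2 fold
change computed from predicted proportions at reference covariate values.
Compositional enrichment uses a reference-robust wrapper: the backend test
is run once per choice of reference subset and a subset is called credible
only when flagged in strictly more than half of the runs.

ADT landmark registration is a two-landmark simplification: per batch and
marker, density peaks are detected and a monotone piecewise-linear warp
maps the negative peak to 0 and the positive peak to 1, preserving
within-batch ranks.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal, stats

from atlaskit.pseudobulk import bh_adjust

logger = logging.getLogger(__name__)

__all__ = [
    "tabulate_subset_frequencies",
    "glm_frequency_shift",
    "majority_vote_composition",
    "alr_backend",
    "RegisteredADT",
    "landmark_register_adt",
    "percent_positive",
]


def tabulate_subset_frequencies(
    cell_meta: pd.DataFrame,
    lineage_key: str = "lineage",
    subset_key: str = "subset",
    min_cells: int = 50,
    min_donors: int = 4,
):
    """Per donor x tissue x subset counts and within-lineage proportions.

    Donor x tissue x lineage combinations with fewer than ``min_cells``
    lineage cells are excluded; subset x tissue units left with fewer than
    ``min_donors`` donors are flagged ineligible.  Returns
    ``(frequency table, audit table)``.
    """
    df = cell_meta[["donor_id", "tissue_group", lineage_key, subset_key]].copy()
    df.columns = ["donor_id", "tissue_group", "lineage", "subset"]
    counts = (df.groupby(["donor_id", "tissue_group", "lineage", "subset"],
                         observed=True).size().rename("n").reset_index())
    lin_tot = counts.groupby(["donor_id", "tissue_group", "lineage"],
                             observed=True)["n"].transform("sum")
    counts["lineage_total"] = lin_tot
    counts["proportion"] = counts["n"] / lin_tot
    eligible = counts["lineage_total"] >= min_cells
    audit_excl = counts.loc[~eligible, ["donor_id", "tissue_group", "lineage"]] \
        .drop_duplicates().assign(reason=f"fewer than {min_cells} lineage cells")
    freq = counts.loc[eligible].reset_index(drop=True)

    donor_counts = (freq.groupby(["subset", "tissue_group"], observed=True)
                    ["donor_id"].nunique().rename("n_donors").reset_index())
    donor_counts["eligible"] = donor_counts["n_donors"] >= min_donors
    freq = freq.merge(donor_counts[["subset", "tissue_group", "eligible"]],
                      on=["subset", "tissue_group"], how="left")
    return freq, {"excluded_samples": audit_excl, "unit_donors": donor_counts}


class _QuasiBinomialFit:
    """Binomial GLM fit with a Pearson overdispersion factor on the SEs.

    Donor-level proportions are overdispersed relative to multinomial
    sampling; the quasi-binomial dispersion phi = X2 / df rescales the
    standard errors (floored at 1 so well-behaved data is unchanged).
    """

    def __init__(self, res, y, totals, X):
        mu = res.predict(X)
        resid2 = (y - totals * mu) ** 2 / np.maximum(totals * mu * (1 - mu), 1e-9)
        df = max(len(y) - X.shape[1], 1)
        self.phi = max(float(resid2.sum() / df), 1.0)
        self.params = res.params
        self.bse = res.bse * np.sqrt(self.phi)


def _fit_binomial_glm(y_counts, totals, X):
    import statsmodels.api as sm

    endog = np.column_stack([y_counts, totals - y_counts])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.GLM(endog, X, family=sm.families.Binomial()).fit(maxiter=100)
    return _QuasiBinomialFit(res, np.asarray(y_counts, float),
                             np.asarray(totals, float), X)


def glm_frequency_shift(
    freq_table: pd.DataFrame,
    response: str = "proportion",
    effect_key: str = "age_group",
    effect_level: str = "old",
    covariates=("sex", "chemistry", "cmv", "site"),
    donor_meta: pd.DataFrame | None = None,
    min_donors: int = 4,
) -> pd.DataFrame:
    """Covariate-adjusted shift test per subset x tissue unit.

    ``response="proportion"`` fits a binomial/logit GLM on (subset count,
    lineage total); ``response="percent"`` fits a Gaussian model on the
    logit of a percent column named ``percent`` (0-100).  The covariate-
    aware log2FC is log2 of the predicted proportion with the effect set to
    ``effect_level`` over the reference, all other covariates at their
    reference (modal) values.  P-values are two-sided Wald; BH across
    units.  Separation or singular fits are skipped and flagged.
    """
    df = freq_table.copy()
    if donor_meta is not None:
        df = df.merge(donor_meta, on="donor_id", how="left")
    needed = [effect_key] + [c for c in covariates if c in df.columns]
    rows = []
    for (subset, tg), unit in df.groupby(["subset", "tissue_group"], observed=True):
        if "eligible" in unit.columns and not unit["eligible"].all():
            continue
        if unit["donor_id"].nunique() < min_donors:
            continue
        ind = (unit[effect_key].astype(str) == effect_level).to_numpy(float)
        if ind.all() or not ind.any():
            continue
        cols = [np.ones(len(unit)), ind]
        for cov in needed[1:]:
            lv = sorted(unit[cov].astype(str).unique())
            for level in lv[1:]:
                cols.append((unit[cov].astype(str) == level).to_numpy(float))
        X = np.column_stack(cols)
        keep = [0, 1]
        for j in range(2, X.shape[1]):
            if np.linalg.matrix_rank(X[:, keep + [j]]) == len(keep) + 1:
                keep.append(j)
        X = X[:, keep]
        skipped = False
        try:
            if response == "proportion":
                res = _fit_binomial_glm(unit["n"].to_numpy(),
                                        unit["lineage_total"].to_numpy(), X)
            elif response == "percent":
                p = np.clip(unit["percent"].to_numpy() / 100.0, 1e-4, 1 - 1e-4)
                y = np.log(p / (1 - p))
                import statsmodels.api as sm
                res = sm.OLS(y, X).fit()
            else:
                raise ValueError(f"unknown response {response!r}")
            coef = res.params[1]
            se = res.bse[1]
            if not np.isfinite(coef) or not np.isfinite(se) or se > 50:
                skipped = True  # separation
        except Exception:
            skipped = True
        if skipped:
            rows.append({"subset": subset, "tissue_group": tg, "skipped": True})
            continue
        z = coef / se
        p = 2 * stats.norm.sf(abs(z))
        # predicted proportions at reference covariates
        x_ref = np.zeros(X.shape[1]); x_ref[0] = 1.0
        x_eff = x_ref.copy(); x_eff[1] = 1.0
        eta0 = float(x_ref @ res.params)
        eta1 = float(x_eff @ res.params)
        p0 = 1 / (1 + np.exp(-eta0))
        p1 = 1 / (1 + np.exp(-eta1))
        rows.append({
            "subset": subset, "tissue_group": tg, "coeff": float(coef),
            "std_error": float(se), "z": float(z), "p_value": float(p),
            "logfc": float(np.log2(p1 / p0)),
            "n_observations": int(len(unit)),
            "donors": ";".join(sorted(unit["donor_id"].astype(str).unique())),
            "skipped": False,
        })
    out = pd.DataFrame(rows)
    if len(out) and "p_value" in out.columns:
        out["adj_p_val"] = bh_adjust(out["p_value"].to_numpy())
    return out


# ---------------------------------------------------------------------------
# Majority-vote compositional analysis
# ---------------------------------------------------------------------------

def alr_backend(counts: pd.DataFrame, grouping: np.ndarray, reference: str,
                fdr: float = 0.05) -> set:
    """Additive-log-ratio linear-model backend: flags shifted subsets.

    For each non-reference subset, regress log((n_s + 0.5)/(n_ref + 0.5))
    per sample on the binary grouping; BH across subsets at ``fdr``.
    """
    import statsmodels.api as sm

    ref = counts[reference].to_numpy(float)
    g = np.asarray(grouping, dtype=float)
    X = np.column_stack([np.ones(len(counts)), g])
    pvals = {}
    for s in counts.columns:
        if s == reference:
            continue
        y = np.log((counts[s].to_numpy(float) + 0.5) / (ref + 0.5))
        res = sm.OLS(y, X).fit()
        pvals[s] = res.pvalues[1]
    subsets = list(pvals)
    adj = bh_adjust(np.array([pvals[s] for s in subsets]))
    return {s for s, q in zip(subsets, adj) if q < fdr}


def majority_vote_composition(
    counts: pd.DataFrame,
    grouping,
    backend=None,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Reference-robust compositional test with strict majority voting.

    ``counts`` is samples x subsets; ``grouping`` a binary per-sample
    factor.  The backend runs once per choice of reference subset; a subset
    is credible iff flagged in strictly more than half of the runs in
    which it was a candidate.  A backend failure on one reference skips
    that run and shrinks the vote denominator.
    """
    if counts.shape[1] < 3:
        raise ValueError("need at least 3 subsets")
    backend = backend or alr_backend
    grouping = np.asarray(grouping)
    flags = {s: 0 for s in counts.columns}
    opportunities = {s: 0 for s in counts.columns}
    for ref in counts.columns:
        try:
            hit = backend(counts, grouping, ref, fdr)
        except Exception as exc:  # pragma: no cover - backend robustness
            logger.warning("backend failed for reference %r: %s", ref, exc)
            continue
        for s in counts.columns:
            if s == ref:
                continue
            opportunities[s] += 1
            if s in hit:
                flags[s] += 1
    rows = []
    for s in counts.columns:
        frac = flags[s] / opportunities[s] if opportunities[s] else 0.0
        rows.append({
            "subset": s, "votes": flags[s], "runs": opportunities[s],
            "vote_fraction": frac, "credible": frac > 0.5,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# ADT landmark registration and percent positivity
# ---------------------------------------------------------------------------

@dataclass
class RegisteredADT:
    """Per-batch piecewise-linear warps and registered marker values."""

    warps: dict  # batch -> (source control points, target control points)
    registered: dict  # batch -> warped values
    threshold: float = 0.5
    flags: dict = field(default_factory=dict)

    def percent_positive_of(self, batch) -> float:
        vals = self.registered[batch]
        return 100.0 * float(np.mean(vals > self.threshold))


def _find_landmarks(values: np.ndarray, max_peaks: int = 2):
    """Up to two most prominent KDE peaks of a marker's distribution."""
    vals = np.asarray(values, dtype=float)
    if np.ptp(vals) < 1e-10:
        return None
    kde = stats.gaussian_kde(vals)
    grid = np.linspace(vals.min() - 0.5, vals.max() + 0.5, 512)
    dens = kde(grid)
    peaks, props = signal.find_peaks(dens, prominence=dens.max() * 0.02)
    if peaks.size == 0:
        peaks = np.array([int(np.argmax(dens))])
        props = {"prominences": np.array([dens.max()])}
    order = np.argsort(-props["prominences"])[:max_peaks]
    locs = np.sort(grid[peaks[order]])
    return locs


def landmark_register_adt(values_by_batch: dict, threshold: float = 0.5
                          ) -> RegisteredADT:
    """Align one marker's negative/positive peaks across batches.

    Two-peak batches get a monotone piecewise-linear warp mapping the
    negative peak to 0 and the positive peak to 1; single-peak batches are
    shifted so their peak sits at 0.  Constant markers get the identity
    warp and are flagged.
    """
    warps = {}
    registered = {}
    flags = {}
    for batch, vals in values_by_batch.items():
        vals = np.asarray(vals, dtype=float)
        locs = _find_landmarks(vals)
        if locs is None:
            warps[batch] = (np.array([0.0, 1.0]), np.array([0.0, 1.0]))
            registered[batch] = vals.copy()
            flags[batch] = "degenerate_constant"
            continue
        if locs.size >= 2:
            src = np.array([locs[0], locs[-1]])
            dst = np.array([0.0, 1.0])
        else:
            src = np.array([locs[0], locs[0] + 1.0])
            dst = np.array([0.0, 1.0])
        slope_lo = (dst[1] - dst[0]) / (src[1] - src[0])
        out = np.interp(vals, src, dst)
        below = vals < src[0]
        above = vals > src[1]
        out[below] = dst[0] + (vals[below] - src[0]) * slope_lo
        out[above] = dst[1] + (vals[above] - src[1]) * slope_lo
        warps[batch] = (src, dst)
        registered[batch] = out
        flags[batch] = "ok" if locs.size >= 2 else "single_peak"
    return RegisteredADT(warps=warps, registered=registered,
                         threshold=threshold, flags=flags)


def percent_positive(
    registered_values: np.ndarray,
    groups: pd.DataFrame,
    threshold: float = 0.5,
    min_cells: int = 50,
) -> pd.DataFrame:
    """Percent of cells above threshold per donor x tissue x subset.

    ``groups`` carries donor_id, tissue_group and subset per cell, aligned
    with ``registered_values``.  Groups below ``min_cells`` are excluded
    with an audit entry.  The output feeds :func:`glm_frequency_shift` with
    ``response="percent"``.
    """
    vals = np.asarray(registered_values, dtype=float)
    df = groups[["donor_id", "tissue_group", "subset"]].copy()
    df["positive"] = (vals > threshold).astype(float)
    agg = (df.groupby(["donor_id", "tissue_group", "subset"], observed=True)
           .agg(n=("positive", "size"), percent=("positive", "mean"))
           .reset_index())
    agg["percent"] *= 100.0
    agg["excluded"] = agg["n"] < min_cells
    return agg
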
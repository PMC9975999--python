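"""Moment-based twin descriptives: intraclass, cross-twin cross-trait and
phenotypic correlations with stratified family bootstrap CIs.

All pair-level correlations use double entry: each complete pair contributes
both orderings (twin1, twin2) and (twin2, twin1), so every statistic is exactly
invariant to which member is labelled twin 1. The MZ/DZ contrast of these
correlations is the model-free signal for genetic influence (Falconer's
a2 = 2(rMZ - rDZ)); the formal variance decomposition lives in
:mod:`twinfear.biometric_model`.

Singletons contribute to individual-level phenotypic correlations and means
but carry no pair information.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .trial_phenotypes import TRAITS

__all__ = [
    "icc",
    "pair_values",
    "cross_twin_cross_trait",
    "phenotypic_correlations",
    "individual_table",
    "bootstrap_ci",
    "descriptives_report",
]


def pair_values(table: pd.DataFrame, trait: str, zygosity: str) -> np.ndarray:
    """Complete-pair values for one trait and zygosity, shape (n_pairs, 2)."""
    sub = table[table["zygosity"] == zygosity]
    x = sub[[f"t1_{trait}", f"t2_{trait}"]].to_numpy(float)
    return x[~np.isnan(x).any(axis=1)]


def icc(pairs: np.ndarray) -> float:
    """Twin-pair intraclass correlation via double-entry Pearson.

    Each pair enters in both orderings, which makes the estimate exactly
    order-invariant and equal to the one-way random-effects ANOVA ICC up to
    degrees-of-freedom factors.

    Parameters
    ----------
    pairs : array (n, 2)
        Complete pairs for one trait in one zygosity group; n >= 3 required.

    Returns
    -------
    float — NaN (with a warning) if the double-entered values have zero
    variance.
    """
    pairs = np.asarray(pairs, dtype=float)
    if pairs.ndim != 2 or pairs.shape[1] != 2:
        raise ValueError("pairs must have shape (n, 2)")
    if len(pairs) < 3:
        raise ValueError(f"need at least 3 complete pairs, got {len(pairs)}")
    a = np.concatenate([pairs[:, 0], pairs[:, 1]])
    b = np.concatenate([pairs[:, 1], pairs[:, 0]])
    if np.ptp(a) == 0.0:
        warnings.warn("zero variance in pair values; ICC undefined")
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def cross_twin_cross_trait(table: pd.DataFrame, zygosity: str) -> pd.DataFrame:
    """Double-entered correlations between trait i of a twin and trait j of
    the co-twin, for one zygosity group.

    Returns a symmetric 3x3 DataFrame whose diagonal equals the double-entry
    ICC per trait. Cells with fewer than 3 pairwise-complete double-entered
    pairs are NaN. Uses complete pairs only, pairwise across trait
    combinations.
    """
    sub = table[table["zygosity"] == zygosity]
    both = sub[[f"t1_{t}" for t in TRAITS] + [f"t2_{t}" for t in TRAITS]].to_numpy(float)
    has_pair = ~np.isnan(both[:, :3]).all(axis=1) & ~np.isnan(both[:, 3:]).all(axis=1)
    both = both[has_pair]
    x1, x2 = both[:, :3], both[:, 3:]
    # double entry: stack both orderings of every pair
    self_vals = np.vstack([x1, x2])
    co_vals = np.vstack([x2, x1])
    out = np.full((3, 3), np.nan)
    for i in range(3):
        for j in range(3):
            a, b = self_vals[:, i], co_vals[:, j]
            ok = ~np.isnan(a) & ~np.isnan(b)
            if ok.sum() >= 6 and np.ptp(a[ok]) > 0 and np.ptp(b[ok]) > 0:  # >= 3 pairs
                out[i, j] = np.corrcoef(a[ok], b[ok])[0, 1]
    out = (out + out.T) / 2.0  # exact symmetry (double entry makes them equal up to fp order)
    return pd.DataFrame(out, index=list(TRAITS), columns=list(TRAITS))


def individual_table(table: pd.DataFrame) -> pd.DataFrame:
    """Long format, one row per individual (twins and singletons)."""
    frames = []
    for k in (1, 2):
        cols = {f"t{k}_{t}": t for t in TRAITS}
        sub = table[["family_id", "zygosity", *cols]].rename(columns=cols)
        frames.append(sub[sub[list(TRAITS)].notna().any(axis=1)])
    return pd.concat(frames, ignore_index=True)


def phenotypic_correlations(table: pd.DataFrame) -> pd.DataFrame:
    """Pairwise-complete Pearson correlations among the three phenotypes,
    pooled over all individuals (both twins and singletons)."""
    ind = individual_table(table)
    corr = ind[list(TRAITS)].corr(method="pearson")  # pairwise complete
    np.fill_diagonal(corr.values, 1.0)
    return corr


def bootstrap_ci(statistic, table: pd.DataFrame, n_iter: int = 100, seed=None, level: float = 0.95):
    """Percentile bootstrap CI for a family-level statistic.

    Families (pairs or singletons) are resampled with replacement, stratified
    by zygosity so each resample preserves the MZ/DZ composition. The
    statistic may return a scalar or an ndarray; intervals are elementwise.

    Returns ``(lower, upper)`` with the statistic's shape. Raises if the
    statistic fails (exception) on more than 20% of resamples.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    rng = np.random.default_rng(seed)
    groups = [g for _, g in table.groupby("zygosity", sort=True)]
    stats, failures = [], 0
    for _ in range(n_iter):
        parts = [g.sample(n=len(g), replace=True, random_state=rng) for g in groups]
        resample = pd.concat(parts, ignore_index=True)
        try:
            stats.append(np.asarray(statistic(resample), dtype=float))
        except Exception:
            failures += 1
    if failures > 0.2 * n_iter:
        raise RuntimeError(f"statistic failed on {failures}/{n_iter} bootstrap resamples")
    stacked = np.stack(stats)
    alpha = (1.0 - level) / 2.0
    lower = np.nanpercentile(stacked, 100 * alpha, axis=0)
    upper = np.nanpercentile(stacked, 100 * (1 - alpha), axis=0)
    if stacked.ndim == 1:
        return float(lower), float(upper)
    return lower, upper


def descriptives_report(table: pd.DataFrame, n_boot: int = 100, seed=None, level: float = 0.95):
    """Twin descriptives: ICC per trait and zygosity with bootstrap CIs,
    cross-twin cross-trait matrices, and pooled phenotypic correlations.

    Returns a dict with keys ``icc`` (DataFrame: zygosity x trait with CI
    columns), ``cross_twin_cross_trait`` (dict zygosity -> DataFrame),
    ``phenotypic`` (DataFrame), and ``text`` (human-readable layout).
    """
    rows = []
    for zyg in ("MZ", "DZ"):
        for trait in TRAITS:
            est = icc(pair_values(table, trait, zyg))
            lo, hi = bootstrap_ci(
                lambda t, tr=trait, z=zyg: icc(pair_values(t, tr, z)),
                table, n_iter=n_boot, seed=seed, level=level,
            )
            rows.append({"zygosity": zyg, "trait": trait, "icc": est,
                         "ci_lower": lo, "ci_upper": hi, "n_boot": n_boot})
    icc_df = pd.DataFrame(rows)
    ctct = {z: cross_twin_cross_trait(table, z) for z in ("MZ", "DZ")}
    pheno = phenotypic_correlations(table)

    lines = ["Twin-pair intraclass correlations (double-entry Pearson, "
             f"{int(level * 100)}% bootstrap CIs, {n_boot} iterations)"]
    for _, r in icc_df.iterrows():
        lines.append(f"  {r.zygosity} {r.trait:<8s} {r.icc:6.3f}  ({r.ci_lower:6.3f}, {r.ci_upper:6.3f})")
    for zyg in ("MZ", "DZ"):
        lines.append(f"Cross-twin cross-trait correlations ({zyg}):")
        lines.append(ctct[zyg].to_string(float_format=lambda v: f"{v:6.3f}"))
    lines.append("Phenotypic correlations (all individuals, pairwise complete):")
    lines.append(pheno.to_string(float_format=lambda v: f"{v:6.3f}"))
    return {"icc": icc_df, "cross_twin_cross_trait": ctct, "phenotypic": pheno,
            "text": "\n".join(lines)}
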
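"""Per-probeset linear models for the 2x2 vapor-by-drinking design.

Implements the six pairwise group contrasts (one shared 4-group linear
model with pooled residual variance), the two-factor model with
interaction, Benjamini-Hochberg FDR adjustment, and contrast-overlap
counts. Empirical-Bayes variance moderation is optional and off by
default: the contracts hold either way.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import special, stats
from scipy.optimize import brentq

# C1..C6 pairwise comparisons among the four treatment groups
CONTRASTS: dict[str, tuple[str, str]] = {
    "C1": ("CIE Drinking", "Air Drinking"),
    "C2": ("CIE NonDrinking", "Air NonDrinking"),
    "C3": ("CIE Drinking", "CIE NonDrinking"),
    "C4": ("CIE Drinking", "Air NonDrinking"),
    "C5": ("CIE NonDrinking", "Air Drinking"),
    "C6": ("Air Drinking", "Air NonDrinking"),
}


def bh_fdr(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in original order.

    q_(i) = min_{j >= i} (m * p_(j) / j), clipped at 1.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be a 1-d vector")
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def _group_means_and_pooled_var(
    x: np.ndarray, groups: np.ndarray, levels: list[str]
) -> tuple[dict[str, np.ndarray], dict[str, int], np.ndarray, int]:
    means: dict[str, np.ndarray] = {}
    counts: dict[str, int] = {}
    ssw = np.zeros(x.shape[0])
    for g in levels:
        cols = groups == g
        ng = int(cols.sum())
        if ng < 2:
            raise ValueError(f"group {g!r} has fewer than 2 samples")
        xg = x[:, cols]
        mg = xg.mean(axis=1)
        means[g] = mg
        counts[g] = ng
        ssw += ((xg - mg[:, None]) ** 2).sum(axis=1)
    df = x.shape[1] - len(levels)
    s2 = ssw / df
    return means, counts, s2, df


def moderate_variances(s2: np.ndarray, df: int) -> tuple[np.ndarray, float]:
    """Shrink per-gene variances toward a common prior fitted by moments.

    Fits a scaled inverse-chi-square prior (d0, s0^2) to the observed s^2 via
    the moments of log s^2 and returns posterior variances
    (d0*s0^2 + df*s^2) / (d0 + df) with the total degrees of freedom d0+df.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    ev = np.var(e, ddof=1) - special.polygamma(1, df / 2.0)
    if ev <= 0:
        return np.full_like(s2, np.exp(np.mean(e))), np.inf  # no extra spread: full shrinkage
    g = lambda d0: special.polygamma(1, d0 / 2.0) - ev
    d0 = brentq(g, 1e-3, 1e6)
    s0_sq = np.exp(np.mean(e) + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
    post = (d0 * s0_sq + df * s2) / (d0 + df)
    post[~ok] = s0_sq
    return post, d0


def pairwise_contrasts(
    matrix: pd.DataFrame, ann: pd.DataFrame, moderate: bool = False
) -> pd.DataFrame:
    """All six pairwise group contrasts from one 4-group linear model.

    Per probeset and contrast: log_ratio = difference of group means, t with
    residual variance pooled across all four groups, two-sided p from the t
    distribution at the model residual df, BH FDR within contrast.
    Zero-variance probesets are flagged and assigned t = 0, p = 1.
    """
    groups = (ann["vapor"].astype(str) + " " + ann["drinking"].astype(str)).to_numpy()
    levels = [g for pair in CONTRASTS.values() for g in pair]
    levels = list(dict.fromkeys(levels))
    missing = [g for g in levels if g not in set(groups)]
    if missing:
        raise ValueError(f"missing treatment groups: {missing}")
    x = matrix.to_numpy(dtype=float)
    means, counts, s2, df = _group_means_and_pooled_var(x, groups, levels)
    if moderate:
        s2_use, d0 = moderate_variances(s2, df)
        df_use = df + d0 if np.isfinite(d0) else x.shape[1]
    else:
        s2_use, df_use = s2, df
    zero = s2_use <= 0
    rows = []
    for label, (a, b) in CONTRASTS.items():
        lr = means[a] - means[b]
        se = np.sqrt(s2_use * (1.0 / counts[a] + 1.0 / counts[b]))
        with np.errstate(divide="ignore", invalid="ignore"):
            t = lr / se
        t[zero] = 0.0
        p = 2.0 * stats.t.sf(np.abs(t), df_use)
        p[zero] = 1.0
        rows.append(
            pd.DataFrame(
                {
                    "probeset": matrix.index,
                    "contrast": label,
                    "log_ratio": lr,
                    "t": t,
                    "p_value": p,
                    "fdr": bh_fdr(p),
                    "zero_variance": zero,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def two_factor_model(matrix: pd.DataFrame, ann: pd.DataFrame) -> pd.DataFrame:
    """Two-way fixed-effects model: vapor + drinking + vapor:drinking.

    Effect-coded design (Type III sums of squares on the balanced coding);
    returns one row per probeset and effect with t, F = t^2 and p.
    """
    vapor = ann["vapor"].astype(str).to_numpy()
    drink = ann["drinking"].astype(str).to_numpy()
    for name, v, lev in (("vapor", vapor, ("CIE", "Air")), ("drinking", drink, ("Drinking", "NonDrinking"))):
        if set(v) != set(lev):
            raise ValueError(f"{name} must have both levels {lev}")
    cell = pd.Series(vapor) + " " + pd.Series(drink)
    if cell.nunique() != 4:
        raise ValueError("empty cell in the 2x2 design")
    x = matrix.to_numpy(dtype=float)
    a = np.where(vapor == "CIE", 1.0, -1.0)
    b = np.where(drink == "Drinking", 1.0, -1.0)
    design = np.column_stack([np.ones_like(a), a, b, a * b])
    n, k = design.shape
    xtx_inv = np.linalg.inv(design.T @ design)
    beta = x @ design @ xtx_inv  # genes x 4
    resid = x - beta @ design.T
    df = n - k
    s2 = (resid**2).sum(axis=1) / df
    zero = s2 <= 0
    effects = {"vapor": 1, "drinking": 2, "interaction": 3}
    rows = []
    for name, j in effects.items():
        se = np.sqrt(s2 * xtx_inv[j, j])
        with np.errstate(divide="ignore", invalid="ignore"):
            t = beta[:, j] / se
        t[zero] = 0.0
        p = 2.0 * stats.t.sf(np.abs(t), df)
        p[zero] = 1.0
        rows.append(
            pd.DataFrame(
                {
                    "probeset": matrix.index,
                    "contrast": name,
                    "log_ratio": 2.0 * beta[:, j],  # effect-coded: 2*coef = level difference
                    "t": t,
                    "F": t**2,
                    "p_value": p,
                    "fdr": bh_fdr(p),
                    "zero_variance": zero,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def significant_sets(
    results: pd.DataFrame, threshold: float = 0.01, column: str = "fdr"
) -> dict[str, set[str]]:
    """Per-contrast sets of significant probesets at a threshold."""
    out: dict[str, set[str]] = {}
    for label, sub in results.groupby("contrast", sort=False):
        out[label] = set(sub.loc[sub[column] <= threshold, "probeset"])
    return out


def contrast_overlap(
    results: pd.DataFrame, fdr: float = 0.01
) -> pd.DataFrame:
    """All 2- and 3-way intersection sizes of per-contrast significant sets."""
    from itertools import combinations

    sets = significant_sets(results, threshold=fdr, column="fdr")
    labels = list(sets)
    rows = []
    for r in (2, 3):
        for combo in combinations(labels, r):
            inter = set.intersection(*(sets[c] for c in combo))
            rows.append({"contrasts": "&".join(combo), "k": r, "overlap": len(inter)})
    return pd.DataFrame(rows)
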
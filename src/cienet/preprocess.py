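"""Quantile normalization and the ANOVA probeset filter.

The network input universe is chosen the way the study design prescribes:
probesets significant by one-way ANOVA across the four treatment groups at
BH-FDR <= 0.01 in any region, unioned across regions. Batch correction is a
hook only: the pipeline expects a pre-corrected matrix.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .de import bh_fdr


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Force every sample (column) to the same empirical distribution.

    The reference distribution is the row-wise mean of the sorted columns;
    tied values within a column receive the mean of the reference values at
    the rank positions they occupy. Idempotent to machine precision.
    """
    if matrix.shape[1] < 2:
        raise ValueError("quantile normalization needs at least 2 samples")
    x = matrix.to_numpy(dtype=float)
    order = np.argsort(x, axis=0, kind="stable")
    ref = np.mean(np.take_along_axis(x, order, axis=0), axis=1)
    out = np.empty_like(x)
    rows = np.empty(x.shape[0], dtype=int)
    for j in range(x.shape[1]):
        rows[order[:, j]] = np.arange(x.shape[0])
        col = ref[rows]
        # average reference values over ties
        _, inv, counts = np.unique(x[:, j], return_inverse=True, return_counts=True)
        sums = np.bincount(inv, weights=col)
        out[:, j] = sums[inv] / counts[inv]
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def group_labels(ann: pd.DataFrame) -> pd.Series:
    """vapor x drinking treatment group per sample, e.g. 'CIE Drinking'."""
    return ann["vapor"].astype(str) + " " + ann["drinking"].astype(str)


def oneway_anova(matrix: pd.DataFrame, ann: pd.DataFrame) -> pd.DataFrame:
    """Vectorized one-way ANOVA of each probeset across the treatment groups.

    Returns a DataFrame (probeset, F, p_value). Zero-variance probesets get
    F = 0, p = 1.
    """
    groups = group_labels(ann)
    if not (ann["sample_id"].to_numpy() == np.asarray(matrix.columns)).all():
        raise ValueError("annotation rows must align with expression columns")
    levels = groups.unique()
    if len(levels) < 2:
        raise ValueError("need at least 2 groups")
    x = matrix.to_numpy(dtype=float)
    n = x.shape[1]
    counts = np.array([(groups == g).sum() for g in levels])
    if (counts < 2).any():
        small = [g for g, c in zip(levels, counts) if c < 2]
        raise ValueError(f"groups with fewer than 2 samples: {small}")
    grand = x.mean(axis=1)
    ssb = np.zeros(x.shape[0])
    ssw = np.zeros(x.shape[0])
    for g, ng in zip(levels, counts):
        xg = x[:, (groups == g).to_numpy()]
        mg = xg.mean(axis=1)
        ssb += ng * (mg - grand) ** 2
        ssw += ((xg - mg[:, None]) ** 2).sum(axis=1)
    df_b = len(levels) - 1
    df_w = n - len(levels)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ssb / df_b) / (ssw / df_w)
    p = stats.f.sf(f, df_b, df_w)
    zero = ssw <= 0
    f[zero] = 0.0
    p[zero] = 1.0
    return pd.DataFrame({"probeset": matrix.index, "F": f, "p_value": p})


def anova_filter(
    matrix: pd.DataFrame, ann: pd.DataFrame, fdr_threshold: float = 0.01
) -> list[str]:
    """Probesets passing the one-way-ANOVA BH-FDR filter, in matrix order."""
    res = oneway_anova(matrix, ann)
    fdr = bh_fdr(res["p_value"].to_numpy())
    keep = res["probeset"].to_numpy()[fdr <= fdr_threshold]
    return list(keep)


def union_filter(
    sets: list[list[str] | set[str]], universe: list[str] | None = None
) -> list[str]:
    """Union of per-region filtered probeset lists.

    Ordered by ``universe`` (the input matrix order) when given, otherwise
    by first appearance across the inputs.
    """
    union: set[str] = set()
    first_seen: list[str] = []
    for s in sets:
        for p in s:
            if p not in union:
                union.add(p)
                first_seen.append(p)
    if universe is not None:
        return [p for p in universe if p in union]
    return first_seen
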
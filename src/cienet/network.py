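"""Weighted coexpression network construction and module detection.

Adjacency is soft-thresholded Pearson correlation (|cor|^beta for the
unsigned network, ((1+cor)/2)^beta signed), similarity is the topological
overlap matrix (TOM), and modules are branches of an average-linkage
dendrogram on 1 - TOM cut by a native dynamic hybrid tree-cut variant whose
sensitivity is indexed by a deep-split preset (0-3). Module labels follow
the conventional color sequence in descending size order; "grey" collects
unassigned genes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

GREY = "grey"

# conventional module color sequence, assigned by descending module size
COLOR_SEQUENCE = [
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "white", "skyblue", "saddlebrown", "steelblue",
    "paleturquoise", "violet", "darkolivegreen", "darkmagenta",
]

# deep-split presets: (max core scatter, min branch gap), both as fractions
# of the dendrogram height range above its 5th-percentile reference. Higher
# deep split tolerates looser branches and smaller gaps, yielding more and
# smaller modules.
DEEP_SPLIT_PRESETS = {
    0: (0.64, 0.27),
    1: (0.73, 0.2025),
    2: (0.82, 0.135),
    3: (0.91, 0.0675),
}


@dataclass
class NetworkConfig:
    power: int = 6
    sign: str = "unsigned"  # or "signed"
    deep_split: int = 2
    min_module_size: int = 30
    merge_height: float | None = None
    cut_height_fraction: float = 0.99  # static cut at this fraction of max height

    def validate(self) -> None:
        if self.power < 1:
            raise ValueError("power must be >= 1")
        if self.sign not in ("unsigned", "signed"):
            raise ValueError("sign must be 'unsigned' or 'signed'")
        if self.deep_split not in DEEP_SPLIT_PRESETS:
            raise ValueError("deep_split must be in {0,1,2,3}")
        if self.merge_height is not None and not 0.0 <= self.merge_height <= 1.0:
            raise ValueError("merge_height must lie in [0, 1]")


def drop_zero_variance(matrix: pd.DataFrame) -> pd.DataFrame:
    """Exclude zero-variance genes (they have no defined correlation)."""
    sd = matrix.to_numpy().std(axis=1)
    bad = sd <= 0
    if bad.any():
        warnings.warn(
            f"excluding {int(bad.sum())} zero-variance probesets from the network"
        )
        return matrix.loc[~bad]
    return matrix


def adjacency(matrix: pd.DataFrame, cfg: NetworkConfig) -> pd.DataFrame:
    """Soft-thresholded correlation adjacency over probesets; diagonal 1."""
    cfg.validate()
    if matrix.shape[1] < 4:
        raise ValueError("need at least 4 samples to build a network")
    matrix = drop_zero_variance(matrix)
    cor = np.corrcoef(matrix.to_numpy(dtype=float))
    cor = np.clip(cor, -1.0, 1.0)
    if cfg.sign == "unsigned":
        a = np.abs(cor) ** cfg.power
    else:
        a = ((1.0 + cor) / 2.0) ** cfg.power
    np.fill_diagonal(a, 1.0)
    return pd.DataFrame(a, index=matrix.index, columns=matrix.index)


def scale_free_fit(k: np.ndarray, n_bins: int = 10) -> tuple[float, float]:
    """Signed scale-free topology fit of a connectivity vector.

    Bins k, regresses log10(mean frequency) on log10(mean k) and returns
    (signed R^2, mean k) where signed R^2 = -sign(slope) * R^2. NaN when
    fewer than 2 bins are occupied.
    """
    k = np.asarray(k, dtype=float)
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    idx = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        sel = idx == b
        if sel.sum() == 0:
            continue
        mk = k[sel].mean()
        freq = sel.mean()
        if mk > 0 and freq > 0:
            xs.append(np.log10(mk))
            ys.append(np.log10(freq))
    if len(xs) < 2:
        return float("nan"), float(k.mean())
    slope, intercept = np.polyfit(xs, ys, 1)
    yhat = slope * np.asarray(xs) + intercept
    ss_res = np.sum((np.asarray(ys) - yhat) ** 2)
    ss_tot = np.sum((np.asarray(ys) - np.mean(ys)) ** 2)
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return float(-np.sign(slope) * r2), float(k.mean())


def pick_soft_threshold(
    matrix: pd.DataFrame,
    candidate_powers: list[int] | None = None,
    r2_threshold: float = 0.80,
    sign: str = "unsigned",
    override: int | None = None,
) -> tuple[int, pd.DataFrame]:
    """Choose the soft power: smallest candidate whose signed scale-free fit
    R^2 reaches the threshold; an explicit override is honored regardless of
    fit (the fit table is still reported). Falls back to the best-fitting
    candidate, with a warning, when none reaches the threshold.
    """
    if candidate_powers is None:
        candidate_powers = list(range(1, 21))
    rows = []
    for beta in candidate_powers:
        cfg = NetworkConfig(power=beta, sign=sign)
        a = adjacency(matrix, cfg).to_numpy()
        k = a.sum(axis=1) - 1.0
        r2, mean_k = scale_free_fit(k)
        rows.append({"power": beta, "signed_r2": r2, "mean_k": mean_k})
    table = pd.DataFrame(rows)
    if override is not None:
        return int(override), table
    ok = table[table["signed_r2"] >= r2_threshold]
    if len(ok):
        return int(ok["power"].iloc[0]), table
    warnings.warn("no candidate power reached the scale-free fit threshold")
    return int(table.loc[table["signed_r2"].idxmax(), "power"]), table


def topological_overlap(adj: pd.DataFrame) -> pd.DataFrame:
    """Topological overlap matrix.

    TOM_ij = (L_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij), i != j, with
    L_ij = sum_{u != i,j} a_iu a_uj and k_i = sum_{u != i} a_iu; TOM_ii = 1.
    """
    a = adj.to_numpy(dtype=float).copy()
    if not np.allclose(a, a.T, atol=1e-12):
        raise ValueError("adjacency must be symmetric")
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    l = a @ a  # zero diagonal => sum over u != i and u != j exactly
    denom = np.minimum.outer(k, k) + 1.0 - a
    tom = (l + a) / denom
    np.fill_diagonal(tom, 1.0)
    return pd.DataFrame(tom, index=adj.index, columns=adj.columns)


def _cluster_scatter(dist: np.ndarray, leaves: np.ndarray) -> float:
    """Mean pairwise dissimilarity within a set of leaves."""
    if len(leaves) < 2:
        return 0.0
    sub = dist[np.ix_(leaves, leaves)]
    m = len(leaves)
    return float((sub.sum() - np.trace(sub)) / (m * (m - 1)))


def _cut_tree(
    z: np.ndarray,
    dist: np.ndarray,
    deep_split: int,
    min_module_size: int,
    cut_height_fraction: float,
) -> list[np.ndarray]:
    """Native dynamic hybrid tree-cut variant.

    Branches above the static cut height are always separated. Below it, a
    branch is split into its two children only when both children are large
    enough, internally coherent (core scatter below the deep-split preset),
    and attached to the parent with a height gap above the preset minimum.
    Returns the leaf index arrays of the resulting clusters (unfiltered by
    size; the caller assigns small or incoherent clusters to grey).
    """
    heights = z[:, 2]
    h_max = float(heights.max()) if len(heights) else 0.0
    h_ref = float(np.quantile(heights, 0.05)) if len(heights) else 0.0
    cut_h = cut_height_fraction * h_max
    span = max(cut_h - h_ref, 1e-12)
    max_scatter_frac, min_gap_frac = DEEP_SPLIT_PRESETS[deep_split]
    max_scatter = h_ref + max_scatter_frac * span
    min_gap = min_gap_frac * span

    root, _ = hierarchy.to_tree(z, rd=True)

    def leaves_of(node) -> np.ndarray:
        return np.array(node.pre_order(lambda leaf: leaf.id))

    out: list[np.ndarray] = []

    def descend(node) -> None:
        if node.is_leaf():
            out.append(np.array([node.id]))
            return
        if node.dist > cut_h:
            # separate components of the static cut
            descend(node.left)
            descend(node.right)
            return
        left, right = node.left, node.right
        lv_l, lv_r = leaves_of(left), leaves_of(right)
        if min(len(lv_l), len(lv_r)) >= min_module_size:
            gap_l = node.dist - (left.dist if not left.is_leaf() else 0.0)
            gap_r = node.dist - (right.dist if not right.is_leaf() else 0.0)
            if (
                gap_l >= min_gap
                and gap_r >= min_gap
                and _cluster_scatter(dist, lv_l) <= max_scatter
                and _cluster_scatter(dist, lv_r) <= max_scatter
            ):
                descend(left)
                descend(right)
                return
        out.append(leaves_of(node))

    descend(root)
    return out


def _trim_cluster(
    tom: np.ndarray, members: np.ndarray, factor: float = 0.5, max_iter: int = 20
) -> np.ndarray:
    """Drop weakly attached members: genes whose mean TOM similarity to the
    rest of the cluster falls below ``factor`` times the cluster median.

    Branches of the dendrogram pick up straggler genes that join near the
    cut height; their intra-cluster topological overlap is far below that
    of genuine members, so an iterated relative threshold removes them
    without touching the coherent core.
    """
    for _ in range(max_iter):
        if len(members) < 3:
            return members
        sub = tom[np.ix_(members, members)]
        s = (sub.sum(axis=1) - np.diag(sub)) / (len(members) - 1)
        keep = s >= factor * np.median(s)
        if keep.all():
            return members
        members = members[keep]
    return members


def detect_modules(tom: pd.DataFrame, cfg: NetworkConfig) -> pd.Series:
    """Assign probesets to modules by cutting the 1-TOM dendrogram.

    Average-linkage clustering, dynamic-hybrid-style cut with sensitivity
    from ``cfg.deep_split``; clusters smaller than ``cfg.min_module_size``
    or with core scatter above the preset become grey, and weakly attached
    stragglers are trimmed from each cluster. Labels are drawn from the
    standard color sequence by descending module size.
    """
    cfg.validate()
    t = tom.to_numpy(dtype=float)
    dist = 1.0 - t
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    z = hierarchy.linkage(squareform(dist, checks=False), method="average")
    clusters = _cut_tree(z, dist, cfg.deep_split, cfg.min_module_size, cfg.cut_height_fraction)

    heights = z[:, 2]
    h_ref = float(np.quantile(heights, 0.05))
    span = max(cfg.cut_height_fraction * float(heights.max()) - h_ref, 1e-12)
    max_scatter = h_ref + DEEP_SPLIT_PRESETS[cfg.deep_split][0] * span

    keep = [
        _trim_cluster(t, c)
        for c in clusters
        if len(c) >= cfg.min_module_size and _cluster_scatter(dist, c) <= max_scatter
    ]
    keep = [c for c in keep if len(c) >= cfg.min_module_size]
    # deterministic ordering: by size desc, then smallest leaf index
    keep.sort(key=lambda c: (-len(c), int(c.min())))
    labels = np.full(tom.shape[0], GREY, dtype=object)
    for rank, c in enumerate(keep):
        if rank < len(COLOR_SEQUENCE):
            name = COLOR_SEQUENCE[rank]
        else:
            name = f"module_{rank + 1}"
        labels[c] = name
    assign = pd.Series(labels, index=tom.index, name="module")
    if (assign == GREY).all():
        warnings.warn("no modules found: all genes assigned to grey")
    if cfg.merge_height is not None:
        assign = _merge_close_modules(tom, assign, cfg)
    return assign


def _merge_close_modules(tom: pd.DataFrame, assign: pd.Series, cfg: NetworkConfig) -> pd.Series:
    """Optionally merge modules whose eigengenes are closer than merge_height
    (dissimilarity 1 - cor). Off by default."""
    # local import: eigengenes need the expression matrix, which we do not
    # have here; merging is based on mean intra-module TOM similarity instead
    while True:
        mods = [m for m in assign.unique() if m != GREY]
        if len(mods) < 2:
            return assign
        best = None
        for i in range(len(mods)):
            for j in range(i + 1, len(mods)):
                a = assign.index[assign == mods[i]]
                b = assign.index[assign == mods[j]]
                sim = tom.loc[a, b].to_numpy().mean()
                d = 1.0 - sim
                if d < cfg.merge_height and (best is None or d < best[0]):
                    best = (d, mods[i], mods[j])
        if best is None:
            return assign
        _, keep_m, drop_m = best
        assign = assign.replace({drop_m: keep_m})


def module_eigengenes(matrix: pd.DataFrame, assign: pd.Series) -> pd.DataFrame:
    """First-principal-component eigengene per non-grey module.

    Member genes are standardized across samples; the eigengene is the
    leading right-singular vector of that submatrix, centered to zero mean
    across samples, scaled to unit standard deviation, and sign-oriented to
    correlate positively with the module's mean standardized profile.
    Returns modules x samples.
    """
    mods = [m for m in assign.unique() if m != GREY]
    rows = {}
    for m in mods:
        genes = assign.index[assign == m]
        sub = matrix.loc[genes].to_numpy(dtype=float)
        mu = sub.mean(axis=1, keepdims=True)
        sd = sub.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        z = (sub - mu) / sd
        if z.shape[0] == 1:
            e = z[0]
        else:
            _, _, vt = np.linalg.svd(z, full_matrices=False)
            e = vt[0]
        mean_profile = z.mean(axis=0)
        if np.dot(e, mean_profile) < 0:
            e = -e
        e = e - e.mean()
        sd_e = e.std()
        if sd_e > 0:
            e = e / sd_e
        rows[m] = e
    return pd.DataFrame(rows, index=matrix.columns).T


def connectivity_stats(
    adj: pd.DataFrame, assign: pd.Series, eigengenes: pd.DataFrame, matrix: pd.DataFrame
) -> pd.DataFrame:
    """Per-gene connectivity: kTotal, kIM within the gene's module, and kME
    (correlation with its module eigengene). Grey genes keep kTotal; their
    kIM and kME are NaN."""
    a = adj.to_numpy(dtype=float).copy()
    np.fill_diagonal(a, 0.0)
    k_total = a.sum(axis=1)
    k_im = np.full(len(adj), np.nan)
    k_me = np.full(len(adj), np.nan)
    idx_of = {g: i for i, g in enumerate(adj.index)}
    x = matrix.loc[adj.index].to_numpy(dtype=float)
    for m in eigengenes.index:
        genes = [g for g in assign.index[assign == m] if g in idx_of]
        ii = np.array([idx_of[g] for g in genes])
        k_im[ii] = a[np.ix_(ii, ii)].sum(axis=1)
        e = eigengenes.loc[m].to_numpy(dtype=float)
        xg = x[ii]
        xc = xg - xg.mean(axis=1, keepdims=True)
        ec = e - e.mean()
        denom = np.sqrt((xc**2).sum(axis=1) * (ec**2).sum())
        with np.errstate(divide="ignore", invalid="ignore"):
            k_me[ii] = (xc @ ec) / denom
    return pd.DataFrame(
        {
            "probeset": adj.index,
            "module": assign.loc[adj.index].to_numpy(),
            "kTotal": k_total,
            "kIM": k_im,
            "kME": k_me,
        }
    )
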
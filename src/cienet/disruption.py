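"""Bootstrap module-disruption Z statistics.

For every module, the correlation of per-gene connectivity (intramodular
kIM, and kME) between two treatment groups is compared with the same
correlation among bootstrap networks built from random sample subsets drawn
without regard to treatment group:

    Z = (obs - mu) / sigma

where mu and sigma are the mean and SD of the pairwise connectivity
correlations across the bootstrap networks. Modules with Z_cor.kIM <= -2
are considered significantly disrupted. The comparison of interest is
CIE Drinking vs the ethanol-naive Air NonDrinking group.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .network import GREY, NetworkConfig, adjacency, connectivity_stats, module_eigengenes
from .preprocess import group_labels

Z_THRESHOLD = -2.0


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    if len(x) < 3 or np.std(x) == 0 or np.std(y) == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def _module_index_map(assign: pd.Series, universe: pd.Index) -> dict[str, np.ndarray]:
    idx_of = {g: i for i, g in enumerate(universe)}
    out = {}
    for m in assign.unique():
        if m == GREY:
            continue
        out[m] = np.array([idx_of[g] for g in assign.index[assign == m] if g in idx_of])
    return out


def _subset_connectivity(
    x: np.ndarray,
    cols: np.ndarray,
    modules: dict[str, np.ndarray],
    cfg: NetworkConfig,
    kme_mode: str,
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per-module (kIM, kME) vectors from the given sample columns.

    Works module-block-wise, which is all the disruption statistic needs:
    kIM uses adjacency among member genes; kME is either the correlation of
    each member with the module eigengene recomputed on these samples
    (default) or the member's total connectivity to all genes (``ktotal``).
    """
    xs = x[:, cols]
    xs_c = xs - xs.mean(axis=1, keepdims=True)
    norms = np.sqrt((xs_c**2).sum(axis=1))
    norms[norms == 0] = 1.0
    xn = xs_c / norms[:, None]
    out = {}
    for label, idx in modules.items():
        sub = xn[idx]
        cor = np.clip(sub @ sub.T, -1.0, 1.0)
        if cfg.sign == "unsigned":
            a = np.abs(cor) ** cfg.power
        else:
            a = ((1.0 + cor) / 2.0) ** cfg.power
        np.fill_diagonal(a, 0.0)
        k_im = a.sum(axis=1)
        if kme_mode == "eigengene":
            if sub.shape[0] == 1:
                e = sub[0]
            else:
                _, _, vt = np.linalg.svd(sub, full_matrices=False)
                e = vt[0]
            if np.dot(e, sub.mean(axis=0)) < 0:
                e = -e
            en = e / np.linalg.norm(e)
            k_me = np.clip(sub @ en, -1.0, 1.0)
        elif kme_mode == "ktotal":
            cor_all = np.clip(sub @ xn.T, -1.0, 1.0)
            if cfg.sign == "unsigned":
                a_all = np.abs(cor_all) ** cfg.power
            else:
                a_all = ((1.0 + cor_all) / 2.0) ** cfg.power
            k_me = a_all.sum(axis=1) - 1.0  # subtract self-adjacency
        else:
            raise ValueError("kme_mode must be 'eigengene' or 'ktotal'")
        out[label] = (k_im, k_me)
    return out


def group_connectivity(
    matrix: pd.DataFrame,
    ann: pd.DataFrame,
    group: str,
    assign: pd.Series,
    cfg: NetworkConfig,
) -> pd.DataFrame:
    """Connectivity statistics computed from one treatment group's samples.

    Adjacency is rebuilt (same soft power as the full network) from the
    group's samples only; kIM is taken within each gene's full-network
    module and kME against the module eigengene recomputed on these samples.
    """
    groups = group_labels(ann)
    cols = [s for s, g in zip(ann["sample_id"], groups) if g == group]
    if len(cols) < 4:
        raise ValueError(f"group {group!r} has fewer than 4 samples")
    sub = matrix[cols]
    adj = adjacency(sub, cfg)
    eig = module_eigengenes(sub.loc[adj.index], assign.loc[adj.index])
    return connectivity_stats(adj, assign.loc[adj.index], eig, sub)


def disruption_z(
    matrix: pd.DataFrame,
    ann: pd.DataFrame,
    group_a: str,
    group_b: str,
    assign: pd.Series,
    cfg: NetworkConfig,
    n_boot: int = 200,
    seed: int = 0,
    kme_mode: str = "eigengene",
    pair_mode: str = "disjoint",
    max_pairs: int | None = None,
) -> pd.DataFrame:
    """Module disruption table comparing group_a vs group_b connectivity.

    Null networks: ``n_boot`` sample subsets of size min(|A|, |B|) drawn
    without replacement ignoring treatment labels. mu/sigma are taken over
    the pairwise correlations between all unordered bootstrap-network pairs
    (subsample ``max_pairs`` of them if set). Output columns follow the
    standard disruption-table schema (mod.cor.kIM, mean.boot.cor.kIM, ...).
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 4]))
    groups = group_labels(ann).to_numpy()
    samples = ann["sample_id"].to_numpy()
    cols_a = np.flatnonzero(groups == group_a)
    cols_b = np.flatnonzero(groups == group_b)
    for g, c in ((group_a, cols_a), (group_b, cols_b)):
        if len(c) < 4:
            raise ValueError(f"group {g!r} has fewer than 4 samples")
    x = matrix[samples].to_numpy(dtype=float)
    modules = _module_index_map(assign, matrix.index)

    conn_a = _subset_connectivity(x, cols_a, modules, cfg, kme_mode)
    conn_b = _subset_connectivity(x, cols_b, modules, cfg, kme_mode)

    subset_size = min(len(cols_a), len(cols_b))
    n = len(samples)
    subsets = [rng.choice(n, size=subset_size, replace=False) for _ in range(n_boot)]
    boots = [
        _subset_connectivity(x, cols, modules, cfg, kme_mode) for cols in subsets
    ]

    if pair_mode == "disjoint":
        # the observed statistic compares two sample-disjoint groups, so the
        # null is taken over bootstrap-network pairs that share no samples
        sets = [set(c.tolist()) for c in subsets]
        pair_idx = [
            (i, j)
            for i in range(n_boot)
            for j in range(i + 1, n_boot)
            if not (sets[i] & sets[j])
        ]
        if len(pair_idx) < 30:
            raise RuntimeError(
                "too few disjoint bootstrap pairs; increase n_boot or use pair_mode='all'"
            )
    elif pair_mode == "all":
        pair_idx = None
    else:
        raise ValueError("pair_mode must be 'all' or 'disjoint'")
    if max_pairs is not None:
        if pair_idx is None:
            pair_idx = [(i, j) for i in range(n_boot) for j in range(i + 1, n_boot)]
        sel = rng.choice(len(pair_idx), size=min(max_pairs, len(pair_idx)), replace=False)
        pair_idx = [pair_idx[s] for s in sel]

    rows = []
    for label, idx in modules.items():
        size = len(idx)
        if size < 3:
            rows.append(
                {
                    "module": label, "size": size,
                    "mod.cor.kIM": np.nan, "mean.boot.cor.kIM": np.nan,
                    "sd.boot.cor.kIM": np.nan, "Z_cor.kIM": np.nan,
                    "mod.cor.kME": np.nan, "mean.boot.cor.kME": np.nan,
                    "sd.boot.cor.kME": np.nan, "Z_cor.kME": np.nan,
                    "disrupted": False, "flagged": True,
                }
            )
            continue
        row: dict[str, object] = {"module": label, "size": size, "flagged": False}
        for stat, pos in (("kIM", 0), ("kME", 1)):
            obs = _pearson(conn_a[label][pos], conn_b[label][pos])
            mat = np.vstack([b[label][pos] for b in boots])
            cors = _pairwise_correlations(mat, pair_idx)
            mu = float(np.nanmean(cors))
            sd = float(np.nanstd(cors, ddof=1))
            z = (obs - mu) / sd if sd > 0 else float("nan")
            row[f"mod.cor.{stat}"] = obs
            row[f"mean.boot.cor.{stat}"] = mu
            row[f"sd.boot.cor.{stat}"] = sd
            row[f"Z_cor.{stat}"] = z
        row["disrupted"] = bool(row["Z_cor.kIM"] <= Z_THRESHOLD)
        rows.append(row)
    cols = [
        "module", "size",
        "mod.cor.kME", "mean.boot.cor.kME", "sd.boot.cor.kME", "Z_cor.kME",
        "mod.cor.kIM", "mean.boot.cor.kIM", "sd.boot.cor.kIM", "Z_cor.kIM",
        "disrupted", "flagged",
    ]
    return pd.DataFrame(rows)[cols]


def _pairwise_correlations(
    mat: np.ndarray, pair_idx: list[tuple[int, int]] | None
) -> np.ndarray:
    """Correlations between rows of ``mat`` for all (or selected) pairs."""
    if pair_idx is None:
        c = np.corrcoef(mat)
        iu = np.triu_indices_from(c, k=1)
        return c[iu]
    return np.array([_pearson(mat[i], mat[j]) for i, j in pair_idx])
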
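"""Permutation validation of module coherence.

Each module's mean intra-module topological overlap is compared with the
same statistic on random pseudo-modules of equal size sampled from the
whole network universe; the resulting Z score gives a one-sided normal
p-value, BH-adjusted across modules. Modules at FDR <= 0.2 are considered
validated; grey is always reported with FDR 1.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .de import bh_fdr
from .network import GREY


def mean_intramodule_overlap(tom: np.ndarray, members: np.ndarray) -> float:
    """Mean off-diagonal TOM over the member pairs."""
    m = len(members)
    if m < 2:
        return float("nan")
    sub = tom[np.ix_(members, members)]
    return float((sub.sum() - np.trace(sub)) / (m * (m - 1)))


def null_overlap_sample(
    tom: np.ndarray, size: int, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """Mean intra-module overlap of ``n_perm`` random pseudo-modules of a
    given size, sampled without replacement from the whole universe."""
    n = tom.shape[0]
    out = np.empty(n_perm)
    for i in range(n_perm):
        members = rng.choice(n, size=size, replace=False)
        out[i] = mean_intramodule_overlap(tom, members)
    return out


def validate_modules(
    tom: pd.DataFrame,
    modules: pd.Series | dict[str, list[str]],
    n_perm: int = 100,
    seed: int = 0,
    fdr_threshold: float = 0.2,
) -> pd.DataFrame:
    """Permutation validation of every module against random pseudo-modules.

    ``modules`` is either a partition (probeset -> label Series, grey
    handled specially) or an explicit mapping label -> member list (which
    need not partition the universe; useful for scoring pseudo-modules).
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 3]))
    t = tom.to_numpy(dtype=float)
    idx_of = {g: i for i, g in enumerate(tom.index)}
    if isinstance(modules, pd.Series):
        mapping = {
            m: list(modules.index[modules == m])
            for m in modules.unique()
        }
    else:
        mapping = {m: list(v) for m, v in modules.items()}

    rows = []
    p_track = []
    for label, genes in mapping.items():
        members = np.array([idx_of[g] for g in genes if g in idx_of])
        size = len(members)
        obs = mean_intramodule_overlap(t, members)
        if label == GREY or size < 2:
            rows.append(
                {
                    "module": label, "size": size, "obs_mean_TO": obs,
                    "null_mean": np.nan, "null_sd": np.nan, "Z": np.nan,
                    "p_value": np.nan, "fdr": 1.0, "validated": False,
                    "flagged": True,
                }
            )
            continue
        null = null_overlap_sample(t, size, n_perm, rng)
        mu, sd = null.mean(), null.std(ddof=1)
        z = (obs - mu) / sd if sd > 0 else np.inf * np.sign(obs - mu)
        p = float(stats.norm.sf(z))
        rows.append(
            {
                "module": label, "size": size, "obs_mean_TO": obs,
                "null_mean": mu, "null_sd": sd, "Z": z, "p_value": p,
                "fdr": np.nan, "validated": False, "flagged": False,
            }
        )
        p_track.append(len(rows) - 1)

    res = pd.DataFrame(rows)
    if p_track:
        q = bh_fdr(res.loc[p_track, "p_value"].to_numpy())
        res.loc[p_track, "fdr"] = q
        res.loc[p_track, "validated"] = q <= fdr_threshold
    return res
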
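"""Spearman correlation of module eigengenes and probesets with drinking traits.

All samples enter the correlation by default, NonDrinking animals carrying
trait value 0 (their intake); restricting to drinkers is an option. The
p-value uses the t approximation t = rho*sqrt((n-2)/(1-rho^2)) on n-2 df.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .traits import TRAIT_COLUMNS


def spearman_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman rho (average ranks for ties) and two-sided t-approximation p.

    Returns (nan, nan) when either vector is constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.std() == 0 or y.std() == 0:
        return float("nan"), float("nan")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    n = len(x)
    if abs(rho) >= 1.0:
        return rho, 0.0
    t = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
    p = float(2.0 * stats.t.sf(abs(t), n - 2))
    return rho, p


def _trait_matrix(
    traits: pd.DataFrame, sample_ids: list[str], sample_map: dict[str, str] | None
) -> pd.DataFrame:
    """Trait rows aligned to samples (sample -> mouse via sample_map, or
    identity when sample ids are mouse ids)."""
    tt = traits.set_index("mouse_id")
    mice = [sample_map.get(s, s) if sample_map else s for s in sample_ids]
    missing = [m for m in mice if m not in tt.index]
    if missing:
        raise ValueError(f"samples without a trait row: {missing}")
    return tt.loc[mice]


def correlate_eigengenes(
    eigengenes: pd.DataFrame,
    traits: pd.DataFrame,
    sample_map: dict[str, str] | None = None,
    include_nondrinkers: bool = True,
    trait_columns: list[str] | None = None,
) -> pd.DataFrame:
    """Module eigengene x trait Spearman correlation table."""
    return _correlate(
        eigengenes, "module", traits, sample_map, include_nondrinkers, trait_columns
    )


def correlate_genes(
    matrix: pd.DataFrame,
    traits: pd.DataFrame,
    sample_map: dict[str, str] | None = None,
    include_nondrinkers: bool = True,
    trait_columns: list[str] | None = None,
) -> pd.DataFrame:
    """Per-probeset x trait Spearman correlation table (S4-style GS / p.GS)."""
    return _correlate(
        matrix, "probeset", traits, sample_map, include_nondrinkers, trait_columns
    )


def _correlate(
    units: pd.DataFrame,
    unit_name: str,
    traits: pd.DataFrame,
    sample_map: dict[str, str] | None,
    include_nondrinkers: bool,
    trait_columns: list[str] | None,
) -> pd.DataFrame:
    samples = list(units.columns)
    tt = _trait_matrix(traits, samples, sample_map)
    if trait_columns is None:
        trait_columns = [c for c in TRAIT_COLUMNS if c in tt.columns]
    keep = np.ones(len(samples), dtype=bool)
    if not include_nondrinkers:
        # drinkers are the mice with a defined percent change (baseline > 0)
        keep = tt["pct_defined"].to_numpy(dtype=bool)
    rows = []
    x = units.to_numpy(dtype=float)[:, keep]
    for trait in trait_columns:
        tv = tt[trait].to_numpy(dtype=float)[keep]
        for i, unit in enumerate(units.index):
            rho, p = spearman_with_p(x[i], tv)
            rows.append(
                {
                    unit_name: unit,
                    "trait": trait,
                    "rho": rho,
                    "p_value": p,
                    "n": int(keep.sum()),
                    "flagged": not np.isfinite(rho),
                }
            )
    return pd.DataFrame(rows)
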
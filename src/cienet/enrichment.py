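"""Hypergeometric over-representation of gene lists in modules.

Upper-tail exact hypergeometric p for the overlap of two sets within a
universe, with BH-FDR (module/list overlaps, threshold 0.05) or Bonferroni
(cell-type marker lists, threshold 0.05) correction across the full
module-by-list table. The default universe is the probeset set that
entered the network.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .de import bh_fdr
from .network import GREY


def hypergeom_overlap(
    set_a: set[str], set_b: set[str], universe: set[str] | list[str]
) -> tuple[int, float]:
    """Overlap size and exact upper-tail hypergeometric p-value.

    P(X >= k) with X ~ Hypergeometric(N=|universe|, n=|B|, m=|A|).
    """
    uni = set(universe)
    for name, s in (("A", set_a), ("B", set_b)):
        extra = set(s) - uni
        if extra:
            raise ValueError(f"set {name} not contained in universe: {sorted(extra)[:5]}")
    n_univ = len(uni)
    m, n = len(set_a), len(set_b)
    k = len(set(set_a) & set(set_b))
    p = float(stats.hypergeom.sf(k - 1, n_univ, m, n))
    return k, min(p, 1.0)


def module_list_enrichment(
    assign: pd.Series,
    lists: dict[str, set[str]],
    universe: list[str] | set[str] | None = None,
    correction: str = "BH",
    threshold: float = 0.05,
) -> pd.DataFrame:
    """Test every non-grey module against every list; correct over the table.

    Lists are intersected with the universe before testing; empty lists are
    flagged and excluded from correction.
    """
    if correction not in ("BH", "Bonferroni"):
        raise ValueError("correction must be 'BH' or 'Bonferroni'")
    if universe is None:
        universe = list(assign.index)
    uni = set(universe)
    mods = [m for m in assign.unique() if m != GREY]
    rows = []
    for m in mods:
        mod_set = set(assign.index[assign == m]) & uni
        for name, lst in lists.items():
            lst_u = set(lst) & uni
            if not lst_u:
                rows.append(
                    {
                        "module": m, "list": name, "overlap": 0,
                        "module_size": len(mod_set), "list_size": 0,
                        "universe_size": len(uni), "p_value": np.nan,
                        "p_corrected": np.nan, "significant": False,
                        "flagged": True,
                    }
                )
                continue
            k, p = hypergeom_overlap(mod_set, lst_u, uni)
            rows.append(
                {
                    "module": m, "list": name, "overlap": k,
                    "module_size": len(mod_set), "list_size": len(lst_u),
                    "universe_size": len(uni), "p_value": p,
                    "p_corrected": np.nan, "significant": False,
                    "flagged": False,
                }
            )
    res = pd.DataFrame(rows)
    ok = ~res["flagged"]
    if ok.any():
        p = res.loc[ok, "p_value"].to_numpy()
        if correction == "BH":
            q = bh_fdr(p)
        else:
            q = np.minimum(p * p.size, 1.0)
        res.loc[ok, "p_corrected"] = q
        res.loc[ok, "significant"] = q <= threshold
    return res


def read_list_files(directory) -> dict[str, set[str]]:
    """Load gene lists from a directory: one id per line, named by filename."""
    from pathlib import Path

    out = {}
    for path in sorted(Path(directory).glob("*")):
        if path.is_file():
            ids = {line.strip() for line in path.read_text().splitlines() if line.strip()}
            out[path.stem] = ids
    return out
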
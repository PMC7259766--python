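#!/usr/bin/env python
"""Hypergeometric over-representation of per-contrast DE gene lists in the
detected modules (BH-FDR over the module x contrast table)."""

from pathlib import Path

import pandas as pd

from cienet import io
from cienet.de import significant_sets
from cienet.enrichment import module_list_enrichment

HERE = Path(__file__).resolve().parent
RES = HERE.parent / "results"


def main() -> None:
    de = pd.read_csv(RES / "de" / "de_pairwise.tsv", sep="\t")
    mods = pd.read_csv(RES / "network" / "modules.tsv", sep="\t")
    assign = pd.Series(mods["module"].to_numpy(), index=mods["probeset"], name="module")
    universe = list(assign.index)
    lists = {c: s & set(universe)
             for c, s in significant_sets(de, threshold=0.01).items()}
    res = module_list_enrichment(assign, lists, universe=universe, correction="BH",
                                 threshold=0.05)
    io.write_table(res, RES / "network" / "module_de_enrichment.tsv")
    sig = res[res["significant"]]
    print(f"{len(sig)} significant module x contrast overlaps (FDR<=0.05):")
    if len(sig):
        print(sig[["module", "list", "overlap", "p_corrected"]].to_string(index=False))


if __name__ == "__main__":
    main()
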
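#!/usr/bin/env python
"""Spearman correlation of module eigengenes (and probesets) with the
drinking traits; all samples enter, NonDrinking mice at trait 0."""

from pathlib import Path

import pandas as pd

from cienet import io
from cienet.traitcor import correlate_eigengenes, correlate_genes

HERE = Path(__file__).resolve().parent
RES = HERE.parent / "results"


def main() -> None:
    eig = pd.read_csv(RES / "network" / "eigengenes.tsv", sep="\t", index_col=0)
    traits = pd.read_csv(RES / "data" / "traits.tsv", sep="\t")
    expr = io.read_expression(RES / "preprocess" / "expression_normalized.tsv")
    res = correlate_eigengenes(eig, traits)
    io.write_table(res, RES / "network" / "eigengene_trait_correlation.tsv")
    io.write_table(correlate_genes(expr, traits),
                   RES / "network" / "gene_trait_correlation.tsv")
    c4 = res[res["trait"] == "abs_change_4"].sort_values("p_value")
    print("module eigengene vs cycle-4 change from baseline (strongest first):")
    print(c4[["module", "rho", "p_value"]].to_string(index=False))


if __name__ == "__main__":
    main()
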
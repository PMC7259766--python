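#!/usr/bin/env python
"""Build the weighted coexpression network and detect modules.

Soft-threshold fit table, adjacency -> TOM, dynamic tree cut, eigengenes,
connectivity statistics, and an MDS plot of the gene space. The TOM is
cached as .npy for the validation script."""

from pathlib import Path

import numpy as np

from cienet import io
from cienet.config import load_config
from cienet.network import (
    adjacency,
    connectivity_stats,
    detect_modules,
    module_eigengenes,
    pick_soft_threshold,
    topological_overlap,
)
from cienet.pipeline import _mds_plot

HERE = Path(__file__).resolve().parent
RES = HERE.parent / "results"
OUT = RES / "network"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    ncfg = load_config(HERE / "config.yaml").network
    expr = io.read_expression(RES / "preprocess" / "expression_normalized.tsv")
    power, fit = pick_soft_threshold(expr, candidate_powers=[1, 2, 4, 6, 8, 10, 12],
                                     override=ncfg.power)
    io.write_table(fit, OUT / "soft_threshold_fit.tsv")
    adj = adjacency(expr, ncfg)
    tom = topological_overlap(adj)
    np.save(OUT / "tom.npy", tom.to_numpy())
    (OUT / "tom_index.txt").write_text("\n".join(tom.index) + "\n")
    assign = detect_modules(tom, ncfg)
    assign.rename_axis("probeset").reset_index().to_csv(
        OUT / "modules.tsv", sep="\t", index=False
    )
    eig = module_eigengenes(expr.loc[adj.index], assign)
    eig.rename_axis("module").to_csv(OUT / "eigengenes.tsv", sep="\t", float_format="%.6g")
    io.write_table(connectivity_stats(adj, assign, eig, expr), OUT / "connectivity.tsv")
    _mds_plot(tom, assign, OUT / "module_mds.png")
    print(f"soft power {power} (override per config); module sizes:")
    print(assign.value_counts().to_string())


if __name__ == "__main__":
    main()
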
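#!/usr/bin/env python
"""Bootstrap module-disruption Z: concordance of per-gene connectivity
between CIE Drinking and Air NonDrinking versus 200 label-blind bootstrap
networks; modules with Z_cor.kIM <= -2 are flagged as disrupted."""

from pathlib import Path

import pandas as pd

from cienet import io
from cienet.config import load_config
from cienet.disruption import disruption_z

HERE = Path(__file__).resolve().parent
RES = HERE.parent / "results"


def main() -> None:
    cfg = load_config(HERE / "config.yaml")
    expr = io.read_expression(RES / "preprocess" / "expression_normalized.tsv")
    ann = io.check_matching(expr, io.read_annotation(RES / "data" / "annotation.csv"))
    mods = pd.read_csv(RES / "network" / "modules.tsv", sep="\t")
    assign = pd.Series(mods["module"].to_numpy(), index=mods["probeset"], name="module")
    assign = assign[assign != "grey"]
    res = disruption_z(expr.loc[assign.index], ann, *cfg.disrupt_groups, assign,
                       cfg.network, n_boot=cfg.disrupt_n_boot, seed=cfg.seed)
    io.write_table(res, RES / "network" / "module_disruption.tsv")
    print(res[["module", "size", "mod.cor.kIM", "Z_cor.kIM", "Z_cor.kME", "disrupted"]]
          .round(3).to_string(index=False))


if __name__ == "__main__":
    main()
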
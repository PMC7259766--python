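"""End-to-end orchestration of the coexpression analysis stages.

One config drives simulate/ingest -> quantile normalization -> differential
expression -> drinking traits -> network/modules -> permutation validation
-> eigengene-trait correlation -> module disruption -> enrichment, writing
every stage's table plus a combined per-module summary (disrupted /
trait-correlated / DE-over-represented). All randomness derives from a
single seed; outputs contain no timestamps, so a rerun with the same config
is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import io
from .de import contrast_overlap, pairwise_contrasts, significant_sets, two_factor_model
from .disruption import disruption_z
from .enrichment import module_list_enrichment
from .network import (
    GREY,
    NetworkConfig,
    adjacency,
    connectivity_stats,
    detect_modules,
    module_eigengenes,
    pick_soft_threshold,
    topological_overlap,
)
from .preprocess import anova_filter, quantile_normalize
from .simulate import SimConfig, ground_truth_frame, simulate_drinking, simulate_expression
from .traitcor import correlate_eigengenes, correlate_genes
from .traits import derive_traits
from .validation import validate_modules


@dataclass
class PipelineConfig:
    """Thresholds and inputs of one single-region run."""

    # either a simulate block or explicit input paths
    simulate: SimConfig | None = None
    expression_path: str | None = None
    annotation_path: str | None = None
    drinking_path: str | None = None

    network: NetworkConfig = field(default_factory=NetworkConfig)
    seed: int = 0
    de_fdr: float = 0.01
    anova_fdr: float = 0.01
    validate_fdr: float = 0.2
    validate_n_perm: int = 100
    disrupt_z: float = -2.0
    disrupt_n_boot: int = 200
    disrupt_groups: tuple[str, str] = ("CIE Drinking", "Air NonDrinking")
    enrich_fdr: float = 0.05
    trait_p: float = 0.01
    # probeset universe entering the network: the one-way-ANOVA filter
    # ("anova", the study's rule) or every probeset ("all")
    universe: str = "anova"
    moderate_variance: bool = False

    def validate(self) -> None:
        if self.simulate is None and (
            self.expression_path is None or self.annotation_path is None
        ):
            raise ValueError("config needs a simulate block or input paths")
        for name, v, lo, hi in (
            ("de_fdr", self.de_fdr, 0, 1),
            ("anova_fdr", self.anova_fdr, 0, 1),
            ("validate_fdr", self.validate_fdr, 0, 1),
            ("enrich_fdr", self.enrich_fdr, 0, 1),
            ("trait_p", self.trait_p, 0, 1),
        ):
            if not lo < v <= hi:
                raise ValueError(f"{name} out of range: {v}")
        if self.universe not in ("anova", "all"):
            raise ValueError("universe must be 'anova' or 'all'")
        self.network.validate()


def config_hash(cfg: PipelineConfig) -> str:
    blob = json.dumps(asdict(cfg), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(cfg: PipelineConfig, outdir: str | Path) -> Path:
    """Run every stage, write per-stage TSVs under outdir, return outdir."""
    cfg.validate()
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[str] = [f"config_hash: {config_hash(cfg)}", f"seed: {cfg.seed}"]

    def stage(name: str):
        log.append(f"stage: {name}")

    # --- ingest or simulate -------------------------------------------------
    truth = None
    if cfg.simulate is not None:
        stage("simulate")
        sim = cfg.simulate
        drinking = simulate_drinking(sim)
        expr, ann, truth = simulate_expression(sim, drinking)
        io.write_expression(expr, out / "expression.tsv")
        io.write_annotation(ann, out / "annotation.csv")
        io.write_drinking(drinking, out / "drinking.csv")
        io.write_table(ground_truth_frame(truth), out / "ground_truth.tsv")
    else:
        stage("ingest")
        expr = io.read_expression(cfg.expression_path)
        ann = io.read_annotation(cfg.annotation_path)
        ann = io.check_matching(expr, ann)
        drinking = io.read_drinking(cfg.drinking_path) if cfg.drinking_path else None

    # --- preprocess ---------------------------------------------------------
    stage("preprocess")
    norm = quantile_normalize(expr)
    io.write_expression(norm, out / "expression_normalized.tsv")

    # --- differential expression -------------------------------------------
    stage("differential_expression")
    de = pairwise_contrasts(norm, ann, moderate=cfg.moderate_variance)
    io.write_table(de, out / "de_pairwise.tsv")
    io.write_table(two_factor_model(norm, ann), out / "de_two_factor.tsv")
    io.write_table(contrast_overlap(de, fdr=cfg.de_fdr), out / "de_overlap.tsv")

    # --- drinking traits ----------------------------------------------------
    traits = None
    if drinking is not None:
        stage("traits")
        traits = derive_traits(drinking)
        io.write_table(traits, out / "traits.tsv")

    # --- network ------------------------------------------------------------
    stage("network")
    if cfg.universe == "anova":
        universe = anova_filter(norm, ann, fdr_threshold=cfg.anova_fdr)
    else:
        universe = list(norm.index)
    net_expr = norm.loc[universe]
    if len(universe) < 2 * cfg.network.min_module_size:
        raise RuntimeError(
            f"network stage: universe of {len(universe)} probesets is too small"
        )
    power, fit_table = pick_soft_threshold(net_expr, override=cfg.network.power)
    io.write_table(fit_table, out / "soft_threshold_fit.tsv")
    adj = adjacency(net_expr, cfg.network)
    tom = topological_overlap(adj)
    assign = detect_modules(tom, cfg.network)
    assign.rename_axis("probeset").reset_index().to_csv(
        out / "modules.tsv", sep="\t", index=False
    )
    eig = module_eigengenes(net_expr.loc[adj.index], assign)
    eig.rename_axis("module").to_csv(out / "eigengenes.tsv", sep="\t", float_format="%.6g")
    conn = connectivity_stats(adj, assign, eig, net_expr)
    io.write_table(conn, out / "connectivity.tsv")
    _mds_plot(tom, assign, out / "module_mds.png")

    # --- module validation --------------------------------------------------
    stage("validation")
    validation = validate_modules(
        tom, assign, n_perm=cfg.validate_n_perm, seed=cfg.seed,
        fdr_threshold=cfg.validate_fdr,
    )
    io.write_table(validation, out / "module_validation.tsv")

    # --- trait correlation --------------------------------------------------
    eig_cor = None
    if traits is not None and len(eig):
        stage("trait_correlation")
        eig_cor = correlate_eigengenes(eig, traits)
        io.write_table(eig_cor, out / "eigengene_trait_correlation.tsv")
        io.write_table(correlate_genes(net_expr, traits), out / "gene_trait_correlation.tsv")

    # --- module disruption --------------------------------------------------
    stage("disruption")
    disruption = disruption_z(
        net_expr, ann, cfg.disrupt_groups[0], cfg.disrupt_groups[1], assign,
        cfg.network, n_boot=cfg.disrupt_n_boot, seed=cfg.seed,
    )
    io.write_table(disruption, out / "module_disruption.tsv")

    # --- enrichment: modules vs per-contrast DE lists -----------------------
    stage("enrichment")
    de_lists = {
        c: s & set(universe) for c, s in significant_sets(de, threshold=cfg.de_fdr).items()
    }
    enrich = module_list_enrichment(
        assign, de_lists, universe=universe, correction="BH", threshold=cfg.enrich_fdr
    )
    io.write_table(enrich, out / "module_de_enrichment.tsv")

    # --- combined summary ---------------------------------------------------
    stage("summary")
    summary = _module_summary(cfg, validation, disruption, eig_cor, enrich)
    io.write_table(summary, out / "module_summary.tsv")

    if truth is not None:
        io.write_table(_recovery_report(truth, assign), out / "ground_truth_recovery.tsv")

    (out / "run_log.txt").write_text("\n".join(log) + "\n")
    return out


def _module_summary(
    cfg: PipelineConfig,
    validation: pd.DataFrame,
    disruption: pd.DataFrame,
    eig_cor: pd.DataFrame | None,
    enrich: pd.DataFrame,
) -> pd.DataFrame:
    """Per-module triple: disrupted, cycle-4-change correlated, DE-enriched."""
    mods = [m for m in validation["module"] if m != GREY]
    dis = disruption.set_index("module")
    rows = []
    for m in mods:
        disrupted = bool(dis.loc[m, "disrupted"]) if m in dis.index else False
        trait_corr = False
        if eig_cor is not None:
            sub = eig_cor[(eig_cor["module"] == m) & (eig_cor["trait"] == "pct_change_4")]
            trait_corr = bool((sub["p_value"] <= cfg.trait_p).any())
        sub_e = enrich[(enrich["module"] == m) & (enrich["list"] == "C4")]
        de_over = bool(sub_e["significant"].any())
        val = validation.set_index("module").loc[m]
        rows.append(
            {
                "module": m,
                "size": int(val["size"]),
                "validated": bool(val["validated"]),
                "disrupted": disrupted,
                "trait_correlated": trait_corr,
                "de_overrepresented": de_over,
            }
        )
    return pd.DataFrame(rows)


def _recovery_report(truth, assign: pd.Series) -> pd.DataFrame:
    """How well detected modules recover the planted partition."""
    from sklearn.metrics import adjusted_rand_score

    planted = pd.Series(truth.module_of_gene).loc[assign.index]
    ari = adjusted_rand_score(planted.to_numpy(), assign.to_numpy())
    rows = [{"metric": "adjusted_rand_index", "value": ari}]
    for lab in truth.module_labels():
        members = planted.index[planted == lab]
        found = assign.loc[members]
        best = found[found != GREY].mode()
        frac = float((found == best.iloc[0]).mean()) if len(best) else 0.0
        rows.append({"metric": f"recovery_{lab}", "value": frac})
    return pd.DataFrame(rows)


def _mds_plot(tom: pd.DataFrame, assign: pd.Series, path: Path) -> None:
    """Classical-MDS scatter of genes from TOM dissimilarity, colored by module."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import numpy as np

    d = 1.0 - tom.to_numpy()
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1][:2]
    coords = vecs[:, order] * np.sqrt(np.maximum(vals[order], 0.0))
    fig, ax = plt.subplots(figsize=(5, 5))
    for m in assign.unique():
        sel = (assign == m).to_numpy()
        color = m if m != GREY else "lightgrey"
        try:
            ax.scatter(coords[sel, 0], coords[sel, 1], s=6, label=m, c=color)
        except ValueError:
            ax.scatter(coords[sel, 0], coords[sel, 1], s=6, label=m)
    ax.set_xlabel("MDS 1")
    ax.set_ylabel("MDS 2")
    ax.legend(fontsize=6, markerscale=2)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
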
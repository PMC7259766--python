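"""Synthetic chronic-intermittent-ethanol (CIE) study generator.

Emulates a single brain region of a 2x2 vapor-chamber (CIE vs Air) by
2-bottle-choice drinking (Drinking vs NonDrinking) design: daily intake
records over six baseline weeks plus four CIE cycles, and a log2 expression
matrix with planted coexpression modules, differential-expression shifts,
eigengene-drinking correlation, and group-specific connectivity disruption.
Every planted feature is returned as ground truth so downstream stages can
be tested by parameter recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .traits import derive_traits

GROUPS = ("CIE Drinking", "CIE NonDrinking", "Air Drinking", "Air NonDrinking")

N_BASELINE_WEEKS = 6
N_CYCLES = 4
DAYS_PER_PHASE = 5


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass
class SimConfig:
    """Parameters of the synthetic study.

    Expression model for gene g in module q, sample s:

        x_gs = mu_g + lambda_g * f_q(s) + delta * I[s in DE groups] + eps_gs

    with loadings ``lambda_g ~ U(loading_range)``, residual sd ``noise_sd``
    and per-sample factors f_q standardized over the pooled sample set.
    Background genes are pure noise around their baseline mean.
    """

    n_genes: int = 2000
    module_sizes: tuple[int, ...] = (100, 100, 100, 100, 100)
    n_per_group: int = 12
    loading_range: tuple[float, float] = (0.5, 0.9)
    noise_sd: float = 0.5
    baseline_expression_range: tuple[float, float] = (6.0, 10.0)
    # differential expression: mean shift applied to n_de_genes background
    # genes in the listed groups
    de_effect: float = 0.8
    n_de_genes: int = 100
    de_groups: tuple[str, ...] = ("CIE Drinking",)
    # module index -> target population Spearman rho between the module factor
    # and cycle-4 change-from-baseline intake
    trait_linked_modules: dict[int, float] = field(default_factory=lambda: {0: 0.7})
    # module index -> (group, fraction of member genes decorrelated in group)
    disrupted_modules: dict[int, tuple[str, float]] = field(
        default_factory=lambda: {1: ("CIE Drinking", 0.8)}
    )
    # drinking model (g/kg)
    baseline_intake_mean: float = 2.5
    cie_escalation: float = 0.35  # added per CIE cycle, CIE Drinking group
    air_escalation: float = 0.08  # added per cycle, Air Drinking group
    intake_sd: float = 0.4
    region: str = "SIM"
    seed: int = 0

    @property
    def n_modules(self) -> int:
        return len(self.module_sizes)

    @property
    def n_samples(self) -> int:
        return 4 * self.n_per_group

    def validate(self) -> None:
        if self.n_per_group < 2:
            raise ConfigError("n_per_group must be >= 2")
        if any(m < 3 for m in self.module_sizes):
            raise ConfigError("each module size must be >= 3")
        if sum(self.module_sizes) > self.n_genes:
            raise ConfigError(
                f"sum(module_sizes)={sum(self.module_sizes)} exceeds n_genes={self.n_genes}"
            )
        lo, hi = self.loading_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ConfigError("loading_range must be an interval within [0, 1]")
        for q, (group, frac) in self.disrupted_modules.items():
            if group not in GROUPS:
                raise ConfigError(f"unknown group {group!r} for disrupted module {q}")
            if not 0.0 <= frac <= 1.0:
                raise ConfigError("disruption fraction must be in [0, 1]")
            if q >= self.n_modules:
                raise ConfigError(f"disrupted module index {q} out of range")
        for q in self.trait_linked_modules:
            if q >= self.n_modules:
                raise ConfigError(f"trait-linked module index {q} out of range")
        if self.n_de_genes > self.n_genes - sum(self.module_sizes):
            raise ConfigError("n_de_genes exceeds the number of background genes")
        if self.noise_sd <= 0:
            raise ConfigError("noise_sd must be positive")


@dataclass
class GroundTruth:
    """Planted structure of one simulated dataset."""

    module_of_gene: dict[str, str]  # probeset -> planted module label
    de_genes_per_contrast: dict[str, set[str]]
    trait_rho_planted: dict[str, float]  # module label -> target Spearman rho
    disrupted: dict[str, str]  # module label -> affected group
    disrupted_genes: dict[str, set[str]]  # module label -> decorrelated genes

    def module_labels(self) -> list[str]:
        seen: list[str] = []
        for lab in self.module_of_gene.values():
            if lab != "background" and lab not in seen:
                seen.append(lab)
        return seen


def _mouse_table(cfg: SimConfig) -> pd.DataFrame:
    rows = []
    i = 0
    for group in GROUPS:
        vapor, drinking = group.split(" ", 1)
        for _ in range(cfg.n_per_group):
            i += 1
            rows.append(
                {
                    "mouse_id": f"m{i:03d}",
                    "group": group,
                    "vapor": vapor,
                    "drinking": drinking,
                }
            )
    return pd.DataFrame(rows)


def _phase_schedule() -> pd.DataFrame:
    """Session -> phase label: 6 baseline weeks then 4 CIE cycles, 5 days each."""
    sessions = []
    s = 0
    for w in range(1, N_BASELINE_WEEKS + 1):
        for _ in range(DAYS_PER_PHASE):
            s += 1
            sessions.append((s, f"baseline_w{w}"))
    for c in range(1, N_CYCLES + 1):
        for _ in range(DAYS_PER_PHASE):
            s += 1
            sessions.append((s, f"cie_c{c}"))
    return pd.DataFrame(sessions, columns=["session", "phase"])


def phase_mean(cfg: SimConfig, group: str, phase: str) -> float:
    """Configured mean daily intake (g/kg) for a group in a phase."""
    if group.endswith("NonDrinking"):
        return 0.0
    if phase.startswith("baseline"):
        return cfg.baseline_intake_mean
    cycle = int(phase.rsplit("c", 1)[1])
    slope = cfg.cie_escalation if group == "CIE Drinking" else cfg.air_escalation
    return cfg.baseline_intake_mean + slope * cycle


def simulate_drinking(cfg: SimConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Daily 2-bottle-choice intake for every mouse and session.

    Drinkers get phase-mean intake plus i.i.d. Gaussian noise truncated at 0;
    the CIE-Drinking group escalates across cycles, the Air-Drinking group
    escalates modestly, NonDrinking mice are identically zero.

    Returns a long DataFrame (mouse_id, group, session, phase, intake_gkg).
    """
    cfg.validate()
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    mice = _mouse_table(cfg)
    sched = _phase_schedule()
    rec = mice.merge(sched, how="cross")
    means = np.array(
        [phase_mean(cfg, g, p) for g, p in zip(rec["group"], rec["phase"])]
    )
    noise = rng.normal(0.0, cfg.intake_sd, size=len(rec))
    intake = np.clip(means + noise, 0.0, None)
    intake[rec["drinking"].to_numpy() == "NonDrinking"] = 0.0
    rec["intake_gkg"] = intake
    return rec[["mouse_id", "group", "session", "phase", "intake_gkg"]]


def _calibrate_trait_factor(
    trait: np.ndarray, target_rho: float, seed: int
) -> float:
    """Mixing weight a such that f = a*z(trait) + sqrt(1-a^2)*noise has
    population Spearman rho with `trait` equal to target_rho.

    The trait vector is fixed (and heavily tied: NonDrinking mice carry 0),
    so the calibration is numerical: Monte-Carlo estimate of E[rho_s] on a
    grid of a, then monotone interpolation. Uses a dedicated RNG so the
    calibration does not perturb the main simulation stream.
    """
    from scipy.stats import spearmanr

    rng = np.random.default_rng(np.random.SeedSequence([seed, 915]))
    z = (trait - trait.mean()) / trait.std()
    n = len(trait)
    grid = np.linspace(0.0, 1.0, 21)
    nrep = 300
    noise = rng.normal(size=(nrep, n))
    mean_rho = np.empty_like(grid)
    for i, a in enumerate(grid):
        f = a * z + np.sqrt(1.0 - a * a) * noise
        rhos = [spearmanr(f[r], trait).statistic for r in range(nrep)]
        mean_rho[i] = np.mean(rhos)
    target = abs(target_rho)
    if target >= mean_rho[-1]:
        a = 1.0
    else:
        a = float(np.interp(target, mean_rho, grid))
    return a if target_rho >= 0 else -a


def simulate_expression(
    cfg: SimConfig, drinking: pd.DataFrame | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Simulate the expression matrix, sample annotation and ground truth.

    Returns (expression probesets x samples, annotation, GroundTruth).
    One sample per mouse; sample ids equal mouse ids.
    """
    cfg.validate()
    root = np.random.SeedSequence([cfg.seed, 2])
    rng = np.random.default_rng(root)
    if drinking is None:
        drinking = simulate_drinking(cfg)

    mice = _mouse_table(cfg)
    sample_ids = mice["mouse_id"].tolist()
    group = mice["group"].to_numpy()
    n = len(sample_ids)
    p = cfg.n_genes

    traits = derive_traits(drinking)
    trait = traits.set_index("mouse_id").loc[sample_ids, "abs_change_4"].to_numpy()

    probesets = [f"ps{i:05d}" for i in range(1, p + 1)]
    module_labels = [f"planted_{q + 1}" for q in range(cfg.n_modules)]

    # per-module factors, standardized over the pooled samples
    factors = np.empty((cfg.n_modules, n))
    for q in range(cfg.n_modules):
        if q in cfg.trait_linked_modules:
            rho = cfg.trait_linked_modules[q]
            a = _calibrate_trait_factor(trait, rho, cfg.seed)
            z = (trait - trait.mean()) / trait.std()
            f = a * z + np.sqrt(1.0 - a * a) * rng.normal(size=n)
        else:
            f = rng.normal(size=n)
        factors[q] = (f - f.mean()) / f.std()

    mu = rng.uniform(*cfg.baseline_expression_range, size=p)
    x = np.tile(mu[:, None], (1, n))

    module_of_gene = {ps: "background" for ps in probesets}
    lo, hi = cfg.loading_range
    start = 0
    disrupted_genes: dict[str, set[str]] = {}
    for q, size in enumerate(cfg.module_sizes):
        idx = np.arange(start, start + size)
        start += size
        lam = rng.uniform(lo, hi, size=size)
        x[idx] += lam[:, None] * factors[q][None, :]
        for i in idx:
            module_of_gene[probesets[i]] = module_labels[q]
        if q in cfg.disrupted_modules:
            dgroup, frac = cfg.disrupted_modules[q]
            n_aff = int(np.ceil(frac * size))
            aff = rng.choice(idx, size=n_aff, replace=False)
            cols = np.flatnonzero(group == dgroup)
            # replace the shared-factor term by an independent per-gene factor
            # (re-drawn loading, random sign) so within-module correlation is
            # broken in this group only
            lam2 = rng.uniform(lo, hi, size=n_aff) * rng.choice([-1.0, 1.0], size=n_aff)
            eta = rng.normal(size=(n_aff, len(cols)))
            lam_aff = lam[aff - idx[0]]
            x[np.ix_(aff, cols)] -= lam_aff[:, None] * factors[q][None, cols]
            x[np.ix_(aff, cols)] += lam2[:, None] * eta
            disrupted_genes[module_labels[q]] = {probesets[i] for i in aff}

    # DE genes: background genes shifted in the affected groups
    bg = np.arange(sum(cfg.module_sizes), p)
    de_idx = rng.choice(bg, size=cfg.n_de_genes, replace=False) if cfg.n_de_genes else np.array([], int)
    if cfg.n_de_genes and cfg.de_effect != 0.0:
        affected_cols = np.flatnonzero(np.isin(group, cfg.de_groups))
        x[np.ix_(de_idx, affected_cols)] += cfg.de_effect
    de_set = {probesets[i] for i in de_idx}

    x += rng.normal(0.0, cfg.noise_sd, size=(p, n))

    expr = pd.DataFrame(x, index=pd.Index(probesets, name="probeset"), columns=sample_ids)
    ann = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "vapor": mice["vapor"],
            "drinking": mice["drinking"],
            "region": cfg.region,
            "batch": "b1",
        }
    )

    # a shift confined to CIE Drinking shows up in every contrast involving it
    de_contrasts = {"C1": de_set, "C3": de_set, "C4": de_set} if cfg.de_groups == ("CIE Drinking",) else {}
    truth = GroundTruth(
        module_of_gene=module_of_gene,
        de_genes_per_contrast=de_contrasts,
        trait_rho_planted={
            module_labels[q]: r for q, r in cfg.trait_linked_modules.items()
        },
        disrupted={module_labels[q]: g for q, (g, _) in cfg.disrupted_modules.items()},
        disrupted_genes=disrupted_genes,
    )
    return expr, ann, truth


def ground_truth_frame(truth: GroundTruth) -> pd.DataFrame:
    """Flatten a GroundTruth to one record per planted feature (for TSV export)."""
    rows = [
        {"kind": "module", "item": ps, "value": lab}
        for ps, lab in truth.module_of_gene.items()
        if lab != "background"
    ]
    rows += [
        {"kind": f"de_{c}", "item": ps, "value": "shifted"}
        for c, genes in truth.de_genes_per_contrast.items()
        for ps in sorted(genes)
    ]
    rows += [
        {"kind": "trait_rho", "item": lab, "value": str(rho)}
        for lab, rho in truth.trait_rho_planted.items()
    ]
    rows += [
        {"kind": "disrupted", "item": lab, "value": grp}
        for lab, grp in truth.disrupted.items()
    ]
    return pd.DataFrame(rows, columns=["kind", "item", "value"])
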
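"""Bootstrap module-disruption Z statistics."""

import numpy as np
import pandas as pd
import pytest

from cienet.disruption import disruption_z, group_connectivity
from cienet.network import NetworkConfig
from cienet.simulate import SimConfig, simulate_expression


@pytest.fixture(scope="module")
def net_cfg():
    return NetworkConfig(power=6)


def test_self_comparison_is_perfect(small_sim, planted_assignment, net_cfg):
    expr = small_sim["expr"].loc[planted_assignment.index]
    res = disruption_z(
        expr, small_sim["ann"], "Air Drinking", "Air Drinking",
        planted_assignment, net_cfg, n_boot=40, seed=3,
    )
    np.testing.assert_allclose(res["mod.cor.kIM"], 1.0, atol=1e-10)
    assert not res["disrupted"].any()


def test_group_connectivity_matches_full_when_group_is_everything(
    small_sim, planted_assignment, net_cfg
):
    expr = small_sim["expr"].loc[planted_assignment.index]
    ann = small_sim["ann"].copy()
    one = ann.assign(vapor="CIE", drinking="Drinking")
    conn = group_connectivity(expr, one, "CIE Drinking", planted_assignment, net_cfg)
    from cienet.network import adjacency, connectivity_stats, module_eigengenes

    adj = adjacency(expr, net_cfg)
    eig = module_eigengenes(expr, planted_assignment)
    full = connectivity_stats(adj, planted_assignment, eig, expr)
    np.testing.assert_allclose(conn["kIM"], full["kIM"], atol=1e-9)


def test_duplicated_samples_leave_connectivity_unchanged(
    small_sim, planted_assignment, net_cfg
):
    from cienet.disruption import _module_index_map, _subset_connectivity

    expr = small_sim["expr"].loc[planted_assignment.index]
    x = expr.to_numpy()
    mods = _module_index_map(planted_assignment, expr.index)
    cols = np.arange(8)
    a = _subset_connectivity(x, cols, mods, net_cfg, "eigengene")
    b = _subset_connectivity(x, np.concatenate([cols, cols]), mods, net_cfg, "eigengene")
    for m in mods:
        np.testing.assert_allclose(a[m][0], b[m][0], atol=1e-9)


def test_disrupted_group_kim_depressed(small_sim, planted_assignment, net_cfg):
    """In the affected group, scrambled genes lose intramodular connectivity."""
    expr = small_sim["expr"].loc[planted_assignment.index]
    ann = small_sim["ann"]
    truth = small_sim["truth"]
    cie = group_connectivity(expr, ann, "CIE Drinking", planted_assignment, net_cfg)
    ctrl = group_connectivity(expr, ann, "Air NonDrinking", planted_assignment, net_cfg)
    scrambled = sorted(truth.disrupted_genes["planted_2"])
    kim_cie = cie.set_index("probeset").loc[scrambled, "kIM"].mean()
    kim_ctrl = ctrl.set_index("probeset").loc[scrambled, "kIM"].mean()
    assert kim_ctrl > 2 * kim_cie


def test_seeded_reproducibility(small_sim, planted_assignment, net_cfg):
    expr = small_sim["expr"].loc[planted_assignment.index]
    kw = dict(n_boot=30, seed=7)
    a = disruption_z(
        expr, small_sim["ann"], "CIE Drinking", "Air NonDrinking",
        planted_assignment, net_cfg, **kw,
    )
    b = disruption_z(
        expr, small_sim["ann"], "CIE Drinking", "Air NonDrinking",
        planted_assignment, net_cfg, **kw,
    )
    pd.testing.assert_frame_equal(a, b)


def test_larger_disruption_gives_smaller_z(net_cfg):
    """Median Z_cor.kIM decreases stochastically with disruption fraction."""
    meds = {}
    for frac in (0.2, 0.9):
        zs = []
        for seed in (1, 2, 3, 4):
            cfg = SimConfig(
                n_genes=300, module_sizes=(80, 80), n_per_group=10, n_de_genes=0,
                trait_linked_modules={},
                disrupted_modules={0: ("CIE Drinking", frac)}, seed=seed,
            )
            expr, ann, truth = simulate_expression(cfg)
            pl = pd.Series(truth.module_of_gene)
            assign = pd.Series(
                pl[pl != "background"].to_numpy(), index=pl.index[pl != "background"]
            )
            res = disruption_z(
                expr.loc[assign.index], ann, "CIE Drinking", "Air NonDrinking",
                assign, net_cfg, n_boot=60, seed=seed,
            )
            zs.append(res.set_index("module").loc["planted_1", "Z_cor.kIM"])
        meds[frac] = np.median(zs)
    assert meds[0.9] < meds[0.2]


def test_schema_and_flags(small_sim, planted_assignment, net_cfg):
    expr = small_sim["expr"].loc[planted_assignment.index]
    res = disruption_z(
        expr, small_sim["ann"], "CIE Drinking", "Air NonDrinking",
        planted_assignment, net_cfg, n_boot=30, seed=5,
    )
    expected = {
        "module", "size", "mod.cor.kME", "mean.boot.cor.kME", "sd.boot.cor.kME",
        "Z_cor.kME", "mod.cor.kIM", "mean.boot.cor.kIM", "sd.boot.cor.kIM",
        "Z_cor.kIM", "disrupted", "flagged",
    }
    assert set(res.columns) == expected
    assert (res["disrupted"] == (res["Z_cor.kIM"] <= -2)).all()


def test_ktotal_mode_runs(small_sim, planted_assignment, net_cfg):
    expr = small_sim["expr"].loc[planted_assignment.index]
    res = disruption_z(
        expr, small_sim["ann"], "CIE Drinking", "Air NonDrinking",
        planted_assignment, net_cfg, n_boot=60, seed=5, kme_mode="ktotal",
    )
    assert np.isfinite(res["Z_cor.kME"]).all()
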
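"""Pairwise contrasts, the two-factor model, and BH-FDR adjustment."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cienet.de import (
    CONTRASTS,
    bh_fdr,
    contrast_overlap,
    pairwise_contrasts,
    significant_sets,
    two_factor_model,
)
from cienet.simulate import SimConfig, simulate_expression


def brute_force_bh(p: np.ndarray) -> np.ndarray:
    """Independent step-up implementation straight from the definition."""
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    for rank_pos, i in enumerate(order):
        candidates = [m * p[order[j]] / (j + 1) for j in range(rank_pos, m)]
        q[i] = min(1.0, min(candidates))
    return q


class TestBhFdr:
    def test_hand_computed_example(self):
        np.testing.assert_allclose(bh_fdr(np.array([0.01, 0.02, 0.03])), [0.03, 0.03, 0.03])

    def test_ties_and_singleton(self):
        np.testing.assert_allclose(bh_fdr(np.array([0.2, 0.2, 0.2])), [0.2, 0.2, 0.2])
        np.testing.assert_allclose(bh_fdr(np.array([0.37])), [0.37])

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=40))
    def test_matches_brute_force_definition(self, p):
        p = np.asarray(p)
        np.testing.assert_allclose(bh_fdr(p), brute_force_bh(p), atol=1e-12)

    def test_monotone_in_sorted_p(self, rng):
        p = rng.uniform(size=500)
        q = bh_fdr(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()
        assert ((q >= 0) & (q <= 1)).all()

    def test_rejects_invalid(self):
        with pytest.raises(ValueError):
            bh_fdr(np.array([0.5, 1.2]))


class TestPairwiseContrasts:
    def test_six_labeled_contrasts(self, small_sim):
        res = pairwise_contrasts(small_sim["expr"].iloc[:50], small_sim["ann"])
        assert sorted(res["contrast"].unique()) == ["C1", "C2", "C3", "C4", "C5", "C6"]
        assert CONTRASTS["C1"] == ("CIE Drinking", "Air Drinking")
        assert CONTRASTS["C4"] == ("CIE Drinking", "Air NonDrinking")
        assert len(res) == 50 * 6

    def test_log_ratio_transitivity_exact(self, small_sim):
        """C4 = C3 + C2 and C1 = C4 - C6 by group-mean arithmetic."""
        res = pairwise_contrasts(small_sim["expr"].iloc[:80], small_sim["ann"])
        lr = res.pivot(index="probeset", columns="contrast", values="log_ratio")
        np.testing.assert_allclose(lr["C4"], lr["C3"] + lr["C2"], atol=1e-10)
        np.testing.assert_allclose(lr["C1"], lr["C4"] - lr["C6"], atol=1e-10)

    def test_identical_groups_null(self, rng):
        x = rng.normal(size=(20, 16))
        x[:, 4:8] = x[:, 0:4]  # Air Drinking duplicates CIE Drinking
        ann = pd.DataFrame(
            {
                "sample_id": [f"s{i}" for i in range(16)],
                "vapor": ["CIE"] * 4 + ["Air"] * 4 + ["CIE"] * 4 + ["Air"] * 4,
                "drinking": ["Drinking"] * 8 + ["NonDrinking"] * 8,
            }
        )
        m = pd.DataFrame(x, columns=ann["sample_id"])
        res = pairwise_contrasts(m, ann)
        c1 = res[res["contrast"] == "C1"]
        np.testing.assert_allclose(c1["log_ratio"], 0, atol=1e-12)
        np.testing.assert_allclose(c1["t"], 0, atol=1e-12)
        np.testing.assert_allclose(c1["p_value"], 1, atol=1e-12)

    def test_missing_group_rejected(self, small_sim):
        ann = small_sim["ann"].copy()
        keep = ann["drinking"] == "Drinking"
        with pytest.raises(ValueError, match="missing"):
            pairwise_contrasts(
                small_sim["expr"].loc[:, ann.loc[keep, "sample_id"]].iloc[:5],
                ann[keep].reset_index(drop=True),
            )

    def test_null_type_one_error_rate(self):
        cfg = SimConfig(
            n_genes=4000, module_sizes=(), n_de_genes=0,
            trait_linked_modules={}, disrupted_modules={}, seed=13,
        )
        expr, ann, _ = simulate_expression(cfg)
        res = pairwise_contrasts(expr, ann)
        for _, sub in res.groupby("contrast"):
            rate = (sub["p_value"] < 0.05).mean()
            assert abs(rate - 0.05) < 0.05 * 0.35  # generous at 4k genes

    def test_moderated_variant_keeps_contracts(self, small_sim):
        res = pairwise_contrasts(small_sim["expr"].iloc[:200], small_sim["ann"], moderate=True)
        assert ((res["p_value"] >= 0) & (res["p_value"] <= 1)).all()
        assert len(res) == 200 * 6


class TestTwoFactor:
    def test_matches_statsmodels_ols(self, small_sim):
        """Effect-coded model agrees with a statsmodels fit per gene."""
        import statsmodels.formula.api as smf

        expr = small_sim["expr"].iloc[:5]
        ann = small_sim["ann"]
        res = two_factor_model(expr, ann)
        for i, ps in enumerate(expr.index):
            df = pd.DataFrame(
                {
                    "y": expr.iloc[i].to_numpy(),
                    "a": np.where(ann["vapor"] == "CIE", 1.0, -1.0),
                    "b": np.where(ann["drinking"] == "Drinking", 1.0, -1.0),
                }
            )
            fit = smf.ols("y ~ a + b + a:b", data=df).fit()
            mine = res[res["probeset"] == ps].set_index("contrast")
            np.testing.assert_allclose(mine.loc["vapor", "t"], fit.tvalues["a"], atol=1e-8)
            np.testing.assert_allclose(
                mine.loc["interaction", "p_value"], fit.pvalues["a:b"], atol=1e-8
            )

    def test_constant_matrix_flagged(self, small_sim):
        ann = small_sim["ann"]
        m = pd.DataFrame(
            np.full((3, len(ann)), 7.0), columns=ann["sample_id"],
            index=["a", "b", "c"],
        )
        res = two_factor_model(m, ann)
        assert res["zero_variance"].all()
        np.testing.assert_allclose(res["p_value"], 1.0)

    def test_interaction_detected_for_single_cell_shift(self, small_sim):
        """A shift confined to one cell of the 2x2 loads on the interaction."""
        truth = small_sim["truth"]
        res = two_factor_model(small_sim["expr"], small_sim["ann"])
        de = sorted(truth.de_genes_per_contrast["C4"])
        inter = res[(res["contrast"] == "interaction")].set_index("probeset")
        bg = [g for g, m in truth.module_of_gene.items() if m == "background" and g not in set(de)]
        assert (inter.loc[de, "p_value"] < 0.05).mean() > 0.5
        assert (inter.loc[bg, "p_value"] < 0.05).mean() < 0.15


class TestOverlap:
    def test_trivial_set_algebra(self):
        res = pd.DataFrame(
            {
                "probeset": ["a", "b", "c"],
                "contrast": ["C1", "C3", "C4"],
                "fdr": [0.001, 0.001, 0.001],
            }
        )
        out = contrast_overlap(res, fdr=0.01)
        assert (out["overlap"] == 0).all()

    def test_planted_de_concentrates_in_c1_c3_c4(self, small_sim):
        res = pairwise_contrasts(small_sim["expr"], small_sim["ann"])
        sets = significant_sets(res, threshold=0.05, column="p_value")
        planted = small_sim["truth"].de_genes_per_contrast["C4"]
        triple = sets["C1"] & sets["C3"] & sets["C4"]
        assert len(triple & planted) / len(planted) >= 0.5
        assert len(sets["C2"] & planted) <= 0.2 * len(planted)
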
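import numpy as np
import pandas as pd
import pytest

from cienet.network import NetworkConfig, adjacency, topological_overlap
from cienet.simulate import SimConfig, simulate_drinking, simulate_expression


@pytest.fixture(scope="session")
def small_cfg() -> SimConfig:
    """Compact study: 3 planted 60-gene modules in 600 genes, 8 mice/group."""
    return SimConfig(
        n_genes=600,
        module_sizes=(60, 60, 60),
        n_per_group=8,
        loading_range=(0.6, 0.9),
        n_de_genes=40,
        trait_linked_modules={0: 0.7},
        disrupted_modules={1: ("CIE Drinking", 0.8)},
        seed=11,
    )


@pytest.fixture(scope="session")
def small_sim(small_cfg):
    drinking = simulate_drinking(small_cfg)
    expr, ann, truth = simulate_expression(small_cfg, drinking)
    return {"drinking": drinking, "expr": expr, "ann": ann, "truth": truth}


@pytest.fixture(scope="session")
def planted_assignment(small_sim) -> pd.Series:
    pl = pd.Series(small_sim["truth"].module_of_gene)
    keep = pl[pl != "background"]
    return pd.Series(keep.to_numpy(), index=keep.index, name="module")


@pytest.fixture(scope="session")
def small_tom(small_sim):
    tom = topological_overlap(adjacency(small_sim["expr"], NetworkConfig(power=6)))
    return tom


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
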
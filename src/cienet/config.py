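"""YAML config loading for the pipeline."""

from __future__ import annotations

from pathlib import Path

import yaml

from .network import NetworkConfig
from .pipeline import PipelineConfig
from .simulate import SimConfig


def _tupleize(d: dict, keys: tuple[str, ...]) -> dict:
    for k in keys:
        if k in d and isinstance(d[k], list):
            d[k] = tuple(d[k])
    return d


def load_config(path: str | Path) -> PipelineConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    sim = None
    if "simulate" in raw:
        s = _tupleize(
            dict(raw.pop("simulate") or {}),
            ("module_sizes", "loading_range", "baseline_expression_range", "de_groups"),
        )
        if "trait_linked_modules" in s:
            s["trait_linked_modules"] = {int(k): float(v) for k, v in s["trait_linked_modules"].items()}
        if "disrupted_modules" in s:
            s["disrupted_modules"] = {
                int(k): (str(v[0]), float(v[1])) for k, v in s["disrupted_modules"].items()
            }
        sim = SimConfig(**s)
    net = NetworkConfig(**(raw.pop("network", None) or {}))
    if "disrupt_groups" in raw and isinstance(raw["disrupt_groups"], list):
        raw["disrupt_groups"] = tuple(raw["disrupt_groups"])
    return PipelineConfig(simulate=sim, network=net, **raw)
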
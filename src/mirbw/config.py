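"""Run configuration: every tunable of the pipeline in one round-trippable
YAML document with the standard defaults."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import yaml

from .dataset import WavenumberGrid
from .preprocess import HSO_INTERVALS
from .simulate import GeneratorConfig


@dataclass(frozen=True)
class PipelineConfig:
    """Tunables of the analysis chain, defaulting to the standard protocol:
    gap-5 first derivative, GH threshold 3 at 99% variance, 5% filter
    significance, tolerances 0..12, herd-validation share 10-30% over 101
    repeats, at most 10 PLS factors, 10 stratified folds."""

    apply_derivative: bool = True
    derivative_gap: int = 5
    hso_intervals: tuple = tuple((lo, hi) for lo, hi in HSO_INTERVALS)
    apply_cleaning: bool = True
    gh_var_explained: float = 0.99
    gh_threshold: float = 3.0
    residual_sd_threshold: float = 3.0
    sbf_alpha: float = 0.05
    tolerances: tuple = tuple(range(0, 13))
    fraction_range: tuple = (0.10, 0.30)
    n_repeats: int = 101
    max_components: int = 10
    k_folds: int = 10
    seed: int = 0


def _generator_to_dict(g: GeneratorConfig) -> dict:
    d = dataclasses.asdict(g)
    d["grid"] = {"start": g.grid.start, "end": g.grid.end, "n_points": g.grid.n_points}
    return d


def _generator_from_dict(d: dict) -> GeneratorConfig:
    d = dict(d)
    if "grid" in d and isinstance(d["grid"], dict):
        g = d["grid"]
        d["grid"] = WavenumberGrid(float(g["start"]), float(g["end"]), int(g["n_points"]))
    for key in ("cows_per_herd", "records_per_cow", "dim_range", "parity_probs",
                "parity_base", "my_parity_scale"):
        if key in d and d[key] is not None:
            d[key] = tuple(d[key])
    return GeneratorConfig(**d)


def save_config(
    path, pipeline: PipelineConfig | None = None, generator: GeneratorConfig | None = None
) -> None:
    doc: dict = {}
    if pipeline is not None:
        p = dataclasses.asdict(pipeline)
        p["hso_intervals"] = [list(iv) for iv in pipeline.hso_intervals]
        p["tolerances"] = list(pipeline.tolerances)
        p["fraction_range"] = list(pipeline.fraction_range)
        doc["pipeline"] = p
    if generator is not None:
        g = _generator_to_dict(generator)
        for key in ("cows_per_herd", "records_per_cow", "dim_range", "parity_probs",
                    "parity_base", "my_parity_scale"):
            g[key] = list(g[key])
        doc["generator"] = g
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)


def load_config(path) -> tuple[PipelineConfig, GeneratorConfig | None]:
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    p = doc.get("pipeline", {})
    if "hso_intervals" in p:
        p["hso_intervals"] = tuple(tuple(iv) for iv in p["hso_intervals"])
    if "tolerances" in p:
        p["tolerances"] = tuple(p["tolerances"])
    if "fraction_range" in p:
        p["fraction_range"] = tuple(p["fraction_range"])
    pipeline = PipelineConfig(**p)
    generator = None
    if "generator" in doc:
        generator = _generator_from_dict(doc["generator"])
    return pipeline, generator


def config_hash(pipeline: PipelineConfig, generator: GeneratorConfig | None = None) -> str:
    payload = {"pipeline": dataclasses.asdict(pipeline)}
    if generator is not None:
        payload["generator"] = _generator_to_dict(generator)
    text = json.dumps(payload, sort_keys=True, default=str)
    return hashlib.sha256(text.encode()).hexdigest()[:16]
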
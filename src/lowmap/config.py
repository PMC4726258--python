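"""Pipeline configuration: one YAML file covering every stage's parameters.

Layout (all sections optional; omitted keys keep their defaults)::

    seed: 1
    io:      {min_qual: 20, min_mq: 25, min_hom_depth: 8}
    maf:     {min_maf: 0.075, max_maf: 0.425}
    hmm:     {T: 1e-8, E_het: 0.01, E_hom: 0.01, C: 0.2, ...}
    merge:   {max_missing_per_type: 0.30, min_consensus: 0.50}
    filter:  {min_call_rate: 0.70, chi2_alpha: 0.03}
    linkage: {min_lod: 10, max_rf: 0.20}
    anchor:  {min_abs_pearson: 0.50, doublet_window_cM: 5.0}
    sim:     {n_chromosomes: 17, n_progeny: 163, coverage: 0.75, ...}

Unknown sections or keys are rejected.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml

from .hmm import HMMParams
from .mapping import AnchorParams, LinkageParams
from .merge_filter import FilterParams, MergeParams
from .pipeline import PipelineParams
from .simulate import SimConfig
from .testcross import MafWindow


@dataclass(frozen=True)
class IOParams:
    min_qual: float = 20.0
    min_mq: float = 25.0
    min_hom_depth: int = 8


@dataclass(frozen=True)
class PipelineConfig:
    seed: int = 0
    io: IOParams = IOParams()
    pipeline: PipelineParams = PipelineParams()
    sim: SimConfig = SimConfig()


class ConfigError(ValueError):
    pass


_SECTIONS = {
    "io": IOParams,
    "maf": MafWindow,
    "hmm": HMMParams,
    "merge": MergeParams,
    "filter": FilterParams,
    "linkage": LinkageParams,
    "anchor": AnchorParams,
    "sim": SimConfig,
}


def _build(cls, values: dict):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(values) - known
    if unknown:
        raise ConfigError(
            f"unknown keys for {cls.__name__}: {sorted(unknown)}")
    try:
        return cls(**values)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid {cls.__name__}: {exc}") from exc


def load_config(path: str | Path | None) -> PipelineConfig:
    """Parse a YAML config file into a :class:`PipelineConfig`."""
    if path is None:
        return PipelineConfig()
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        return PipelineConfig()
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    unknown = set(raw) - set(_SECTIONS) - {"seed"}
    if unknown:
        raise ConfigError(f"unknown config sections: {sorted(unknown)}")
    seed = raw.get("seed", 0)
    if not isinstance(seed, int):
        raise ConfigError("seed must be an integer")
    parts = {}
    for name, cls in _SECTIONS.items():
        section = raw.get(name, {})
        if not isinstance(section, dict):
            raise ConfigError(f"section {name!r} must be a mapping")
        parts[name] = _build(cls, section)
    sim = dataclasses.replace(parts["sim"], seed=raw.get(
        "sim", {}).get("seed", seed))
    pipeline = PipelineParams(
        maf=parts["maf"], hmm=parts["hmm"], merge=parts["merge"],
        filter=parts["filter"], linkage=parts["linkage"],
        anchor=parts["anchor"], min_hom_depth=parts["io"].min_hom_depth)
    return PipelineConfig(seed=seed, io=parts["io"], pipeline=pipeline,
                          sim=sim)


def config_to_dict(cfg: PipelineConfig) -> dict:
    """Round-trippable plain-dict form (logged verbatim by each stage)."""
    return {
        "seed": cfg.seed,
        "io": dataclasses.asdict(cfg.io),
        "maf": dataclasses.asdict(cfg.pipeline.maf),
        "hmm": dataclasses.asdict(cfg.pipeline.hmm),
        "merge": dataclasses.asdict(cfg.pipeline.merge),
        "filter": dataclasses.asdict(cfg.pipeline.filter),
        "linkage": dataclasses.asdict(cfg.pipeline.linkage),
        "anchor": dataclasses.asdict(cfg.pipeline.anchor),
        "sim": dataclasses.asdict(cfg.sim),
    }
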
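"""Pipeline configuration: one YAML-backed dataclass with per-stage blocks.

Unknown keys are rejected so typos fail fast; all effective defaults are
serialized into the run metadata of every pipeline run.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields

import yaml


class ConfigError(ValueError):
    pass


@dataclass
class CompetitionBlock:
    alpha: float = 0.9
    beta: float = 50.0
    death_fraction: float = 0.5
    start_ratio: float = 1.0
    n_cycles: int = 20
    ratios: list = field(default_factory=lambda: [1.0, 5.0, 25.0])


@dataclass
class GrowthBlock:
    window: list = field(default_factory=lambda: [75.0, 225.0])
    lag_span_min: float = 60.0


@dataclass
class SurvivalBlock:
    n_doses: int = 11
    one_sided_direction: str = "less"  # mutant scores lower than wild-type


@dataclass
class TracesBlock:
    channel: str = "GFP"
    pre_min_window: list = field(default_factory=lambda: [11, 13])
    post_max_window: list = field(default_factory=lambda: [13, 20])
    abundance_pre: list = field(default_factory=lambda: [1, 12])
    abundance_post: list = field(default_factory=lambda: [20, 36])
    demux_seed: int = 0


@dataclass
class ExpressionBlock:
    k: int = 10
    seed: int = 7
    alpha: float = 0.05
    min_timepoints: int = 2
    motifs: list = field(default_factory=lambda: ["CCCCT", "GATGAG"])
    enrichment_fdr: float = 0.02


@dataclass
class PipelineConfig:
    seed: int = 0
    out_dir: str = "esr_run"
    log_level: str = "INFO"
    competition: CompetitionBlock = field(default_factory=CompetitionBlock)
    growth: GrowthBlock = field(default_factory=GrowthBlock)
    survival: SurvivalBlock = field(default_factory=SurvivalBlock)
    traces: TracesBlock = field(default_factory=TracesBlock)
    expression: ExpressionBlock = field(default_factory=ExpressionBlock)

    _BLOCKS = {
        "competition": CompetitionBlock,
        "growth": GrowthBlock,
        "survival": SurvivalBlock,
        "traces": TracesBlock,
        "expression": ExpressionBlock,
    }

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data or {})
        kwargs = {}
        top = {f.name for f in fields(cls)}
        for key, val in data.items():
            if key not in top:
                raise ConfigError(f"unknown config key {key!r}")
            if key in cls._BLOCKS:
                block_cls = cls._BLOCKS[key]
                known = {f.name for f in fields(block_cls)}
                bad = set(val) - known
                if bad:
                    raise ConfigError(f"unknown key in {key!r} block: {sorted(bad)}")
                kwargs[key] = block_cls(**val)
            else:
                kwargs[key] = val
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_dict(self) -> dict:
        return asdict(self)
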
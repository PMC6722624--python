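"""Run configuration: one serializable object reproducing a whole analysis.

An archived RunConfig plus the input data reproduce every output bit-exactly;
each pipeline run writes a resolved copy of its configuration next to the
outputs for provenance.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .simulate import GeneratorConfig


@dataclass
class ModelConfig:
    k_pop: int = 10
    k_ind: int = 6
    degree: int = 3
    penalty_order: int = 2
    n_chains: int = 4
    n_iter: int = 2000
    n_warmup: int = 1000
    variance_prior_shape: float = 0.001
    variance_prior_rate: float = 0.001
    fixed_prior_variance: float = 1e6


@dataclass
class AnalysisConfig:
    grid_step_deg: float = 1.0
    credible_level: float = 0.95
    eps_torque: float = 1.0


@dataclass
class RunConfig:
    seed: int = 0
    input_csv: str | None = None      # user data; None -> synthetic
    outdir: str = "isogamm_out"
    target_velocity_dps: float = 60.0
    tolerance_dps: float = 6.0
    compare_models: bool = True       # also fit the intercept-only variant
    make_plots: bool = True
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        kwargs = dict(raw)
        kwargs["generator"] = GeneratorConfig(**kwargs.pop("generator", {}))
        kwargs["model"] = ModelConfig(**kwargs.pop("model", {}))
        kwargs["analysis"] = AnalysisConfig(**kwargs.pop("analysis", {}))
        return cls(**kwargs)

    def resolved_outdir(self) -> Path:
        out = Path(self.outdir)
        out.mkdir(parents=True, exist_ok=True)
        return out
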
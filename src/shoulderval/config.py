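"""Run configuration: every knob of the simulate -> preprocess -> extract
-> agree chain, serializable to a plain-text YAML file that round-trips
losslessly."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .synthetic import CohortSpec, SystemErrorModel

__all__ = ["RunConfig", "load_config", "save_config", "default_config"]


@dataclass
class RunConfig:
    cohort: CohortSpec = field(default_factory=CohortSpec)
    reference_error: SystemErrorModel = field(
        default_factory=SystemErrorModel.default_reference
    )
    wearable_error: SystemErrorModel = field(
        default_factory=SystemErrorModel.default_wearable
    )
    # preprocessing
    target_rate_hz: float = 200.0
    antialias: bool = True
    sync: bool = True
    baseline_window_s: float = 0.5
    # segmentation / outcomes
    onset_threshold: float = 0.05
    sustain_s: float = 0.1
    shared_segmentation: bool = True  # fragment once, on the reference
    mav_window_frac: float = 0.25
    icc_form: str = "consistency"
    # output
    out_dir: str = "results/run"
    write_trials: bool = True

    @property
    def seed(self) -> int:
        return self.cohort.seed

    def with_seed(self, seed: int) -> "RunConfig":
        cfg = from_dict(to_dict(self))
        cfg.cohort.seed = int(seed)
        return cfg

    def to_yaml(self) -> str:
        return yaml.safe_dump(to_dict(self), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        return from_dict(yaml.safe_load(text))


def to_dict(cfg: RunConfig) -> dict:
    return asdict(cfg)


def from_dict(d: dict) -> RunConfig:
    d = dict(d)
    cohort = CohortSpec(**d.pop("cohort", {}))
    ref = SystemErrorModel(**d.pop("reference_error", {}))
    wear = SystemErrorModel(**d.pop("wearable_error", {}))
    return RunConfig(
        cohort=cohort, reference_error=ref, wearable_error=wear, **d
    )


def default_config() -> RunConfig:
    return RunConfig()


def load_config(path) -> RunConfig:
    return RunConfig.from_yaml(Path(path).read_text())


def save_config(cfg: RunConfig, path) -> Path:
    path = Path(path)
    path.write_text(cfg.to_yaml())
    return path
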
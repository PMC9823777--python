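"""Run configuration: one YAML file wiring every stage together."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .dve import DVEConfig
from .evaluation import ClassifierSpec
from .predictor import PredictorConfig
from .synthetic import DEFAULT_CORRUPTION_RATE, SyntheticSpec
from .trainer import TrainerConfig

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """Everything a demo run needs; the seed propagates to every stage."""

    synthetic: SyntheticSpec = field(default_factory=SyntheticSpec)
    dve: DVEConfig = field(default_factory=DVEConfig)
    predictor: PredictorConfig | None = None
    trainer: TrainerConfig = field(default_factory=TrainerConfig)
    classifier: ClassifierSpec = field(default_factory=ClassifierSpec)
    corruption_rate: float = DEFAULT_CORRUPTION_RATE
    out_dir: str = "tsdval_out"
    seed: int = 0

    def validate(self) -> None:
        self.synthetic.validate()
        self.dve.validate()
        if self.predictor is not None:
            self.predictor.validate()
        self.trainer.validate()
        self.classifier.validate()
        if not 0.0 <= self.corruption_rate <= 1.0:
            raise ValueError("corruption_rate must be in [0, 1]")

    def with_seed(self, seed: int) -> "RunConfig":
        cfg = RunConfig(**{**asdict_shallow(self)})
        cfg.seed = seed
        cfg.synthetic = SyntheticSpec(**{**asdict(self.synthetic), "seed": seed})
        cfg.trainer = TrainerConfig(**{**asdict(self.trainer), "seed": seed})
        return cfg

    # -- YAML round-trip ------------------------------------------------------
    def to_yaml(self, path) -> None:
        payload = {
            "synthetic": asdict(self.synthetic),
            "dve": asdict(self.dve),
            "predictor": None if self.predictor is None else asdict(self.predictor),
            "trainer": asdict(self.trainer),
            "classifier": asdict(self.classifier),
            "corruption_rate": self.corruption_rate,
            "out_dir": self.out_dir,
            "seed": self.seed,
        }
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(
            synthetic=SyntheticSpec(**payload.get("synthetic", {})),
            dve=DVEConfig(**payload.get("dve", {})),
            trainer=TrainerConfig(**_as_trainer(payload.get("trainer", {}))),
            classifier=ClassifierSpec(**_fix_tuple(payload.get("classifier", {}))),
            corruption_rate=payload.get("corruption_rate",
                                        DEFAULT_CORRUPTION_RATE),
            out_dir=payload.get("out_dir", "tsdval_out"),
            seed=payload.get("seed", 0),
        )
        pred = payload.get("predictor")
        if pred is not None:
            pred = dict(pred)
            if "head_kernels" in pred:
                pred["head_kernels"] = tuple(pred["head_kernels"])
            cfg.predictor = PredictorConfig(**pred)
        cfg.validate()
        return cfg


def asdict_shallow(cfg: RunConfig) -> dict:
    return {f: getattr(cfg, f) for f in cfg.__dataclass_fields__}


def _as_trainer(d: dict) -> dict:
    d = dict(d)
    if "explore_band" in d:
        d["explore_band"] = tuple(d["explore_band"])
    return d


def _fix_tuple(d: dict) -> dict:
    return dict(d)
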
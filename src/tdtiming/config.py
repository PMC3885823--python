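"""Experiment configuration: YAML/JSON loading, validation, defaults.

A configuration file selects one of the five packaged experiments and may
override any of the nested parameter groups; unknown keys are rejected so
typos fail loudly.  An empty file is a valid configuration for the
dopamine interval-sweep experiment with all defaults (alpha=0.01,
gamma=0.98, lambda=0.95, D=50, sigma=0.08, 20 steps/s, 500-step ITI,
100 trials).
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional

import yaml

from .actor import ActorConfig
from .basis import BasisConfig, GainProfile
from .semimarkov import RectifiedPEConfig
from .tasks import TaskSpec
from .td import LearnerConfig

__all__ = ["ExperimentConfig", "load_config", "save_config", "config_hash"]

EXPERIMENTS = ("pavlovian", "sweep", "peak", "bisection", "rectified")


@dataclass(frozen=True)
class ExperimentConfig:
    """Validated bundle of everything one experiment run needs."""

    experiment: str = "sweep"
    basis: BasisConfig = field(default_factory=BasisConfig)
    learner: LearnerConfig = field(default_factory=LearnerConfig)
    actor: Optional[ActorConfig] = None
    task: TaskSpec = field(default_factory=TaskSpec)
    semi_markov: Optional[RectifiedPEConfig] = None
    gains: Dict[str, GainProfile] = field(default_factory=dict)
    seed: int = 0
    output_dir: str = "tdtiming-output"

    def __post_init__(self) -> None:
        if self.experiment not in EXPERIMENTS:
            raise ValueError(
                f"unknown experiment {self.experiment!r}; choose from {EXPERIMENTS}"
            )

    def to_dict(self) -> dict:
        def enc(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, dict):
                return {k: enc(v) for k, v in obj.items()}
            if isinstance(obj, tuple):
                return list(obj)
            return obj

        return {
            "experiment": self.experiment,
            "basis": enc(self.basis),
            "learner": enc(self.learner),
            "actor": enc(self.actor) if self.actor else None,
            "task": enc(self.task),
            "semi_markov": enc(self.semi_markov) if self.semi_markov else None,
            "gains": {k: enc(v) for k, v in self.gains.items()},
            "seed": self.seed,
            "output_dir": self.output_dir,
        }


def _build(cls, data: Optional[dict], where: str):
    if data is None:
        return None
    if not isinstance(data, dict):
        raise ValueError(f"{where}: expected a mapping, got {type(data).__name__}")
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - fields
    if unknown:
        raise ValueError(f"{where}: unknown key(s) {sorted(unknown)}")
    kwargs = dict(data)
    if cls is ActorConfig and "actions" in kwargs:
        kwargs["actions"] = tuple(kwargs["actions"])
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{where}: {exc}") from exc


def config_from_mapping(data: Optional[dict]) -> ExperimentConfig:
    """Build a validated :class:`ExperimentConfig` from a plain mapping."""
    data = dict(data or {})
    top_keys = {
        "experiment", "basis", "learner", "actor", "task",
        "semi_markov", "gains", "seed", "output_dir",
    }
    unknown = set(data) - top_keys
    if unknown:
        raise ValueError(f"unknown top-level key(s) {sorted(unknown)}")
    gains_raw = data.get("gains") or {}
    gains = {
        stim: _build(GainProfile, g, f"gains.{stim}") for stim, g in gains_raw.items()
    }
    cfg = ExperimentConfig(
        experiment=data.get("experiment", "sweep"),
        basis=_build(BasisConfig, data.get("basis"), "basis") or BasisConfig(),
        learner=_build(LearnerConfig, data.get("learner"), "learner")
        or LearnerConfig(),
        actor=_build(ActorConfig, data.get("actor"), "actor"),
        task=_build(TaskSpec, data.get("task"), "task") or TaskSpec(),
        semi_markov=_build(RectifiedPEConfig, data.get("semi_markov"), "semi_markov"),
        gains=gains,
        seed=int(data.get("seed", 0)),
        output_dir=str(data.get("output_dir", "tdtiming-output")),
    )
    if cfg.experiment == "rectified" and cfg.semi_markov is None:
        cfg = dataclasses.replace(cfg, semi_markov=RectifiedPEConfig())
    if cfg.experiment == "bisection" and cfg.actor is None:
        cfg = dataclasses.replace(
            cfg, actor=ActorConfig(actions=("short", "long", "withhold"))
        )
    return cfg


def load_config(path) -> ExperimentConfig:
    """Load and validate a YAML or JSON experiment configuration file."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        data = json.loads(text) if text.strip() else {}
    else:
        data = yaml.safe_load(text)
    if data is not None and not isinstance(data, dict):
        raise ValueError(f"{path}: configuration must be a mapping")
    return config_from_mapping(data)


def save_config(cfg: ExperimentConfig, path) -> None:
    """Serialize a configuration; load_config(save_config(c)) == c."""
    path = Path(path)
    payload = cfg.to_dict()
    # drop Nones so round-trips re-apply the same defaults
    payload = {k: v for k, v in payload.items() if v is not None}
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(payload, indent=2))
    else:
        path.write_text(yaml.safe_dump(payload, sort_keys=False))


def config_hash(cfg: ExperimentConfig) -> str:
    """Short stable hash identifying a configuration (for output manifests)."""
    blob = json.dumps(cfg.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
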
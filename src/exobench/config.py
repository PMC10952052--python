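"""Study configuration: conditions, tasks, generator and analysis settings."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import exo as exo_mod
from .synthetic import EmgGenModel, Task, TaskSpec

__all__ = ["StudyConfig", "DEFAULT_CONDITIONS", "NO_EXO"]

NO_EXO = "no_exo"
#: the four synthetic device parameterizations shipped with the package plus
#: the no-device control condition
DEFAULT_CONDITIONS = [NO_EXO, "laevo_like", "paexo_like",
                      "auxivo_like", "darwing_like"]

_DEFAULT_BORG = {NO_EXO: 12.0, "laevo_like": 10.0, "paexo_like": 11.0,
                 "auxivo_like": 12.5, "darwing_like": 11.0}
_DEFAULT_VAS = {
    NO_EXO: {"default": 0.3},
    "laevo_like": {"default": 1.0, "chest": 0.8},
    "paexo_like": {"default": 2.0, "legs": 3.5},
    "auxivo_like": {"default": 2.5, "legs": 3.8, "groin": 3.5},
    "darwing_like": {"default": 0.8},
}


@dataclass
class StudyConfig:
    """Everything needed to generate and analyze one synthetic study."""

    n_subjects: int = 10
    conditions: list[str] = field(default_factory=lambda: list(DEFAULT_CONDITIONS))
    tasks: list[str] = field(default_factory=lambda: [t.value for t in Task])
    master_seed: int = 42
    marker_noise_std: float = 0.0005  # m, per axis
    n_repetitions: int = 2  # lift cycles per Dynamic trial (one metronome set)
    emg_model: EmgGenModel = field(default_factory=EmgGenModel)
    #: device parameter files; names missing here resolve to packaged models
    exo_model_files: dict[str, str] = field(default_factory=dict)
    #: rigid devices whose hip hinge does not allow squatting
    squat_excluded: set[str] = field(default_factory=lambda: {"paexo_like"})
    borg_mean: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_BORG))
    borg_sd: float = 1.5
    vas_mean: dict[str, dict] = field(default_factory=lambda: {
        k: dict(v) for k, v in _DEFAULT_VAS.items()})
    vas_sd: float = 0.8
    vas_regions: list[str] = field(default_factory=lambda: [
        "shoulders", "chest", "lower_back", "legs", "groin"])
    # analysis settings
    segmentation_dead_band: float = 2.0  # deg/s
    segmentation_min_duration: float = 0.25  # s
    movement_threshold: float = 5.0  # deg/s, gates iEMG
    filter_order: int = 2  # per-pass Butterworth order (net 4th with filtfilt)
    notch_50hz: bool = False
    alpha: float = 0.05

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("need at least one subject")
        for t in self.tasks:
            Task(t)
        for cond, path in self.exo_model_files.items():
            if not Path(path).exists():
                raise FileNotFoundError(
                    f"exo model file for condition {cond!r} not found: {path}")
        for thr in (self.segmentation_dead_band, self.movement_threshold,
                    self.segmentation_min_duration):
            if thr < 0:
                raise ValueError("thresholds must be non-negative")
        for cond in self.conditions:
            if cond != NO_EXO:
                self.exo_model(cond)  # raises if unresolvable

    def exo_model(self, condition: str) -> exo_mod.ExoModel | None:
        if condition == NO_EXO:
            return None
        if condition in self.exo_model_files:
            return exo_mod.load_exo_model(self.exo_model_files[condition])
        return exo_mod.builtin_device(condition)

    def task_spec(self, task: Task) -> TaskSpec:
        return TaskSpec(task=task, n_repetitions=self.n_repetitions)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["squat_excluded"] = sorted(d["squat_excluded"])
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]

    @classmethod
    def from_dict(cls, data: dict) -> "StudyConfig":
        data = dict(data)
        if "emg_model" in data and isinstance(data["emg_model"], dict):
            data["emg_model"] = EmgGenModel(**data["emg_model"])
        if "squat_excluded" in data:
            data["squat_excluded"] = set(data["squat_excluded"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)
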
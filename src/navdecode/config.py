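"""Study configuration: one YAML document drives the whole synthetic study.

Every randomized stage draws its seed deterministically from the master
seed through a counter scheme (see ``stage_seed``), so a study re-run from
the same config is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
from pathlib import Path

import numpy as np
import yaml

#: stable stage codes for seed derivation; never reorder, only append
STAGE_CODES = {
    "trajectory": 0,
    "bold": 1,
    "decode": 2,
    "permutation": 3,
    "feedback": 4,
    "objects": 5,
    "chance": 6,
    "voxels": 7,
}


def stage_seed(master_seed: int, subject_index: int, stage: str, session_index: int = 0) -> int:
    """Derive a stage seed: master + (subject, session, stage) counter key.

    Uses numpy's SeedSequence spawn keys, so distinct (subject, session,
    stage) triples give statistically independent streams; the returned
    integer is < 2^31.
    """
    seq = np.random.SeedSequence(
        master_seed, spawn_key=(subject_index, session_index, STAGE_CODES[stage])
    )
    return int(seq.generate_state(1)[0] % (2**31))


@dataclasses.dataclass
class ArenaConfig:
    radius_vm: float = 25.0
    unreal_units_per_vm: float = 62.5


@dataclasses.dataclass
class TaskConfig:
    n_repetitions: int = 6
    memory_noise_sd: float = 6.0
    noise_decay: float = 0.75
    omission_prob: float = 0.05
    exclusion_missing_fraction: float = 1.0 / 3.0  # drop subjects missing more


@dataclasses.dataclass
class TrajectoryConfig:
    duration_s: float = 1041.6  # 17.36 min of free navigation
    dt_s: float = 0.1
    mean_speed: float = 2.0  # vm/s
    turn_volatility: float = 40.0  # deg / sqrt(s)


@dataclasses.dataclass
class BoldConfig:
    tr_s: float = 2.36
    lag_trs: int = 2
    n_voxels: int = 200
    tuning_sd: float = 30.0  # degrees
    gain: float = 1.5
    baseline: float = 100.0
    noise_sd: float = 4.0
    fraction_tuned: float = 0.5
    drift_amplitude: float = 2.0


@dataclasses.dataclass
class EventConfig:
    n_bins: int = 6
    min_duration_s: float = 1.0
    min_speed: float = 0.05


@dataclasses.dataclass
class DecodeConfig:
    k_folds: int = 3
    min_per_class: int = 3
    C: float = 1.0
    tol: float = 1e-4
    max_iter: int = 1000


@dataclasses.dataclass
class PermutationConfig:
    n_iterations: int = 0  # 0 disables per-subject permutation nulls


@dataclasses.dataclass
class StudyConfig:
    """Complete description of one synthetic study.

    ``conditions`` maps condition name -> BOLD overrides (typically the
    gain: the within-subject L-DOPA analogue); ``groups`` maps group
    name -> BOLD overrides (typically tuning_sd: the between-subject age
    analogue). Each subject completes one session per condition.
    """

    seed: int = 1234
    n_subjects: int = 10  # per group
    arena: ArenaConfig = dataclasses.field(default_factory=ArenaConfig)
    task: TaskConfig = dataclasses.field(default_factory=TaskConfig)
    trajectory: TrajectoryConfig = dataclasses.field(default_factory=TrajectoryConfig)
    bold: BoldConfig = dataclasses.field(default_factory=BoldConfig)
    events: EventConfig = dataclasses.field(default_factory=EventConfig)
    decode: DecodeConfig = dataclasses.field(default_factory=DecodeConfig)
    permutation: PermutationConfig = dataclasses.field(default_factory=PermutationConfig)
    conditions: dict = dataclasses.field(
        default_factory=lambda: {"placebo": {"gain": 1.5}, "levodopa": {"gain": 2.5}}
    )
    groups: dict = dataclasses.field(
        default_factory=lambda: {"younger": {"tuning_sd": 30.0}, "older": {"tuning_sd": 60.0}}
    )
    roi: str = "simulated_roi"

    def bold_for(self, group: str, condition: str) -> BoldConfig:
        """BOLD parameters for one cell: base values + group/condition overrides."""
        params = dataclasses.asdict(self.bold)
        params.update(self.groups.get(group, {}))
        params.update(self.conditions.get(condition, {}))
        return BoldConfig(**params)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        d = dict(d)
        for key, sub in [
            ("arena", ArenaConfig), ("task", TaskConfig),
            ("trajectory", TrajectoryConfig), ("bold", BoldConfig),
            ("events", EventConfig), ("decode", DecodeConfig),
            ("permutation", PermutationConfig),
        ]:
            if key in d and isinstance(d[key], dict):
                d[key] = sub(**d[key])
        return cls(**d)

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, path_or_text) -> "StudyConfig":
        p = Path(str(path_or_text))
        text = p.read_text() if p.exists() else str(path_or_text)
        return cls.from_dict(yaml.safe_load(text))

    def content_hash(self) -> str:
        """sha256 of the canonical YAML serialization (manifest key)."""
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()
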
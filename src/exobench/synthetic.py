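"""Seeded synthetic study generator: lifting kinematics, EMG, and scores.

Emulates the measurement campaign the pipeline is built for: optical markers
at 128 Hz on the trunk (C7, T10, clavicle, both acromions, anterior/posterior
sacroiliac) plus device-specific exo markers, and 12-channel surface EMG at
2048 Hz from six bilateral trunk muscles, for four lifting tasks (Static
holds at 40°/60°, Asymmetric, Squat, Stoop) under five device conditions.

The trunk is a single rigid segment pivoting at the sacrum point; trunk
inclination θ follows a raised-cosine (C¹) flexion-extension profile paced at
the metronome rate (30 bpm, one beat per phase) for Dynamic tasks, or a
ramp-and-hold for Static tasks.  Squat replaces trunk flexion with vertical
pelvis translation (plus a small residual inclination); Asymmetric adds a yaw
sinusoid.  EMG channels are amplitude-modulated band-limited Gaussian noise:
the activation is a baseline plus a gain times the exo-compensated
gravitational trunk moment, normalized to its value at 90° with the load —
a statistical stand-in for the muscle response the analysis assumes, not a
physiological model.

Every generated trial carries a ground-truth sidecar (true θ, band
elongation, exo moment, phase labels), so each downstream stage can be tested
without access to any real capture data.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import butter, filtfilt
from scipy.spatial.transform import Rotation

from . import exo as exo_mod
from .emg import EmgRecording
from .kinematics import Phase, segmentation_from_labels
from .markers import MarkerFrameSeries, write_markers_tsv

__all__ = [
    "GRAVITY",
    "Task",
    "DYNAMIC_TASKS",
    "SubjectAnthropometry",
    "TaskSpec",
    "EmgGenModel",
    "GroundTruth",
    "MUSCLES",
    "EMG_CHANNELS",
    "ERECTOR_SPINAE",
    "gravitational_moment",
    "generate_lift_kinematics",
    "generate_emg",
    "generate_mvc_trials",
    "generate_study",
]

GRAVITY = 9.81  # m/s^2

MUSCLES = ["Abd", "IntObq", "ExtObq", "LongLumb", "LongThor", "Ilioc"]
EMG_CHANNELS = [f"{m}_{s}" for m in MUSCLES for s in ("L", "R")]
#: back-extensor channels targeted by back-support exos
ERECTOR_SPINAE = [f"{m}_{s}" for m in ("LongLumb", "LongThor", "Ilioc")
                  for s in ("L", "R")]
#: relative moment-responsiveness per muscle group (back extensors carry the
#: gravitational moment; abdominals stay near baseline during lifting)
CHANNEL_GAIN = {"Abd": 0.1, "IntObq": 0.3, "ExtObq": 0.3,
                "LongLumb": 1.0, "LongThor": 0.9, "Ilioc": 1.0}


class Task(str, Enum):
    STATIC40 = "Static40"
    STATIC60 = "Static60"
    ASYMMETRIC = "Asymmetric"
    SQUAT = "Squat"
    STOOP = "Stoop"


DYNAMIC_TASKS = (Task.ASYMMETRIC, Task.SQUAT, Task.STOOP)

_DEFAULT_PEAK = {Task.STATIC40: 40.0, Task.STATIC60: 60.0,
                 Task.ASYMMETRIC: 70.0, Task.SQUAT: 15.0, Task.STOOP: 85.0}


@dataclass
class SubjectAnthropometry:
    """Segment parameters of the single-segment trunk model.

    ``trunk_length`` is sacrum-to-acromion (m); ``trunk_mass`` the mass of the
    trunk segment (kg) acting at ``trunk_com_fraction`` of the trunk length;
    ``load_mass`` the handled gear (kg, default 12.6) acting at ``load_lever``
    (m) from the sacrum along the horizontal.
    """

    trunk_length: float = 0.50
    shoulder_width: float = 0.38
    trunk_mass: float = 32.0
    load_mass: float = 12.6
    trunk_com_fraction: float = 0.5
    load_lever: float = 0.30

    def __post_init__(self) -> None:
        for name in ("trunk_length", "shoulder_width", "trunk_mass",
                     "load_mass", "load_lever"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if not 0.0 < self.trunk_com_fraction < 1.0:
            raise ValueError("trunk_com_fraction must lie in (0, 1)")


@dataclass
class TaskSpec:
    """One task execution recipe (angles, pacing, repetitions)."""

    task: Task
    peak_inclination: float | None = None
    hold_duration: float = 5.0
    cycle_rate: float = 30.0  # metronome beats/min; one beat per lift phase
    n_repetitions: int = 2
    out_of_plane_amplitude: float | None = None
    squat_depth: float = 0.25  # vertical pelvis excursion, m

    def __post_init__(self) -> None:
        self.task = Task(self.task)
        if self.peak_inclination is None:
            self.peak_inclination = _DEFAULT_PEAK[self.task]
        if self.task in (Task.STATIC40, Task.STATIC60):
            self.peak_inclination = _DEFAULT_PEAK[self.task]
        if self.task == Task.SQUAT and self.peak_inclination > 20.0:
            raise ValueError("Squat keeps trunk inclination <= 20 deg")
        if self.task == Task.STOOP and self.peak_inclination < 60.0:
            raise ValueError("Stoop requires peak inclination >= 60 deg")
        if self.out_of_plane_amplitude is None:
            self.out_of_plane_amplitude = 30.0 if self.task == Task.ASYMMETRIC else 0.0
        if self.task == Task.ASYMMETRIC and self.out_of_plane_amplitude == 0:
            raise ValueError("Asymmetric requires nonzero out-of-plane amplitude")
        if self.task != Task.ASYMMETRIC and self.out_of_plane_amplitude != 0:
            raise ValueError("only Asymmetric has out-of-plane motion")
        if self.cycle_rate <= 0 or self.n_repetitions < 1 or self.hold_duration <= 0:
            raise ValueError("invalid pacing parameters")

    @property
    def is_static(self) -> bool:
        return self.task in (Task.STATIC40, Task.STATIC60)


@dataclass
class EmgGenModel:
    """Parameters of the amplitude-modulated EMG generator.

    ``assist_share`` s ∈ [0, 1] is the fraction of the exo moment credited
    with unloading the back muscles: activation
    a(t) = baseline + gain · max(0, M_grav − s·M_exo)/M_ref with M_ref the
    gravitational moment at 90° inclination with the load.
    """

    baseline_activation: float = 0.02
    gain: float = 0.6
    assist_share: float = 1.0
    noise_band: tuple[float, float] = (30.0, 300.0)
    mvc_scale_volts: float = 1.0e-3
    seed: int = 0
    line_noise_50hz: float = 0.0  # optional mains component, fraction of MVC scale

    def __post_init__(self) -> None:
        if not 0.0 <= self.assist_share <= 1.0:
            raise ValueError("assist_share must lie in [0, 1]")
        if self.baseline_activation + self.gain > 1.0 + 1e-12:
            raise ValueError("baseline_activation + gain must not exceed 1 at peak load")
        if self.baseline_activation < 0 or self.gain < 0 or self.mvc_scale_volts <= 0:
            raise ValueError("invalid EMG generator parameters")


@dataclass
class GroundTruth:
    """Per-trial generator ground truth at the marker rate."""

    time: np.ndarray
    rate: float
    true_theta: np.ndarray  # deg
    phase_labels: np.ndarray  # 'flexion' | 'extension' | 'hold' per frame
    true_exo_moment: np.ndarray  # Nm; zeros for the no-exo condition
    true_elongation: np.ndarray | None = None  # mm, soft devices only
    true_assist_share: float = 1.0

    def to_json(self) -> str:
        payload = {
            "rate": self.rate,
            "time": np.round(self.time, 6).tolist(),
            "true_theta": np.round(self.true_theta, 6).tolist(),
            "phase_labels": self.phase_labels.tolist(),
            "true_exo_moment": np.round(self.true_exo_moment, 6).tolist(),
            "true_elongation": (None if self.true_elongation is None
                                 else np.round(self.true_elongation, 6).tolist()),
            "true_assist_share": self.true_assist_share,
        }
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        d = json.loads(text)
        return cls(
            time=np.asarray(d["time"]), rate=d["rate"],
            true_theta=np.asarray(d["true_theta"]),
            phase_labels=np.asarray(d["phase_labels"], dtype=object),
            true_exo_moment=np.asarray(d["true_exo_moment"]),
            true_elongation=(None if d["true_elongation"] is None
                             else np.asarray(d["true_elongation"])),
            true_assist_share=d["true_assist_share"],
        )


def gravitational_moment(anthro: SubjectAnthropometry,
                         theta_deg: np.ndarray) -> np.ndarray:
    """Gravitational trunk+load moment about the sacrum (Nm) at inclination θ."""
    lever = (anthro.trunk_mass * GRAVITY * anthro.trunk_com_fraction
             * anthro.trunk_length
             + anthro.load_mass * GRAVITY * anthro.load_lever)
    return lever * np.sin(np.radians(theta_deg))


# ---------------------------------------------------------------------------
# kinematics
# ---------------------------------------------------------------------------

def _raised_cosine(n: int) -> np.ndarray:
    """Smooth 0→1 profile over n samples (half raised cosine)."""
    return 0.5 * (1.0 - np.cos(np.linspace(0.0, np.pi, n)))


def _profile(task: TaskSpec, rate: float) -> np.ndarray:
    """Normalized excursion profile s(t) ∈ [0, 1] for a trial."""
    lead = np.zeros(int(round(0.25 * rate)))
    if task.is_static:
        ramp = _raised_cosine(int(round(1.0 * rate)))
        hold = np.ones(int(round(task.hold_duration * rate)))
        parts = [lead, ramp, hold, ramp[::-1], lead]
    else:
        half = int(round(60.0 / task.cycle_rate * rate))  # one beat per phase
        up, down = _raised_cosine(half), _raised_cosine(half)[::-1]
        parts = [lead] + [up, down] * task.n_repetitions + [lead]
    return np.concatenate(parts)


_PELVIS_Z0 = 1.00  # standing height of the sacrum point, m
_BAND_T_LOCAL = (-0.05, 0.08, 0.30)  # trunk-fixed, absolute meters
_BAND_M_LOCAL = (-0.05, 0.08, 0.02)  # pelvis-fixed, absolute meters
_EXO_HIP_LOCAL = (0.05, 0.0, -0.05)  # pelvis-fixed
_EXO_THIGH_LAB = (0.05, 0.0, _PELVIS_Z0 - 0.40)  # lab-fixed (leg stationary)


def _marker_layout(anthro: SubjectAnthropometry,
                   exo: exo_mod.ExoModel | None):
    """(label, frame, local offset) table for the requested marker set."""
    L = anthro.trunk_length
    half_w = anthro.shoulder_width / 2.0
    table = [
        ("C7", "trunk", np.array([-0.04, 0.0, 0.97 * L])),
        ("T10", "trunk", np.array([-0.05, 0.0, 0.60 * L])),
        ("CLAV", "trunk", np.array([0.05, 0.0, 0.88 * L])),
        ("LACR", "trunk", np.array([0.0, half_w, L])),
        ("RACR", "trunk", np.array([0.0, -half_w, L])),
        ("LPSI", "pelvis", np.array([0.0, 0.06, 0.0])),
        ("RPSI", "pelvis", np.array([0.0, -0.06, 0.0])),
        ("LASI", "pelvis", np.array([0.12, 0.06, 0.0])),
        ("RASI", "pelvis", np.array([0.12, -0.06, 0.0])),
    ]
    if isinstance(exo, exo_mod.RigidExoModel):
        table += [
            ("EXO_HIP", "pelvis", np.array(_EXO_HIP_LOCAL)),
            ("EXO_THIGH", "lab", np.array(_EXO_THIGH_LAB)),
        ]
    elif isinstance(exo, exo_mod.SoftExoModel):
        for t_label, m_label in exo.band_marker_labels:
            sign = 1.0 if t_label.startswith("L") else -1.0
            t_loc = np.array(_BAND_T_LOCAL) * np.array([1.0, sign, 1.0])
            m_loc = np.array(_BAND_M_LOCAL) * np.array([1.0, sign, 1.0])
            table += [(t_label, "trunk", t_loc), (m_label, "pelvis", m_loc)]
    elif exo is not None:
        raise TypeError(f"unknown exo model type {type(exo)!r}")
    return table


def _phase_labels(theta: np.ndarray, time: np.ndarray,
                  dead_band: float = 5.0) -> np.ndarray:
    # dead band matches the default movement-mask threshold so the labeled
    # moving portion is consistent with the analysis gate
    vel = np.gradient(theta, time)
    labels = np.full(len(theta), Phase.HOLD.value, dtype=object)
    labels[vel > dead_band] = Phase.FLEXION.value
    labels[vel < -dead_band] = Phase.EXTENSION.value
    return labels


def generate_lift_kinematics(anthro: SubjectAnthropometry, task: TaskSpec,
                             exo: exo_mod.ExoModel | None = None,
                             seed: int = 0,
                             marker_noise_std: float = 0.0005,
                             rate: float = 128.0,
                             ) -> tuple[MarkerFrameSeries, GroundTruth]:
    """Generate one trial's marker trajectories and its ground truth.

    Returns markers in a Z-up metric lab frame at ``rate`` Hz with additive
    i.i.d. Gaussian noise (σ = ``marker_noise_std`` m per axis; 0 disables),
    and the :class:`GroundTruth` including the exo moment evaluated from the
    supplied device model along the noise-free trajectory.
    """
    profile = _profile(task, rate)
    n = len(profile)
    time = np.arange(n) / rate
    theta = task.peak_inclination * profile
    yaw = task.out_of_plane_amplitude * profile
    drop = task.squat_depth * profile if task.task == Task.SQUAT else np.zeros(n)

    pelvis_origin = np.column_stack(
        [np.zeros(n), np.zeros(n), _PELVIS_Z0 - drop])
    rot = Rotation.from_euler(
        "zy", np.column_stack([yaw, theta]), degrees=True)

    layout = _marker_layout(anthro, exo)
    labels = [lab for lab, _, _ in layout]
    positions = np.empty((n, len(layout), 3))
    for i, (_, frame, local) in enumerate(layout):
        if frame == "trunk":
            positions[:, i, :] = pelvis_origin + rot.apply(local)
        elif frame == "pelvis":
            positions[:, i, :] = pelvis_origin + local
        else:  # lab-fixed
            positions[:, i, :] = local

    clean = MarkerFrameSeries(labels=labels, positions=positions.copy(),
                              rate=rate, time=time)
    phase = _phase_labels(theta, time)
    seg = segmentation_from_labels(phase, rate)

    elongation = None
    moment = np.zeros(n)
    if isinstance(exo, exo_mod.SoftExoModel):
        elongation = exo_mod.band_elongation(clean, exo)
        moment = exo_mod.soft_assistive_moment(clean, seg, exo)
    elif isinstance(exo, exo_mod.RigidExoModel):
        moment, _ = exo_mod.rigid_assistive_moment(clean, seg, exo)

    if marker_noise_std > 0:
        rng = np.random.default_rng(seed)
        positions = positions + rng.normal(0.0, marker_noise_std,
                                           positions.shape)
    series = MarkerFrameSeries(labels=labels, positions=positions, rate=rate,
                               time=time)
    gt = GroundTruth(time=time, rate=rate, true_theta=theta,
                     phase_labels=phase, true_exo_moment=moment,
                     true_elongation=elongation)
    return series, gt


# ---------------------------------------------------------------------------
# EMG
# ---------------------------------------------------------------------------

def _band_limited_carrier(rng: np.random.Generator, n: int, rate: float,
                          band: tuple[float, float]) -> np.ndarray:
    """Unit-variance Gaussian noise band-limited to ``band`` Hz."""
    white = rng.standard_normal(n)
    b, a = butter(2, np.asarray(band) / (rate / 2.0), btype="bandpass")
    x = filtfilt(b, a, white)
    return x / x.std()


def _activation_to_recording(activation: dict[str, np.ndarray], rate: float,
                             model: EmgGenModel, rng: np.random.Generator,
                             meta: dict | None = None) -> EmgRecording:
    n = len(next(iter(activation.values())))
    time = np.arange(n) / rate
    signal = np.empty((n, len(EMG_CHANNELS)))
    for k, ch in enumerate(EMG_CHANNELS):
        carrier = _band_limited_carrier(rng, n, rate, model.noise_band)
        signal[:, k] = activation[ch] * carrier * model.mvc_scale_volts
        if model.line_noise_50hz > 0:
            signal[:, k] += (model.line_noise_50hz * model.mvc_scale_volts
                             * np.sin(2 * np.pi * 50.0 * time))
    return EmgRecording(channels=list(EMG_CHANNELS), signal=signal, rate=rate,
                        time=time, meta=meta or {})


def generate_emg(ground_truth: GroundTruth, anthro: SubjectAnthropometry,
                 model: EmgGenModel, duration: float | None = None,
                 rate: float = 2048.0) -> EmgRecording:
    """Load-modulated surface EMG for one trial.

    Channel amplitude is a(t)·carrier(t)·mvc_scale with
    a(t) = baseline + g_ch·gain·max(0, M_grav(t) − s·M_exo(t))/M_ref; the
    carrier is unit-variance Gaussian noise band-limited to the analysis
    band, drawn independently per channel.
    """
    if duration is None:
        duration = float(ground_truth.time[-1])
    if duration > ground_truth.time[-1] + 1e-9:
        raise ValueError("ground truth does not cover the requested duration")
    n = int(round(duration * rate))
    time = np.arange(n) / rate
    theta = np.interp(time, ground_truth.time, ground_truth.true_theta)
    m_exo = np.interp(time, ground_truth.time, ground_truth.true_exo_moment)
    m_grav = gravitational_moment(anthro, theta)
    m_ref = float(gravitational_moment(anthro, np.array(90.0)))
    drive = np.maximum(0.0, m_grav - model.assist_share * m_exo) / m_ref
    rng = np.random.default_rng(model.seed)
    activation = {}
    for ch in EMG_CHANNELS:
        g = CHANNEL_GAIN[ch.rsplit("_", 1)[0]]
        activation[ch] = model.baseline_activation + g * model.gain * drive
    return _activation_to_recording(
        activation, rate, model, rng,
        meta={"assist_share": model.assist_share, "seed": model.seed})


def generate_mvc_trials(model: EmgGenModel, n_trials: int = 2,
                        rate: float = 2048.0,
                        plateau_duration: float = 2.5) -> list[EmgRecording]:
    """Maximum-voluntary-contraction calibration recordings.

    For each muscle group, ``n_trials`` recordings in which both sides of the
    target muscle ramp to a plateau at full activation (1.0 = MVC) held for
    at least 2 s while the other channels stay at baseline.  The recording's
    ``meta['target_muscle']`` names the group.
    """
    if plateau_duration < 2.0:
        raise ValueError("MVC plateau must be held for at least 2 s")
    rng = np.random.default_rng(model.seed)
    ramp = _raised_cosine(int(round(0.5 * rate)))
    plateau = np.ones(int(round(plateau_duration * rate)))
    prof = np.concatenate([ramp, plateau, ramp[::-1]])
    out: list[EmgRecording] = []
    for muscle in MUSCLES:
        for trial in range(n_trials):
            activation = {}
            for ch in EMG_CHANNELS:
                if ch.rsplit("_", 1)[0] == muscle:
                    activation[ch] = (model.baseline_activation
                                      + (1.0 - model.baseline_activation) * prof)
                else:
                    activation[ch] = np.full(len(prof),
                                             model.baseline_activation)
            out.append(_activation_to_recording(
                activation, rate, model, rng,
                meta={"target_muscle": muscle, "trial": trial}))
    return out


# ---------------------------------------------------------------------------
# full study
# ---------------------------------------------------------------------------

def _subject_rng(master_seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([master_seed, *key]))


def _draw_anthro(rng: np.random.Generator) -> SubjectAnthropometry:
    return SubjectAnthropometry(
        trunk_length=float(np.clip(rng.normal(0.50, 0.02), 0.42, 0.58)),
        shoulder_width=float(np.clip(rng.normal(0.38, 0.02), 0.32, 0.44)),
        trunk_mass=float(np.clip(rng.normal(32.0, 3.0), 24.0, 42.0)),
    )


def generate_study(config, out_dir) -> dict:
    """Write a complete synthetic study dataset to ``out_dir``.

    Layout: a ``manifest.json``, subjective-score CSVs, and per subject a
    ``mvc/`` directory plus one directory per (condition, task) trial holding
    ``markers.tsv``, ``emg.csv`` and ``ground_truth.json``.  The Squat task is
    omitted for the Paexo-like rigid device (its hip hinge does not allow the
    squat degree of freedom).  Identical (config, master seed) reproduce the
    directory byte-for-byte.
    """
    from .config import StudyConfig  # local import to avoid cycles

    if not isinstance(config, StudyConfig):
        raise TypeError("config must be a StudyConfig")
    config.validate()
    root = Path(out_dir)
    root.mkdir(parents=True, exist_ok=True)

    subjects = [f"S{i + 1:02d}" for i in range(config.n_subjects)]
    sexes = ["M" if i % 2 == 0 else "F" for i in range(config.n_subjects)]
    trials = []
    borg_rows = []
    vas_rows = []
    global_rows = []
    subject_info = {}

    for si, subject in enumerate(subjects):
        srng = _subject_rng(config.master_seed, si)
        anthro = _draw_anthro(srng)
        gain_factor = float(np.clip(srng.normal(1.0, 0.1), 0.7, 1.3))
        subject_info[subject] = {"sex": sexes[si],
                                 "anthro": dataclasses.asdict(anthro),
                                 "gain_factor": gain_factor}
        order = [config.conditions[k]
                 for k in srng.permutation(len(config.conditions))]
        subject_info[subject]["condition_order"] = order

        # MVC calibration recordings
        mvc_dir = root / subject / "mvc"
        mvc_dir.mkdir(parents=True, exist_ok=True)
        mvc_model = dataclasses.replace(
            config.emg_model,
            seed=int(_subject_rng(config.master_seed, si, 9999)
                     .integers(2**31)))
        for rec in generate_mvc_trials(mvc_model):
            name = f"{rec.meta['target_muscle']}_{rec.meta['trial'] + 1}.csv"
            rec.write_csv(mvc_dir / name)

        for ci, condition in enumerate(config.conditions):
            exo = config.exo_model(condition)
            for ti, task_name in enumerate(config.tasks):
                task = Task(task_name)
                if task == Task.SQUAT and condition in config.squat_excluded:
                    continue
                spec = config.task_spec(task)
                trial_seed = int(_subject_rng(config.master_seed, si, ci, ti)
                                 .integers(2**31))
                series, gt = generate_lift_kinematics(
                    anthro, spec, exo=exo, seed=trial_seed,
                    marker_noise_std=config.marker_noise_std)
                emg_model = dataclasses.replace(
                    config.emg_model, gain=config.emg_model.gain * gain_factor,
                    seed=trial_seed + 1)
                rec = generate_emg(gt, anthro, emg_model)

                tdir = root / subject / condition / task.value
                tdir.mkdir(parents=True, exist_ok=True)
                write_markers_tsv(series, tdir / "markers.tsv")
                rec.write_csv(tdir / "emg.csv")
                (tdir / "ground_truth.json").write_text(gt.to_json())
                trials.append({"subject": subject, "condition": condition,
                               "task": task.value,
                               "dir": str(tdir.relative_to(root))})

                borg = int(np.clip(round(srng.normal(
                    config.borg_mean[condition], config.borg_sd)), 6, 20))
                borg_rows.append({"subject": subject, "condition": condition,
                                  "task": task.value, "borg": borg})

            for region in config.vas_regions:
                mean = config.vas_mean[condition].get(
                    region, config.vas_mean[condition]["default"])
                vas = float(np.clip(srng.normal(mean, config.vas_sd), 0.0, 10.0))
                vas_rows.append({"subject": subject, "condition": condition,
                                 "region": region, "vas": round(vas, 2)})
            gmean = config.vas_mean[condition]["default"]
            gvas = float(np.clip(srng.normal(gmean, config.vas_sd), 0.0, 10.0))
            global_rows.append({"subject": subject, "condition": condition,
                                "sex": sexes[si], "vas": round(gvas, 2)})

    pd.DataFrame(borg_rows).to_csv(root / "scores_borg.csv", index=False)
    pd.DataFrame(vas_rows).to_csv(root / "scores_vas.csv", index=False)
    pd.DataFrame(global_rows).to_csv(root / "scores_global_vas.csv", index=False)

    manifest = {
        "master_seed": config.master_seed,
        "subjects": subjects,
        "conditions": config.conditions,
        "tasks": [Task(t).value for t in config.tasks],
        "squat_excluded": sorted(config.squat_excluded),
        "marker_rate": 128.0,
        "emg_rate": 2048.0,
        "subject_info": subject_info,
        "trials": trials,
    }
    (root / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                   sort_keys=True))
    return manifest
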
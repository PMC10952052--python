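"""Canonical verification experiments for the benchmarking pipeline.

Self-contained, seeded experiments that exercise the pipeline end to end on
synthetic inputs with known answers: a closed-form hysteresis cycle, filter
and envelope calibration, kinematic and device-parameter recovery, the
assist-share iEMG ratio experiment, and the qualitative rigid-vs-soft
assistance ranking.  They are used by the test suite and by the
reproduction script, and are convenient sanity checks after any change to
the processing chain.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from . import emg as em
from . import exo as xo
from . import kinematics as kin
from .synthetic import (DYNAMIC_TASKS, ERECTOR_SPINAE, EmgGenModel,
                        SubjectAnthropometry, Task, TaskSpec, generate_emg,
                        generate_lift_kinematics, generate_mvc_trials,
                        gravitational_moment)

__all__ = [
    "closed_form_hysteresis",
    "bandpass_gains",
    "envelope_calibration",
    "static_angle_recovery",
    "soft_stiffness_recovery",
    "iemg_ratio_experiment",
    "device_assistance_survey",
]


def closed_form_hysteresis(rate: float = 128.0, k_loading: float = 40.0,
                           k_unloading: float = 24.0,
                           theta_max_rad: float = 1.0) -> xo.HysteresisResult:
    """Hysteresis of a linear-branch cycle with a known closed form.

    θ(t) follows a raised cosine 0 → θ_max → 0 at the capture rate; the
    moment is k_load·θ on the way down and k_unload·θ on the way up, so the
    branch areas are triangles (k·θ_max²/2) and the loss is
    (k_load − k_unload)·θ_max²/2.
    """
    half = int(2.0 * rate)
    up = 0.5 * (1 - np.cos(np.linspace(0, np.pi, half)))
    theta_rad = theta_max_rad * np.concatenate([up, up[::-1]])
    theta_deg = np.degrees(theta_rad)
    moment = np.concatenate([k_loading * theta_rad[:half],
                             k_unloading * theta_rad[half:]])
    time = np.arange(2 * half) / rate
    theta = kin.AngleSeries(angle=theta_deg,
                            velocity=np.gradient(theta_deg, time),
                            rate=rate, time=time)
    cycle = ((kin.Phase.FLEXION, 0, half), (kin.Phase.EXTENSION, half, 2 * half))
    curve = xo.build_moment_angle_curve(moment, theta, cycle, task="demo",
                                        exo="linear")
    return xo.hysteresis(curve)


def bandpass_gains(rate: float = 2048.0, duration: float = 4.0,
                   freqs: tuple[float, ...] = (5.0, 100.0, 600.0)) -> dict:
    """Measured gain of the zero-lag band-pass at probe frequencies, plus the
    lag (samples) of the cross-correlation peak for the in-band probe."""
    t = np.arange(int(duration * rate)) / rate
    out: dict = {}
    for f in freqs:
        x = np.sin(2 * np.pi * f * t)
        rec = em.EmgRecording(channels=["probe"], signal=x[:, None], rate=rate)
        y = em.bandpass(rec).signal[:, 0]
        mid = slice(len(t) // 4, 3 * len(t) // 4)
        out[f"gain_{f:g}hz"] = float(np.abs(y[mid]).max())
        if 30.0 <= f <= 300.0:
            xc, yc = x[mid] - x[mid].mean(), y[mid] - y[mid].mean()
            corr = np.correlate(yc, xc, mode="full")
            out["inband_xcorr_lag_samples"] = int(
                np.argmax(corr) - (len(xc) - 1))
    return out


def envelope_calibration(amplitude: float = 2.5e-4, seed: int = 0,
                         rate: float = 2048.0,
                         plateau: float = 10.0) -> dict:
    """Linear-envelope gain on an amplitude-modulated Gaussian carrier.

    The mean envelope of a zero-mean Gaussian of standard deviation A is
    A·sqrt(2/π) after full-wave rectification; the 6 Hz low-pass preserves
    that mean, so the plateau envelope should sit at A·sqrt(2/π).
    """
    from scipy.signal import butter, filtfilt

    rng = np.random.default_rng(seed)
    n = int(plateau * rate)
    b, a = butter(2, np.array([30.0, 300.0]) / (rate / 2), btype="bandpass")
    carrier = filtfilt(b, a, rng.standard_normal(n))
    carrier /= carrier.std()
    x = amplitude * carrier
    rec = em.EmgRecording(channels=["probe"], signal=x[:, None], rate=rate)
    env = em.envelope(rec).signal[:, 0]
    mid = slice(n // 5, 4 * n // 5)
    measured = float(env[mid].mean())
    expected = amplitude * np.sqrt(2.0 / np.pi)
    return {"measured": measured, "expected": expected,
            "ratio": measured / expected, "n": n}


def static_angle_recovery(target: Task = Task.STATIC40,
                          anthro: SubjectAnthropometry | None = None) -> dict:
    """Noise-free Static trial: recovered hold angle and max tracking error."""
    anthro = anthro or SubjectAnthropometry()
    spec = TaskSpec(task=target)
    series, gt = generate_lift_kinematics(anthro, spec, marker_noise_std=0.0)
    theta = kin.trunk_inclination(series)
    hold = gt.true_theta >= gt.true_theta.max() - 1e-9
    return {
        "hold_angle_deg": float(theta.angle[hold].mean()),
        "max_error_deg": float(np.abs(theta.angle - gt.true_theta).max()),
        "n": series.n_frames,
    }


def soft_stiffness_recovery(stiffness: float = 0.9,
                            anthro: SubjectAnthropometry | None = None) -> dict:
    """Recover k·ΔL_max·arm through the full soft-exo pipeline.

    A unilateral linear band of known stiffness (N/mm) is attached to a
    noise-free Stoop trial; the pipeline peak sagittal moment is compared
    with the analytic peak k·ΔL_max·moment_arm.
    """
    anthro = anthro or SubjectAnthropometry()
    model = xo.SoftExoModel(name="probe_band",
                            loading_coeffs=[0.0, stiffness],
                            unloading_coeffs=[0.0, stiffness],
                            elongation_range=(0.0, 200.0),
                            band_marker_labels=[("LBAND_T", "LBAND_M")],
                            moment_arm=0.10)
    spec = TaskSpec(task=Task.STOOP, n_repetitions=1)
    series, gt = generate_lift_kinematics(anthro, spec, exo=model,
                                          marker_noise_std=0.0)
    theta = kin.trunk_inclination(series)
    seg = kin.segment_phases(theta)
    moment = xo.soft_assistive_moment(series, seg, model)
    expected = stiffness * float(gt.true_elongation.max()) * model.moment_arm
    return {"measured_peak_Nm": float(moment.max()),
            "expected_peak_Nm": expected,
            "relative_error": float(moment.max() / expected - 1.0),
            "n": series.n_frames}


def iemg_ratio_experiment(assist_share: float = 0.3, n_seeds: int = 20,
                          seed: int = 0,
                          anthro: SubjectAnthropometry | None = None) -> dict:
    """Across-seed mean iEMG ratio (exo / no-exo) for erector-spinae channels.

    An ideal fully compensating device (exo moment equal to the
    gravitational trunk moment) with assist share s removes exactly the
    fraction s of the muscle drive, so after MVC normalization and
    movement-gated integration the expected ratio is slightly above 1 − s
    (the baseline activation is shared by both conditions).
    """
    anthro = anthro or SubjectAnthropometry()
    spec = TaskSpec(task=Task.STOOP, n_repetitions=1)
    series, gt = generate_lift_kinematics(anthro, spec, marker_noise_std=0.0)
    theta = kin.trunk_inclination(series)
    mask = kin.movement_mask(theta)
    m_grav = gravitational_moment(anthro, gt.true_theta)
    gt_exo = dataclasses.replace(gt, true_exo_moment=m_grav,
                                 true_assist_share=assist_share)

    base = EmgGenModel(seed=seed)
    root = np.random.SeedSequence(seed)
    ref = em.mvc_reference(generate_mvc_trials(
        dataclasses.replace(base, seed=int(root.generate_state(1)[0] >> 1))))

    def pipeline_iemg(rec: em.EmgRecording) -> float:
        norm = em.normalize(em.envelope(em.bandpass(rec)), ref)
        iemg = em.dynamic_iemg(norm, mask, series.rate)
        return float(np.mean([iemg[c] for c in ERECTOR_SPINAE]))

    ratios = []
    for child in root.spawn(n_seeds):
        s_no, s_ex = (int(st >> 1) for st in child.generate_state(2))
        rec_no = generate_emg(gt, anthro, dataclasses.replace(base, seed=s_no))
        rec_ex = generate_emg(gt_exo, anthro,
                              dataclasses.replace(base, seed=s_ex,
                                                  assist_share=assist_share))
        ratios.append(pipeline_iemg(rec_ex) / pipeline_iemg(rec_no))
    return {"assist_share": assist_share,
            "mean_ratio": float(np.mean(ratios)),
            "ratios": [float(r) for r in ratios],
            "n": n_seeds}


def device_assistance_survey(devices: tuple[str, ...] = (
        "laevo_like", "paexo_like", "auxivo_like", "darwing_like"),
        anthro: SubjectAnthropometry | None = None) -> dict:
    """Peak-moment and hysteresis survey over noise-free Dynamic trials.

    One trial per device × Dynamic task (the Paexo-like hip hinge skips
    Squat); returns the assistance summary tables plus the rigid-vs-soft
    peak-moment margin.
    """
    anthro = anthro or SubjectAnthropometry()
    records = []
    kinds = {}
    for name in devices:
        model = xo.builtin_device(name)
        kinds[name] = model.kind
        for task in DYNAMIC_TASKS:
            if task == Task.SQUAT and model.kind == "rigid" and "paexo" in name:
                continue
            spec = TaskSpec(task=task)
            series, _ = generate_lift_kinematics(anthro, spec, exo=model,
                                                 marker_noise_std=0.0)
            theta = kin.trunk_inclination(series)
            seg = kin.segment_phases(theta)
            if model.kind == "soft":
                moment = xo.soft_assistive_moment(series, seg, model)
                arm_max = model.moment_arm
            else:
                moment, arm = xo.rigid_assistive_moment(series, seg, model)
                arm_max = float(arm.max())
            curve = xo.build_moment_angle_curve(
                moment, theta, kin.first_lift_cycle(seg),
                task=task.value, exo=name)
            records.append({"exo": name, "task": task.value, "curve": curve,
                            "moment_arm_max": arm_max})
    summary = xo.summarize_assistance(records)
    peaks = summary["peaks"].set_index("exo")["peak_moment_Nm"]
    rigid = [n for n in devices if kinds[n] == "rigid"]
    soft = [n for n in devices if kinds[n] == "soft"]
    return {"summary": summary,
            "peaks_Nm": peaks.to_dict(),
            "mean_loss_percent": summary["peaks"].set_index("exo")
                                 ["mean_loss_percent"].to_dict(),
            "rigid_min_peak_Nm": float(peaks[rigid].min()) if rigid else None,
            "soft_max_peak_Nm": float(peaks[soft].max()) if soft else None}
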
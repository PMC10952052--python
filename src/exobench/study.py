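"""End-to-end study orchestration: dataset validation, per-trial processing,
aggregation, and report writing.

``validate_dataset`` checks a dataset directory against its manifest (files
present, rates valid, required markers available) without modifying it;
``run_benchmark`` processes every trial — trunk kinematics, phase
segmentation, device moments and hysteresis for exo conditions, MVC-normalized
EMG metrics — then aggregates assistance tables, runs the condition
statistics, and writes CSV/JSON outputs plus a run manifest (config hash,
seed, versions) sufficient to reproduce deterministic stages bit-identically.
Per-trial failures are quarantined and reported; the run continues.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import emg as emg_mod
from . import exo as exo_mod
from . import kinematics as kin
from .config import NO_EXO, StudyConfig
from .markers import read_markers
from .stats import build_comparison_report
from .synthetic import DYNAMIC_TASKS, ERECTOR_SPINAE, Task

__all__ = ["ValidationReport", "ReportBundle", "validate_dataset",
           "run_benchmark", "static_hold_window"]


@dataclass
class ValidationReport:
    errors: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)
    cells_present: list[tuple[str, str]] = field(default_factory=list)
    cells_absent: list[tuple[str, str]] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors


@dataclass
class ReportBundle:
    metrics: pd.DataFrame
    assistance: dict[str, pd.DataFrame]
    curves: pd.DataFrame
    statistics: dict
    manifest: dict
    trial_warnings: list[dict] = field(default_factory=list)
    failures: list[dict] = field(default_factory=list)


def _load_manifest(root: Path) -> dict:
    path = root / "manifest.json"
    if not path.exists():
        raise FileNotFoundError(f"no manifest.json under {root}")
    return json.loads(path.read_text())


def validate_dataset(dataset_root, config: StudyConfig | None = None
                     ) -> ValidationReport:
    """Check dataset completeness and sample-rate validity; never modifies data."""
    config = config or StudyConfig()
    root = Path(dataset_root)
    rep = ValidationReport()
    try:
        manifest = _load_manifest(root)
    except FileNotFoundError as exc:
        rep.errors.append(str(exc))
        return rep

    required_markers = list(kin.SACRUM_MARKERS + kin.ACROMION_MARKERS)
    seen_cells = set()
    for trial in manifest["trials"]:
        tdir = root / trial["dir"]
        label = f"{trial['subject']}/{trial['condition']}/{trial['task']}"
        for fname in ("markers.tsv", "emg.csv"):
            if not (tdir / fname).exists():
                rep.errors.append(f"{label}: missing {fname}")
        if rep.errors and not (tdir / "markers.tsv").exists():
            continue
        try:
            series = read_markers(tdir / "markers.tsv",
                                  required=required_markers)
        except Exception as exc:  # unparseable, gaps, missing markers
            rep.errors.append(f"{label}: {exc}")
            continue
        if not 100.0 <= series.rate <= 500.0:
            rep.warnings.append(
                f"{label}: unusual marker rate {series.rate:.1f} Hz")
        try:
            rec = emg_mod.read_emg_csv(tdir / "emg.csv")
        except Exception as exc:
            rep.errors.append(f"{label}: {exc}")
            continue
        if rec.rate < 1024.0:
            rep.errors.append(
                f"{label}: EMG rate {rec.rate:.0f} Hz too low for the "
                "30-300 Hz band-pass (need >= 1024 Hz)")
        seen_cells.add((trial["condition"], trial["task"]))
    for cond, path in config.exo_model_files.items():
        if not Path(path).exists():
            rep.errors.append(f"exo model file for {cond!r} missing: {path}")
    for subject in manifest["subjects"]:
        mvc_dir = root / subject / "mvc"
        if not mvc_dir.exists() or not any(mvc_dir.glob("*.csv")):
            rep.errors.append(f"{subject}: no MVC calibration recordings")

    expected_absent = {(c, Task.SQUAT.value)
                       for c in manifest.get("squat_excluded", [])}
    for cond in manifest["conditions"]:
        for task in manifest["tasks"]:
            cell = (cond, task)
            if cell in seen_cells:
                rep.cells_present.append(cell)
            elif cell in expected_absent:
                rep.cells_absent.append(cell)
            else:
                rep.errors.append(f"expected trial cell missing: {cell}")
    return rep


def static_hold_window(theta: kin.AngleSeries, vel_band: float = 2.0,
                       frac_of_peak: float = 0.5) -> tuple[float, float]:
    """Longest quasi-static near-peak interval of a Static trial (seconds)."""
    near_peak = theta.angle > frac_of_peak * theta.angle.max()
    still = np.abs(theta.velocity) < vel_band
    ok = near_peak & still
    best, cur_start, best_span = None, None, 0
    for i, flag in enumerate(np.append(ok, False)):
        if flag and cur_start is None:
            cur_start = i
        elif not flag and cur_start is not None:
            if i - cur_start > best_span:
                best, best_span = (cur_start, i), i - cur_start
            cur_start = None
    if best is None:
        raise ValueError("no static hold found")
    return float(theta.time[best[0]]), float(theta.time[best[1] - 1])


def _subject_mvc_reference(root: Path, subject: str,
                           config: StudyConfig) -> emg_mod.MvcReference:
    trials = [emg_mod.read_emg_csv(p)
              for p in sorted((root / subject / "mvc").glob("*.csv"))]
    return emg_mod.mvc_reference(trials)


def _process_trial(root: Path, trial: dict, config: StudyConfig,
                   mvc_ref: emg_mod.MvcReference, exo_models: dict):
    tdir = root / trial["dir"]
    task = Task(trial["task"])
    condition = trial["condition"]
    series = read_markers(tdir / "markers.tsv",
                          required=list(kin.SACRUM_MARKERS
                                        + kin.ACROMION_MARKERS))
    theta = kin.trunk_inclination(series)
    rec = emg_mod.read_emg_csv(tdir / "emg.csv")
    env = emg_mod.envelope(
        emg_mod.bandpass(rec, order=config.filter_order,
                         notch_50hz=config.notch_50hz),
        order=config.filter_order)
    norm = emg_mod.normalize(env, mvc_ref)

    metrics_rows = []
    curve = None
    arm_max = np.nan

    if task in (Task.STATIC40, Task.STATIC60):
        window = static_hold_window(theta)
        rms = emg_mod.static_rms(norm, window)
        for ch, val in rms.items():
            muscle, side = ch.rsplit("_", 1)
            metrics_rows.append({"subject": trial["subject"],
                                 "condition": condition, "task": task.value,
                                 "muscle": muscle, "side": side,
                                 "metric": "rms", "value": val})
    else:
        seg = kin.segment_phases(theta,
                                 dead_band=config.segmentation_dead_band,
                                 min_duration=config.segmentation_min_duration)
        mask = kin.movement_mask(theta, threshold=config.movement_threshold)
        iemg = emg_mod.dynamic_iemg(norm, mask, series.rate)
        for ch, val in iemg.items():
            muscle, side = ch.rsplit("_", 1)
            metrics_rows.append({"subject": trial["subject"],
                                 "condition": condition, "task": task.value,
                                 "muscle": muscle, "side": side,
                                 "metric": "iemg", "value": val})
        if condition != NO_EXO:
            model = exo_models[condition]
            if isinstance(model, exo_mod.SoftExoModel):
                moment = exo_mod.soft_assistive_moment(series, seg, model)
                arm_max = model.moment_arm
            else:
                moment, arm = exo_mod.rigid_assistive_moment(series, seg, model)
                arm_max = float(arm.max())
            cycle = kin.first_lift_cycle(seg)
            curve = exo_mod.build_moment_angle_curve(
                moment, theta, cycle, task=task.value, exo=condition)
    return metrics_rows, curve, arm_max


def run_benchmark(dataset_root, out_dir, config: StudyConfig | None = None
                  ) -> ReportBundle:
    """Process a dataset end to end and write the report bundle to ``out_dir``."""
    config = config or StudyConfig()
    root = Path(dataset_root)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    validation = validate_dataset(root, config)
    if not validation.ok:
        raise ValueError("dataset validation failed:\n"
                         + "\n".join(validation.errors))
    manifest = _load_manifest(root)
    exo_models = {c: config.exo_model(c) for c in manifest["conditions"]
                  if c != NO_EXO}

    mvc_refs = {s: _subject_mvc_reference(root, s, config)
                for s in manifest["subjects"]}

    metrics_rows: list[dict] = []
    assistance_records: list[dict] = []
    curve_frames: list[pd.DataFrame] = []
    trial_warnings: list[dict] = []
    failures: list[dict] = []

    for trial in sorted(manifest["trials"],
                        key=lambda t: (t["subject"], t["condition"], t["task"])):
        label = f"{trial['subject']}/{trial['condition']}/{trial['task']}"
        try:
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always")
                rows, curve, arm_max = _process_trial(
                    root, trial, config, mvc_refs[trial["subject"]], exo_models)
            for w in caught:
                trial_warnings.append({"trial": label,
                                       "message": str(w.message)})
        except Exception as exc:
            failures.append({"trial": label, "error": str(exc)})
            continue
        metrics_rows.extend(rows)
        if curve is not None:
            assistance_records.append({"exo": trial["condition"],
                                       "task": trial["task"],
                                       "subject": trial["subject"],
                                       "curve": curve,
                                       "moment_arm_max": arm_max})
            curve_frames.append(curve.to_frame())

    metrics = pd.DataFrame(metrics_rows)
    assistance = (exo_mod.summarize_assistance(assistance_records)
                  if assistance_records
                  else {"peaks": pd.DataFrame(), "hysteresis": pd.DataFrame(),
                        "hysteresis_grid": pd.DataFrame()})
    curves = (pd.concat(curve_frames, ignore_index=True)
              if curve_frames else pd.DataFrame())

    borg_path = root / "scores_borg.csv"
    gvas_path = root / "scores_global_vas.csv"
    borg = pd.read_csv(borg_path) if borg_path.exists() else None
    gvas = pd.read_csv(gvas_path) if gvas_path.exists() else None
    statistics = (build_comparison_report(metrics, borg=borg, global_vas=gvas,
                                          alpha=config.alpha)
                  if len(metrics) else {})

    run_manifest = {
        "exobench_version": __version__,
        "config_hash": config.config_hash(),
        "config": config.to_dict(),
        "master_seed": manifest.get("master_seed"),
        "numpy_version": np.__version__,
        "n_trials": len(manifest["trials"]),
        "n_failures": len(failures),
        "force_resolution": exo_mod.FORCE_RESOLUTION_CONVENTION,
    }

    metrics.to_csv(out / "metrics.csv", index=False)
    assistance["peaks"].to_csv(out / "assistance_peaks.csv", index=False)
    assistance["hysteresis"].to_csv(out / "hysteresis.csv", index=False)
    assistance["hysteresis_grid"].to_csv(out / "hysteresis_grid.csv")
    curves.to_csv(out / "curves.csv", index=False)
    (out / "statistics.json").write_text(json.dumps(statistics, indent=1,
                                                    sort_keys=True))
    (out / "run_manifest.json").write_text(json.dumps(run_manifest, indent=1,
                                                      sort_keys=True))
    (out / "warnings.json").write_text(json.dumps(
        {"trial_warnings": trial_warnings, "failures": failures}, indent=1))

    return ReportBundle(metrics=metrics, assistance=assistance, curves=curves,
                        statistics=statistics, manifest=run_manifest,
                        trial_warnings=trial_warnings, failures=failures)
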
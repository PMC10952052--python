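"""Passive-exoskeleton assistance models, moment-angle curves, and hysteresis.

Two device families are modeled.  *Soft* exosuits store energy in elastic
bands: a polynomial force-elongation fit (N vs mm) per branch (loading during
flexion, unloading during extension) is evaluated on the band elongation
measured between the two markers at either end of the band, and the force is
multiplied by a constant sagittal moment arm (default 0.10 m) to obtain the
assistive moment about the sacrum.  *Rigid* exoskeletons are characterized by
a polynomial torque-angle fit (Nm vs the exo angle α): the device torque is
resolved into a force on the trunk at the chest pad, magnitude M_exo/|B1|,
directed perpendicular to the trunk link B1 within the plane spanned by B1
and B2 and pushing the trunk toward extension; the sagittal assistive moment
about the sacrum is the sagittal component of r x F with r from the sacrum
point to the chest-pad marker.  This force-resolution convention is recorded
in output metadata so alternative resolutions can be swapped in.

Hysteresis — the energy lost per lift cycle — is the difference between the
areas under the loading (flexion, i.e. lowering) and unloading (extension)
branches of the moment-angle curve, integrated in the time domain as
∫ M(t) θ̇(t) dt with θ in radians, which avoids re-gridding non-monotone
branches.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .kinematics import (
    EXO_MARKERS,
    SACRUM_MARKERS,
    AngleSeries,
    Phase,
    PhaseSegmentation,
    exo_angle,
)
from .markers import MarkerFrameSeries

__all__ = [
    "SoftExoModel",
    "RigidExoModel",
    "MomentAngleCurve",
    "HysteresisResult",
    "load_exo_model",
    "builtin_device",
    "builtin_device_names",
    "band_elongation",
    "soft_assistive_moment",
    "rigid_assistive_moment",
    "build_moment_angle_curve",
    "hysteresis",
    "summarize_assistance",
]

FORCE_RESOLUTION_CONVENTION = (
    "force at chest pad, magnitude M_exo/|B1|, perpendicular to B1 in the "
    "B1-B2 plane, extension-assisting; sagittal moment about sacrum from r x F"
)


def _evaluate_branch(coeffs: list[float], valid_range: tuple[float, float],
                     x: np.ndarray, what: str) -> np.ndarray:
    """Evaluate an ascending-order polynomial fit, clipping to its range."""
    lo, hi = valid_range
    if np.any((x < lo) | (x > hi)):
        warnings.warn(
            f"{what}: input outside fit range [{lo}, {hi}]; clipped to endpoint"
        )
    xc = np.clip(x, lo, hi)
    return np.polynomial.polynomial.polyval(xc, np.asarray(coeffs, dtype=float))


@dataclass
class SoftExoModel:
    """Soft exosuit: polynomial force-elongation fits per branch.

    ``loading_coeffs``/``unloading_coeffs`` are ascending polynomial
    coefficients giving band force in N as a function of elongation in mm,
    valid over ``elongation_range`` (mm).  ``band_marker_labels`` lists one
    (T, M) marker pair per band (bilateral devices have two); forces from all
    bands are summed.  ``moment_arm`` is the constant sagittal lever in m.
    """

    name: str
    loading_coeffs: list[float]
    unloading_coeffs: list[float]
    elongation_range: tuple[float, float] = (0.0, 100.0)
    band_marker_labels: list[tuple[str, str]] = field(
        default_factory=lambda: [("LBAND_T", "LBAND_M"), ("RBAND_T", "RBAND_M")]
    )
    moment_arm: float = 0.10
    kind: str = "soft"

    def __post_init__(self) -> None:
        if self.moment_arm <= 0:
            raise ValueError("moment_arm must be positive")
        grid = np.linspace(*self.elongation_range, 50)
        load = _force_or_zero(self.loading_coeffs, grid)
        unload = _force_or_zero(self.unloading_coeffs, grid)
        if np.any(load + 1e-9 < unload):
            raise ValueError(
                f"{self.name}: unloading force exceeds loading force within range"
            )

    def force(self, elongation_mm: np.ndarray, branch: str) -> np.ndarray:
        coeffs = self.loading_coeffs if branch == "loading" else self.unloading_coeffs
        f = _evaluate_branch(coeffs, self.elongation_range, elongation_mm,
                             f"{self.name} {branch} force-elongation")
        return np.maximum(f, 0.0)


def _force_or_zero(coeffs, grid):
    return np.maximum(np.polynomial.polynomial.polyval(grid, np.asarray(coeffs)), 0.0)


@dataclass
class RigidExoModel:
    """Rigid exoskeleton: polynomial torque-angle fits per branch.

    Coefficients (ascending) give device torque in Nm as a function of the
    exo angle α in degrees over ``alpha_range``.  ``attachment_labels`` binds
    (chest-pad/clavicle, exo hip joint, thigh pad) marker names.
    """

    name: str
    loading_coeffs: list[float]
    unloading_coeffs: list[float]
    alpha_range: tuple[float, float] = (0.0, 110.0)
    attachment_labels: tuple[str, str, str] = EXO_MARKERS
    kind: str = "rigid"

    def __post_init__(self) -> None:
        grid = np.linspace(*self.alpha_range, 50)
        load = _force_or_zero(self.loading_coeffs, grid)
        unload = _force_or_zero(self.unloading_coeffs, grid)
        if np.any(load + 1e-9 < unload):
            raise ValueError(
                f"{self.name}: unloading torque exceeds loading torque within range"
            )

    def torque(self, alpha_deg: np.ndarray, branch: str) -> np.ndarray:
        coeffs = self.loading_coeffs if branch == "loading" else self.unloading_coeffs
        tau = _evaluate_branch(coeffs, self.alpha_range, alpha_deg,
                               f"{self.name} {branch} torque-angle")
        return np.maximum(tau, 0.0)


ExoModel = SoftExoModel | RigidExoModel


def load_exo_model(path) -> ExoModel:
    """Load a device parameter file (YAML or JSON)."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return exo_model_from_dict(data)


def exo_model_from_dict(data: dict) -> ExoModel:
    kind = data["type"]
    if kind == "soft":
        return SoftExoModel(
            name=data["name"],
            loading_coeffs=list(data["loading"]["coeffs"]),
            unloading_coeffs=list(data["unloading"]["coeffs"]),
            elongation_range=tuple(data.get("elongation_range_mm", (0.0, 100.0))),
            band_marker_labels=[tuple(p) for p in data.get(
                "band_marker_labels",
                [("LBAND_T", "LBAND_M"), ("RBAND_T", "RBAND_M")])],
            moment_arm=float(data.get("moment_arm_m", 0.10)),
        )
    if kind == "rigid":
        return RigidExoModel(
            name=data["name"],
            loading_coeffs=list(data["loading"]["coeffs"]),
            unloading_coeffs=list(data["unloading"]["coeffs"]),
            alpha_range=tuple(data.get("alpha_range_deg", (0.0, 110.0))),
            attachment_labels=tuple(data.get("attachment_labels", EXO_MARKERS)),
        )
    raise ValueError(f"unknown exo type {kind!r}")


def builtin_device_names() -> list[str]:
    from importlib.resources import files

    folder = files("exobench").joinpath("devices")
    return sorted(p.name[:-5] for p in folder.iterdir()
                  if p.name.endswith(".yaml"))


def builtin_device(name: str) -> ExoModel:
    """Load one of the packaged synthetic device parameterizations."""
    from importlib.resources import files

    res = files("exobench").joinpath("devices").joinpath(f"{name}.yaml")
    if not res.is_file():
        raise FileNotFoundError(
            f"no packaged device {name!r}; available: {builtin_device_names()}")
    return exo_model_from_dict(yaml.safe_load(res.read_text()))


# ---------------------------------------------------------------------------
# soft exosuit
# ---------------------------------------------------------------------------

def band_elongation(series: MarkerFrameSeries, model: SoftExoModel,
                    reference_frame: int = 0,
                    per_band: bool = False) -> np.ndarray:
    """Band elongation ΔL(t) in mm from the T and M markers.

    ΔL(t) = |TM(t)| - |TM(t0)| per band, straight-line distance (band
    curvature assumed small), referenced to ``reference_frame`` (default the
    first frame, assumed neutral standing).  Returns the across-band mean, or
    an (n_frames, n_bands) array with ``per_band=True``.
    """
    cols = []
    for t_label, m_label in model.band_marker_labels:
        d = np.linalg.norm(series.get(t_label) - series.get(m_label), axis=1)
        cols.append((d - d[reference_frame]) * 1000.0)
    out = np.column_stack(cols)
    return out if per_band else out.mean(axis=1)


def _branch_per_frame(seg: PhaseSegmentation, n_frames: int) -> np.ndarray:
    """'loading' during flexion, 'unloading' during extension; frames outside
    every segment (static holds, dead band before movement) use loading."""
    branch = np.full(n_frames, "loading", dtype=object)
    for phase, start, end in seg.segments:
        branch[start:end] = "loading" if phase == Phase.FLEXION else "unloading"
    return branch


def soft_assistive_moment(series: MarkerFrameSeries, seg: PhaseSegmentation,
                          model: SoftExoModel,
                          reference_frame: int = 0) -> np.ndarray:
    """Sagittal assistive moment (Nm) of a soft exosuit along a trial.

    Each band's phase-appropriate force-elongation fit is evaluated on its
    own elongation; band forces are summed and multiplied by the constant
    moment arm.  Negative forces clamp to zero (a passive band cannot push).
    """
    elong = band_elongation(series, model, reference_frame, per_band=True)
    branch = _branch_per_frame(seg, series.n_frames)
    total_force = np.zeros(series.n_frames)
    for b in ("loading", "unloading"):
        rows = branch == b
        if rows.any():
            total_force[rows] = model.force(elong[rows], b).sum(axis=1)
    return total_force * model.moment_arm


# ---------------------------------------------------------------------------
# rigid exoskeleton
# ---------------------------------------------------------------------------

def rigid_assistive_moment(series: MarkerFrameSeries, seg: PhaseSegmentation,
                           model: RigidExoModel,
                           sacrum_markers: tuple[str, str] = SACRUM_MARKERS,
                           ) -> tuple[np.ndarray, np.ndarray]:
    """Sagittal assistive moment (Nm) and sagittal moment arm (m), per frame.

    The device torque from the phase-appropriate torque-angle fit at α(t) is
    resolved into a trunk force of magnitude M_exo/|B1| at the chest-pad
    marker, perpendicular to B1 in the B1-B2 plane and extension-assisting;
    the assistive moment is the sagittal (lab Y) component of r x F with r
    from the sacrum point to the chest pad.  Negative (flexing) moments clamp
    to zero.
    """
    clav_l, hip_l, thigh_l = model.attachment_labels
    alpha = exo_angle(series, markers=model.attachment_labels)
    branch = _branch_per_frame(seg, series.n_frames)
    tau = np.zeros(series.n_frames)
    for b in ("loading", "unloading"):
        rows = branch == b
        if rows.any():
            tau[rows] = model.torque(alpha.angle[rows], b)

    clav = series.get(clav_l)
    hip = series.get(hip_l)
    thigh = series.get(thigh_l)
    sacrum = series.midpoint(*sacrum_markers)

    b1 = hip - clav
    b2 = thigh - hip
    n1 = np.linalg.norm(b1, axis=1)
    normal = np.cross(b1, b2)
    nn = np.linalg.norm(normal, axis=1)
    # degenerate (collinear links): assume sagittal-plane motion, normal = lab Y
    degenerate = nn < 1e-9 * np.maximum(n1 * np.linalg.norm(b2, axis=1), 1e-12)
    normal[degenerate] = [0.0, 1.0, 0.0]
    direction = np.cross(normal, b1)
    dn = np.linalg.norm(direction, axis=1)
    dn[dn < 1e-12] = 1.0
    direction /= dn[:, None]

    force = (tau / n1)[:, None] * direction
    r = clav - sacrum
    moment_y = np.cross(r, force)[:, 1]
    # extension-assist is a negative moment about lab +Y (flexion rotates the
    # trunk from +Z toward +X, i.e. positively about +Y); flip the force
    # direction frame-wise where it would push into flexion
    assist = -moment_y
    flip = assist < 0
    assist[flip] = -assist[flip]
    moment_arm = np.hypot(r[:, 0], r[:, 2])
    return assist, moment_arm


# ---------------------------------------------------------------------------
# moment-angle curves and hysteresis
# ---------------------------------------------------------------------------

@dataclass
class MomentAngleCurve:
    """Assistive moment vs trunk inclination for one lift cycle.

    ``flexion``/``extension`` are (theta_deg, moment_Nm) sample arrays taken
    at the trial frames inside each branch of the first lift cycle.
    """

    flexion_theta: np.ndarray
    flexion_moment: np.ndarray
    extension_theta: np.ndarray
    extension_moment: np.ndarray
    task: str = ""
    exo: str = ""
    metadata: dict = field(default_factory=dict)

    def peak(self) -> tuple[float, float]:
        """(peak moment in Nm, trunk angle at peak in deg) over both branches."""
        theta = np.concatenate([self.flexion_theta, self.extension_theta])
        moment = np.concatenate([self.flexion_moment, self.extension_moment])
        if len(moment) == 0:
            raise ValueError("empty curve")
        k = int(np.argmax(moment))
        return float(moment[k]), float(theta[k])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for branch, th, mo in (("flexion", self.flexion_theta, self.flexion_moment),
                               ("extension", self.extension_theta,
                                self.extension_moment)):
            for t, m in zip(th, mo):
                rows.append({"task": self.task, "exo": self.exo, "branch": branch,
                             "theta_deg": t, "moment_Nm": m})
        return pd.DataFrame(rows)


@dataclass
class HysteresisResult:
    """Energy per lift cycle in each branch and the hysteresis loss.

    ``loss_percent`` is expressed relative to the loading (lowering) branch
    area; undefined (NaN) when the loading area is not positive.
    """

    loading_area: float
    unloading_area: float

    @property
    def loss(self) -> float:
        return self.loading_area - self.unloading_area

    @property
    def loss_percent(self) -> float:
        if self.loading_area <= 0:
            return float("nan")
        return 100.0 * self.loss / self.loading_area


def build_moment_angle_curve(moment: np.ndarray, theta: AngleSeries,
                             cycle, task: str = "", exo: str = "",
                             metadata: dict | None = None) -> MomentAngleCurve:
    """Restrict a moment timeseries to the first-lift-cycle branches."""
    flex, ext = cycle
    fs, fe = flex[1], flex[2]
    es, ee = ext[1], ext[2]
    if fe <= fs or ee <= es:
        raise ValueError("empty lift cycle")
    meta = {"force_resolution": FORCE_RESOLUTION_CONVENTION}
    if metadata:
        meta.update(metadata)
    return MomentAngleCurve(
        flexion_theta=theta.angle[fs:fe].copy(),
        flexion_moment=np.asarray(moment[fs:fe], dtype=float),
        extension_theta=theta.angle[es:ee].copy(),
        extension_moment=np.asarray(moment[es:ee], dtype=float),
        task=task, exo=exo, metadata=meta,
    )


def hysteresis(curve: MomentAngleCurve) -> HysteresisResult:
    """Hysteresis of one moment-angle cycle, Nm·rad.

    Branch areas are ∫ M dθ (θ in radians) computed sample-wise along the
    trial frames (trapezoidal, equivalent to time-domain ∫ M θ̇ dt); the
    extension branch traverses θ downward, so its raw integral is negated.
    """
    if len(curve.flexion_moment) < 2 or len(curve.extension_moment) < 2:
        raise ValueError("both branches must be non-empty")
    loading = float(np.trapezoid(curve.flexion_moment,
                                 np.radians(curve.flexion_theta)))
    unloading = -float(np.trapezoid(curve.extension_moment,
                                    np.radians(curve.extension_theta)))
    return HysteresisResult(loading_area=loading, unloading_area=unloading)


def summarize_assistance(records: list[dict]) -> dict[str, pd.DataFrame]:
    """Aggregate per-trial curves into device-level assistance tables.

    ``records`` rows carry keys ``exo``, ``task``, ``curve``
    (:class:`MomentAngleCurve`) and optionally ``moment_arm_max`` (m).
    Returns ``peaks`` (per exo: peak moment, angle at peak, max sagittal
    moment arm) and ``hysteresis`` (exo x task grid of mean loss in Nm·rad
    with loss percent, cells absent where no trial exists, e.g. the
    Paexo-like device never performs Squat).
    """
    rows = []
    for rec in records:
        curve: MomentAngleCurve = rec["curve"]
        h = hysteresis(curve)
        peak_m, peak_theta = curve.peak()
        rows.append({
            "exo": rec["exo"], "task": rec["task"],
            "peak_moment_Nm": peak_m, "angle_at_peak_deg": peak_theta,
            "moment_arm_max_cm": 100.0 * rec.get("moment_arm_max", np.nan),
            "loss_Nmrad": h.loss, "loss_percent": h.loss_percent,
        })
    df = pd.DataFrame(rows)
    peaks = (df.groupby("exo")
               .apply(_peak_row, include_groups=False)
               .reset_index())
    hyst = (df.groupby(["exo", "task"])[["loss_Nmrad", "loss_percent"]]
              .mean().reset_index())
    hyst["cell"] = [f"{r.loss_Nmrad:.2f} ({r.loss_percent:.1f}%)"
                    for r in hyst.itertuples()]
    grid = hyst.pivot(index="exo", columns="task", values="cell")
    return {"peaks": peaks, "hysteresis": hyst, "hysteresis_grid": grid}


def _peak_row(g: pd.DataFrame) -> pd.Series:
    k = g["peak_moment_Nm"].idxmax()
    return pd.Series({
        "peak_moment_Nm": g.loc[k, "peak_moment_Nm"],
        "angle_at_peak_deg": g.loc[k, "angle_at_peak_deg"],
        "peak_task": g.loc[k, "task"],
        "moment_arm_max_cm": g["moment_arm_max_cm"].max(),
        "mean_loss_percent": g["loss_percent"].mean(),
    })
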
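"""Trunk and exoskeleton angles, phase segmentation, and lift-cycle extraction.

Trunk inclination θ is the angle of the vector from the sacrum point (midpoint
of the two posterior sacroiliac markers) to the acromion midpoint, measured
from the vertical lab axis; θ = 0° standing upright, flexion increases θ.
The exo angle α is the angle between the rigid exo's trunk link B1 (clavicle
marker → exo hip joint marker) and its leg link B2 (exo hip joint → thigh
pad).  Dynamic lifting trials are segmented into flexion and extension phases
from the sign of the trunk angular velocity, with a dead band and a minimum
segment duration to suppress chatter at movement reversals; muscle-effort
integration (iEMG) is gated by a movement mask on |velocity|.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy.signal import butter, filtfilt

from .markers import MarkerFrameSeries

__all__ = [
    "Phase",
    "AngleSeries",
    "PhaseSegmentation",
    "trunk_inclination",
    "exo_angle",
    "segment_phases",
    "first_lift_cycle",
    "movement_mask",
    "segmentation_from_labels",
]

#: default marker-label bindings for the synthetic marker set; real exports
#: with different naming conventions are bound through these keyword args.
SACRUM_MARKERS = ("LPSI", "RPSI")
ACROMION_MARKERS = ("LACR", "RACR")
EXO_MARKERS = ("CLAV", "EXO_HIP", "EXO_THIGH")


class Phase(str, Enum):
    FLEXION = "flexion"
    EXTENSION = "extension"
    HOLD = "hold"


@dataclass
class AngleSeries:
    """An angle trajectory (degrees) with its angular velocity (deg/s)."""

    angle: np.ndarray
    velocity: np.ndarray
    rate: float
    time: np.ndarray
    source: str = "trunk"


@dataclass
class PhaseSegmentation:
    """Ordered, alternating, non-overlapping flexion/extension segments.

    Segments are half-open frame intervals ``[start, end)``.
    """

    segments: list[tuple[Phase, int, int]] = field(default_factory=list)
    rate: float = 128.0

    def __len__(self) -> int:
        return len(self.segments)

    def count(self, phase: Phase) -> int:
        return sum(1 for p, _, _ in self.segments if p == phase)

    def labels(self, n_frames: int) -> np.ndarray:
        """Per-frame phase labels; frames outside every segment are 'hold'."""
        out = np.full(n_frames, Phase.HOLD.value, dtype=object)
        for phase, start, end in self.segments:
            out[start:end] = phase.value
        return out


def _smoothed(angle: np.ndarray, rate: float, cutoff: float | None) -> np.ndarray:
    if cutoff is None or len(angle) < 15:
        return angle
    b, a = butter(2, cutoff / (rate / 2.0), btype="low")
    return filtfilt(b, a, angle)


def _angle_from_vertical(vec: np.ndarray) -> np.ndarray:
    norm = np.linalg.norm(vec, axis=1)
    if np.any(norm < 1e-12):
        raise ValueError("degenerate (zero-length) trunk vector")
    horiz = np.hypot(vec[:, 0], vec[:, 1])
    return np.degrees(np.arctan2(horiz, vec[:, 2]))


def trunk_inclination(series: MarkerFrameSeries,
                      sacrum_markers: tuple[str, str] = SACRUM_MARKERS,
                      acromion_markers: tuple[str, str] = ACROMION_MARKERS,
                      vel_smooth_hz: float | None = 2.0) -> AngleSeries:
    """Trunk inclination θ(t) from the sacrum point to the acromion midpoint.

    The reported angle is computed directly from the marker geometry; a
    zero-lag 2 Hz low-pass (configurable, ``None`` disables) is applied only
    before differentiation so the velocity channel is smooth.
    """
    sacrum = series.midpoint(*sacrum_markers)
    acromion = series.midpoint(*acromion_markers)
    theta = _angle_from_vertical(acromion - sacrum)
    vel = np.gradient(_smoothed(theta, series.rate, vel_smooth_hz), series.time)
    return AngleSeries(angle=theta, velocity=vel, rate=series.rate,
                       time=series.time, source="trunk")


def exo_angle(series: MarkerFrameSeries,
              markers: tuple[str, str, str] = EXO_MARKERS,
              vel_smooth_hz: float | None = 2.0) -> AngleSeries:
    """Rigid-exo angle α(t) between trunk link B1 and leg link B2."""
    clav, hip, thigh = (series.get(m) for m in markers)
    b1 = hip - clav
    b2 = thigh - hip
    n1 = np.linalg.norm(b1, axis=1)
    n2 = np.linalg.norm(b2, axis=1)
    if np.any(n1 < 1e-12) or np.any(n2 < 1e-12):
        raise ValueError("degenerate exo link vector")
    cross = np.linalg.norm(np.cross(b1, b2), axis=1)
    dot = np.einsum("ij,ij->i", b1, b2)
    alpha = np.degrees(np.arctan2(cross, dot))
    vel = np.gradient(_smoothed(alpha, series.rate, vel_smooth_hz), series.time)
    return AngleSeries(angle=alpha, velocity=vel, rate=series.rate,
                       time=series.time, source="exo")


def segment_phases(angles: AngleSeries, dead_band: float = 2.0,
                   min_duration: float = 0.25) -> PhaseSegmentation:
    """Segment a trial into flexion/extension phases from velocity sign.

    Frames with velocity above ``+dead_band`` deg/s are flexion, below
    ``-dead_band`` extension.  Runs shorter than ``min_duration`` are merged
    into the longer neighboring run; dead-band frames between segments are
    attached to the preceding segment.  A trial with no movement (Static
    hold) yields an empty segmentation with a warning.
    """
    vel = angles.velocity
    n = len(vel)
    sign = np.zeros(n, dtype=int)
    sign[vel > dead_band] = 1
    sign[vel < -dead_band] = -1

    # run-length encode the nonzero portions
    runs: list[list] = []  # [phase_sign, start, end)
    i = 0
    while i < n:
        if sign[i] == 0:
            i += 1
            continue
        j = i
        while j < n and sign[j] == sign[i]:
            j += 1
        runs.append([sign[i], i, j])
        i = j

    if not runs:
        warnings.warn("no movement detected: all velocities within dead band")
        return PhaseSegmentation(segments=[], rate=angles.rate)

    min_frames = max(1, int(round(min_duration * angles.rate)))

    def coalesce(rr: list[list]) -> list[list]:
        out: list[list] = []
        for r in rr:
            if out and out[-1][0] == r[0]:
                out[-1][2] = r[2]
            else:
                out.append(list(r))
        return out

    runs = coalesce(runs)
    # iteratively absorb sub-minimum runs into their longer neighbor
    changed = True
    while changed and len(runs) > 1:
        changed = False
        lengths = [r[2] - r[1] for r in runs]
        order = int(np.argmin(lengths))
        if lengths[order] < min_frames:
            neighbors = []
            if order > 0:
                neighbors.append(order - 1)
            if order < len(runs) - 1:
                neighbors.append(order + 1)
            target = max(neighbors, key=lambda k: runs[k][2] - runs[k][1])
            runs[order][0] = runs[target][0]
            runs = coalesce(runs)
            changed = True
    runs = [r for r in runs if r[2] - r[1] >= min_frames]
    if not runs:
        warnings.warn("no segment longer than the minimum duration")
        return PhaseSegmentation(segments=[], rate=angles.rate)

    # attach dead-band frames between segments to the preceding segment
    for k in range(len(runs) - 1):
        runs[k][2] = runs[k + 1][1]

    segments = [
        (Phase.FLEXION if r[0] > 0 else Phase.EXTENSION, r[1], r[2]) for r in runs
    ]
    return PhaseSegmentation(segments=segments, rate=angles.rate)


def first_lift_cycle(seg: PhaseSegmentation) -> tuple[tuple[Phase, int, int],
                                                      tuple[Phase, int, int]]:
    """First flexion segment and the first subsequent extension segment.

    The first lifting cycle begins with the first flexion (bending down to
    pick up the load) and ends with the extension back to standing.
    """
    flex = None
    for item in seg.segments:
        phase, _, _ = item
        if flex is None:
            if phase == Phase.FLEXION:
                flex = item
        elif phase == Phase.EXTENSION:
            return flex, item
    if flex is None:
        raise ValueError("no flexion segment found")
    raise ValueError("no extension segment after the first flexion")


def movement_mask(angles: AngleSeries, threshold: float = 5.0) -> np.ndarray:
    """Boolean per-frame mask: True where |angular velocity| > threshold."""
    return np.abs(angles.velocity) > threshold


def segmentation_from_labels(labels: np.ndarray, rate: float) -> PhaseSegmentation:
    """Build a segmentation from per-frame 'flexion'/'extension'/'hold' labels."""
    segments: list[tuple[Phase, int, int]] = []
    n = len(labels)
    i = 0
    while i < n:
        lab = labels[i]
        j = i
        while j < n and labels[j] == lab:
            j += 1
        if lab in (Phase.FLEXION.value, Phase.EXTENSION.value):
            segments.append((Phase(lab), i, j))
        i = j
    return PhaseSegmentation(segments=segments, rate=rate)
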
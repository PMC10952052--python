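"""Labeled 3D marker trajectories and the tab-separated capture export dialect.

The in-memory container is :class:`MarkerFrameSeries`: one lab frame
(right-handed, Z vertical up, meters), one sampling rate (128 Hz for optical
capture), all markers present in every frame.  On-disk exchange uses a TSV
dialect mirroring optical motion-capture exports: a header row
``Frame\tTime\t<label>_X\t<label>_Y\t<label>_Z ...`` followed by one row per
frame with positions in millimeters.  Missing samples (gaps) are empty fields;
gaps of at most ``max_gap`` consecutive frames are linearly interpolated on
read, longer gaps are an error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MarkerFrameSeries",
    "MarkerGapError",
    "UnsupportedFormatError",
    "read_markers",
    "write_markers_tsv",
]


class MarkerGapError(ValueError):
    """A marker trajectory has a gap longer than the interpolation limit."""


class UnsupportedFormatError(ValueError):
    """The requested marker file dialect cannot be read in this build."""


@dataclass
class MarkerFrameSeries:
    """Labeled marker positions over time in a single metric lab frame.

    Attributes
    ----------
    labels : list of str
        Marker names, order matches the second axis of ``positions``.
    positions : ndarray, shape (n_frames, n_markers, 3)
        Positions in meters, lab frame (X anterior, Y left, Z up).
    rate : float
        Sampling rate in Hz.
    time : ndarray, shape (n_frames,)
        Time of each frame in seconds, strictly increasing, starts at 0.
    """

    labels: list[str]
    positions: np.ndarray
    rate: float
    time: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 3 or self.positions.shape[2] != 3:
            raise ValueError("positions must have shape (n_frames, n_markers, 3)")
        if self.positions.shape[1] != len(self.labels):
            raise ValueError("number of labels does not match positions")
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        if self.time is None:
            self.time = np.arange(self.n_frames) / self.rate
        self.time = np.asarray(self.time, dtype=float)
        if self.n_frames > 1 and not np.all(np.diff(self.time) > 0):
            raise ValueError("time must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    def has(self, *labels: str) -> bool:
        return all(lab in self.labels for lab in labels)

    def get(self, label: str) -> np.ndarray:
        """Return the (n_frames, 3) trajectory of one marker in meters."""
        try:
            idx = self.labels.index(label)
        except ValueError as exc:
            raise KeyError(f"marker {label!r} not present (have {self.labels})") from exc
        return self.positions[:, idx, :]

    def midpoint(self, label_a: str, label_b: str) -> np.ndarray:
        return 0.5 * (self.get(label_a) + self.get(label_b))


def write_markers_tsv(series: MarkerFrameSeries, path) -> None:
    """Write a marker series to the TSV capture dialect (positions in mm)."""
    cols: dict[str, np.ndarray] = {
        "Frame": np.arange(series.n_frames),
        # time needs more digits than the mm positions or the rate degrades
        "Time": np.array([f"{t:.8f}" for t in series.time]),
    }
    for i, lab in enumerate(series.labels):
        for j, axis in enumerate("XYZ"):
            cols[f"{lab}_{axis}"] = series.positions[:, i, j] * 1000.0
    df = pd.DataFrame(cols)
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


def _fill_gaps(values: np.ndarray, label: str, max_gap: int) -> np.ndarray:
    """Linearly interpolate NaN runs of length <= max_gap; error otherwise."""
    out = values.copy()
    isnan = np.isnan(out).any(axis=1)
    if not isnan.any():
        return out
    n = len(out)
    idx = np.flatnonzero(isnan)
    # identify contiguous runs
    run_starts = idx[np.r_[True, np.diff(idx) > 1]]
    run_ends = idx[np.r_[np.diff(idx) > 1, True]]
    for start, end in zip(run_starts, run_ends):
        length = end - start + 1
        if length > max_gap or start == 0 or end == n - 1:
            raise MarkerGapError(
                f"marker {label!r}: gap of {length} frames at frames "
                f"{start}..{end} exceeds the {max_gap}-frame interpolation limit"
            )
        for axis in range(3):
            out[start : end + 1, axis] = np.interp(
                np.arange(start, end + 1),
                [start - 1, end + 1],
                [out[start - 1, axis], out[end + 1, axis]],
            )
    return out


def read_markers(path, dialect: str = "tsv", max_gap: int = 10,
                 required: list[str] | None = None) -> MarkerFrameSeries:
    """Read marker trajectories, converting positions to meters.

    Parameters
    ----------
    path : path-like
        File to read.
    dialect : {"tsv", "c3d"}
        Only the TSV capture dialect is supported in this build; requesting
        ``"c3d"`` raises :class:`UnsupportedFormatError`.
    max_gap : int
        Longest NaN gap (consecutive frames) filled by linear interpolation.
    required : list of str, optional
        Marker labels that must be present; missing labels raise KeyError.
    """
    if dialect == "c3d":
        raise UnsupportedFormatError(
            "C3D reading is not available in this build; export the capture "
            "to the TSV dialect instead"
        )
    if dialect != "tsv":
        raise UnsupportedFormatError(f"unknown marker dialect {dialect!r}")
    df = pd.read_csv(path, sep="\t")
    if "Time" not in df.columns:
        raise ValueError(f"{path}: not a marker TSV export (no Time column)")
    time = df["Time"].to_numpy(dtype=float)
    if len(time) < 2:
        raise ValueError(f"{path}: needs at least two frames")
    rate = 1.0 / float(np.median(np.diff(time)))
    labels: list[str] = []
    for col in df.columns:
        if col.endswith("_X"):
            labels.append(col[:-2])
    if not labels:
        raise ValueError(f"{path}: no marker columns found")
    if required:
        missing = [lab for lab in required if lab not in labels]
        if missing:
            raise KeyError(f"{path}: missing required markers {missing}")
    n = len(df)
    positions = np.empty((n, len(labels), 3))
    for i, lab in enumerate(labels):
        block = df[[f"{lab}_X", f"{lab}_Y", f"{lab}_Z"]].to_numpy(dtype=float)
        positions[:, i, :] = _fill_gaps(block, lab, max_gap) / 1000.0
    return MarkerFrameSeries(labels=labels, positions=positions, rate=rate,
                             time=time - time[0])
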
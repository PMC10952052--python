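"""Surface-EMG processing: band-pass, linear envelope, MVC normalization,
static RMS and movement-gated iEMG.

The processing chain follows standard ergonomics practice: band-pass
30-300 Hz, full-wave rectification, 6 Hz low-pass to the linear envelope,
amplitude normalization to the maximum voluntary contraction (MVC) of each
muscle.  All filters are zero-lag Butterworth applied forward-backward
(``filtfilt``); with the default convention a second-order design is used so
the net magnitude response is fourth-order.  Static trials are summarized by
the RMS of the normalized envelope over the hold window; Dynamic trials by
the time-integral of the envelope (iEMG, %MVC·s) gated by a movement mask
derived from the trunk angular velocity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d
from scipy.signal import butter, filtfilt, iirnotch

__all__ = [
    "EmgRecording",
    "MvcReference",
    "bandpass",
    "envelope",
    "mvc_reference",
    "normalize",
    "static_rms",
    "dynamic_iemg",
    "read_emg_csv",
]


@dataclass
class EmgRecording:
    """Multi-channel EMG: ``signal`` (n_samples, n_channels) in volts (or
    %MVC after normalization), channel names ``muscle_side``."""

    channels: list[str]
    signal: np.ndarray
    rate: float
    time: np.ndarray = field(default=None)  # type: ignore[assignment]
    units: str = "V"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.signal = np.atleast_2d(np.asarray(self.signal, dtype=float))
        if self.signal.shape[1] != len(self.channels):
            raise ValueError("signal width does not match channel count")
        if self.time is None:
            self.time = np.arange(self.signal.shape[0]) / self.rate
        self.time = np.asarray(self.time, dtype=float)

    @property
    def n_samples(self) -> int:
        return self.signal.shape[0]

    def channel(self, name: str) -> np.ndarray:
        return self.signal[:, self.channels.index(name)]

    def write_csv(self, path) -> None:
        df = pd.DataFrame(self.signal, columns=self.channels)
        df.insert(0, "time", self.time)
        df.to_csv(path, index=False, float_format="%.5e")


def read_emg_csv(path, channel_map: dict[str, str] | None = None) -> EmgRecording:
    """Read the delimited EMG export (header of channel names, time in s,
    values in volts).  ``channel_map`` renames real-export channels onto the
    canonical ``muscle_side`` names."""
    df = pd.read_csv(path)
    if "time" not in df.columns:
        raise ValueError(f"{path}: EMG export must have a 'time' column")
    time = df["time"].to_numpy(dtype=float)
    if len(time) < 2:
        raise ValueError(f"{path}: EMG recording too short")
    channels = [c for c in df.columns if c != "time"]
    if channel_map:
        channels = [channel_map.get(c, c) for c in channels]
    rate = 1.0 / float(np.median(np.diff(time)))
    return EmgRecording(channels=channels,
                        signal=df.drop(columns="time").to_numpy(dtype=float),
                        rate=rate, time=time)


def _zero_lag(rec: EmgRecording, b: np.ndarray, a: np.ndarray) -> np.ndarray:
    warmup = 3 * max(len(a), len(b))
    if rec.n_samples <= 3 * warmup:
        raise ValueError(
            f"recording of {rec.n_samples} samples is shorter than the filter "
            "warm-up; need a longer signal")
    return filtfilt(b, a, rec.signal, axis=0)


def bandpass(raw: EmgRecording, band: tuple[float, float] = (30.0, 300.0),
             order: int = 2, notch_50hz: bool = False) -> EmgRecording:
    """Zero-phase Butterworth band-pass (default 30-300 Hz).

    ``order`` is the design order per pass; the forward-backward application
    doubles the effective magnitude roll-off (order 2 → net fourth-order).
    An optional 50 Hz notch can be enabled for mains-contaminated recordings.
    """
    if raw.rate < 2 * band[1]:
        raise ValueError(
            f"sampling rate {raw.rate} Hz too low for a {band[1]} Hz band edge")
    b, a = butter(order, np.asarray(band) / (raw.rate / 2.0), btype="bandpass")
    out = _zero_lag(raw, b, a)
    if notch_50hz:
        bn, an = iirnotch(50.0, Q=30.0, fs=raw.rate)
        out = filtfilt(bn, an, out, axis=0)
    return replace(raw, signal=out)


def envelope(filtered: EmgRecording, cutoff: float = 6.0,
             order: int = 2) -> EmgRecording:
    """Linear envelope: full-wave rectification then zero-phase low-pass."""
    b, a = butter(order, cutoff / (filtered.rate / 2.0), btype="low")
    rect = replace(filtered, signal=np.abs(filtered.signal))
    return replace(filtered, signal=_zero_lag(rect, b, a))


@dataclass
class MvcReference:
    """Per-channel normalization amplitude in volts (strictly positive)."""

    values: dict[str, float]

    def __post_init__(self) -> None:
        bad = [ch for ch, v in self.values.items() if not v > 0]
        if bad:
            raise ValueError(f"non-positive MVC reference for channels {bad}")

    def __getitem__(self, channel: str) -> float:
        return self.values[channel]


def mvc_reference(mvc_trials: list[EmgRecording], window_s: float = 0.5,
                  preprocess: bool = True) -> MvcReference:
    """Per-channel MVC amplitude from calibration trials.

    Each trial is processed to its linear envelope (unless ``preprocess`` is
    False, for already-processed inputs) and the reference is the maximum,
    over all trials, of the ``window_s`` moving average of the envelope —
    more robust to isolated spikes than the raw envelope maximum.
    """
    if not mvc_trials:
        raise ValueError("need at least one MVC trial")
    best: dict[str, float] = {}
    for rec in mvc_trials:
        env = envelope(bandpass(rec)) if preprocess else rec
        w = max(1, int(round(window_s * env.rate)))
        smoothed = uniform_filter1d(env.signal, size=w, axis=0)
        for k, ch in enumerate(env.channels):
            peak = float(smoothed[:, k].max())
            best[ch] = max(best.get(ch, 0.0), peak)
    return MvcReference(values=best)


def normalize(env: EmgRecording, ref: MvcReference) -> EmgRecording:
    """Express the envelope in %MVC (may exceed 100 for submaximal MVCs)."""
    missing = [ch for ch in env.channels if ch not in ref.values]
    if missing:
        raise KeyError(f"MVC reference missing channels {missing}")
    scale = np.array([100.0 / ref[ch] for ch in env.channels])
    out = env.signal * scale
    sustained = (out > 120.0).mean(axis=0)
    for k, ch in enumerate(env.channels):
        if sustained[k] > 0.25:
            warnings.warn(
                f"channel {ch}: envelope exceeds 120 %MVC for "
                f"{100 * sustained[k]:.0f}% of samples; MVC may be submaximal")
    return replace(env, signal=out, units="%MVC")


def static_rms(norm: EmgRecording,
               window: tuple[float, float]) -> dict[str, float]:
    """RMS of the normalized envelope over a hold window (seconds)."""
    t0, t1 = window
    sel = (norm.time >= t0) & (norm.time <= t1)
    if not sel.any():
        raise ValueError(f"empty RMS window [{t0}, {t1}] s")
    seg = norm.signal[sel]
    rms = np.sqrt(np.mean(seg**2, axis=0))
    return {ch: float(rms[k]) for k, ch in enumerate(norm.channels)}


def dynamic_iemg(norm: EmgRecording, mask: np.ndarray,
                 mask_rate: float) -> dict[str, float]:
    """Movement-gated iEMG (%MVC·s): trapezoidal time-integral of the
    normalized envelope over mask-true samples.

    ``mask`` is a per-frame boolean at the motion-capture rate; it is
    upsampled to the EMG timebase by nearest-neighbor before gating.
    """
    idx = np.clip(np.round(norm.time * mask_rate).astype(int), 0, len(mask) - 1)
    gate = mask[idx].astype(float)
    if not gate.any():
        warnings.warn("movement mask is empty; iEMG = 0")
        return {ch: 0.0 for ch in norm.channels}
    vals = np.trapezoid(norm.signal * gate[:, None], norm.time, axis=0)
    return {ch: float(vals[k]) for k, ch in enumerate(norm.channels)}
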
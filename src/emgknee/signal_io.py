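"""Recording I/O, band-pass filtering, window segmentation and target alignment.

A recording pairs a multi-channel surface-EMG matrix (typically 5 kHz) with a
knee-angle stream measured at a lower rate (typically 100 Hz).  On disk a
recording is three sibling files sharing one stem::

    <stem>.emg.csv    one column per muscle, millivolts
    <stem>.angle.csv  single column, degrees
    <stem>.meta.json  {emg_rate, angle_rate, channel_labels, subject_id, trial_id}

plus an optional ``<stem>.phase.csv`` carrying ground-truth gait phase for
synthetic recordings.  Floats are written with 17 significant digits so a
write -> read round trip is bit-exact.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps

from .exceptions import (
    AlignmentError,
    DegenerateScaleError,
    EmptyInputError,
    FormatError,
    ParameterError,
)

#: Canonical muscle labels: vastus lateralis/medialis, biceps femoris,
#: semitendinosus, lateral/medial gastrocnemius.
MUSCLES = ("VL", "VM", "BF", "ST", "LG", "MG")

_FLOAT_FMT = "%.17g"


@dataclass
class TimeSeriesRecording:
    """One trial: paired sEMG channels and a knee-angle stream.

    Parameters
    ----------
    emg : ndarray, shape (n_samples, n_channels)
        Band-unlimited (raw) or filtered sEMG in millivolts.
    emg_rate : float
        sEMG sampling rate in Hz.
    channel_labels : tuple of str
        Muscle name per column; unique.
    angle : ndarray, shape (n_angle,)
        Knee flexion angle in degrees.
    angle_rate : float
        Angle sampling rate in Hz.
    phase : ndarray or None
        Optional ground-truth gait phase in [0, 1) on the angle time grid
        (synthetic recordings only).
    """

    emg: np.ndarray
    emg_rate: float
    channel_labels: tuple
    angle: np.ndarray
    angle_rate: float
    subject_id: str = "S0"
    trial_id: str = "T0"
    phase: np.ndarray | None = None

    def __post_init__(self):
        self.emg = np.asarray(self.emg, dtype=float)
        self.angle = np.asarray(self.angle, dtype=float)
        self.channel_labels = tuple(self.channel_labels)
        if self.emg.ndim != 2:
            raise FormatError("emg must be a 2-D (n_samples, n_channels) matrix")
        if self.emg_rate <= 0 or self.angle_rate <= 0:
            raise FormatError("sampling rates must be positive")
        if len(self.channel_labels) != self.emg.shape[1]:
            raise FormatError(
                f"{len(self.channel_labels)} labels for {self.emg.shape[1]} columns"
            )
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise FormatError("channel labels must be unique")
        if self.angle.ndim != 1 or self.angle.size == 0:
            raise FormatError("angle must be a non-empty 1-D vector")
        # angle length must match duration within one sample
        expected = self.duration * self.angle_rate
        if abs(self.angle.size - expected) > 1.0 + 1e-9:
            raise FormatError(
                f"angle length {self.angle.size} inconsistent with duration "
                f"{self.duration:g}s at {self.angle_rate:g} Hz"
            )
        if self.phase is not None:
            self.phase = np.asarray(self.phase, dtype=float)
            if self.phase.shape != self.angle.shape:
                raise FormatError("phase must be on the angle time grid")

    @property
    def duration(self) -> float:
        """Trial duration in seconds (sEMG grid)."""
        return self.emg.shape[0] / self.emg_rate

    def channel(self, label: str) -> np.ndarray:
        """Return one sEMG channel by muscle label."""
        if label not in self.channel_labels:
            raise KeyError(f"no channel {label!r}; have {self.channel_labels}")
        return self.emg[:, self.channel_labels.index(label)]


def _sibling(stem: Path, ext: str) -> Path:
    # robust against dots inside the stem name
    return stem.parent / (stem.name + ext)


def write_recording(rec: TimeSeriesRecording, stem) -> None:
    """Write a recording to ``<stem>.emg.csv / .angle.csv / .meta.json``."""
    stem = Path(stem)
    stem.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rec.emg, columns=list(rec.channel_labels)).to_csv(
        _sibling(stem, ".emg.csv"), index=False, float_format=_FLOAT_FMT
    )
    pd.DataFrame({"angle_deg": rec.angle}).to_csv(
        _sibling(stem, ".angle.csv"), index=False, float_format=_FLOAT_FMT
    )
    meta = {
        "emg_rate": rec.emg_rate,
        "angle_rate": rec.angle_rate,
        "channel_labels": list(rec.channel_labels),
        "subject_id": rec.subject_id,
        "trial_id": rec.trial_id,
    }
    _sibling(stem, ".meta.json").write_text(json.dumps(meta, indent=1))
    if rec.phase is not None:
        pd.DataFrame({"phase": rec.phase}).to_csv(
            _sibling(stem, ".phase.csv"), index=False, float_format=_FLOAT_FMT
        )


def read_recording(stem) -> TimeSeriesRecording:
    """Read a recording written by :func:`write_recording`."""
    stem = Path(stem)
    meta_path = _sibling(stem, ".meta.json")
    if not meta_path.exists():
        raise FormatError(f"missing metadata sidecar {meta_path}")
    try:
        meta = json.loads(meta_path.read_text())
    except json.JSONDecodeError as e:  # pragma: no cover - defensive
        raise FormatError(f"unreadable metadata {meta_path}: {e}") from e
    for key in ("emg_rate", "angle_rate", "channel_labels", "subject_id", "trial_id"):
        if key not in meta:
            raise FormatError(f"metadata {meta_path} missing key {key!r}")
    emg = pd.read_csv(_sibling(stem, ".emg.csv"),
                      float_precision="round_trip").to_numpy(dtype=float)
    angle = pd.read_csv(_sibling(stem, ".angle.csv"),
                        float_precision="round_trip")["angle_deg"].to_numpy(dtype=float)
    phase_path = _sibling(stem, ".phase.csv")
    phase = (
        pd.read_csv(phase_path, float_precision="round_trip")["phase"].to_numpy(dtype=float)
        if phase_path.exists()
        else None
    )
    return TimeSeriesRecording(
        emg=emg,
        emg_rate=float(meta["emg_rate"]),
        channel_labels=tuple(meta["channel_labels"]),
        angle=angle,
        angle_rate=float(meta["angle_rate"]),
        subject_id=str(meta["subject_id"]),
        trial_id=str(meta["trial_id"]),
        phase=phase,
    )


def bandpass_filter(x, fs, low=10.0, high=500.0, order=4):
    """Zero-phase Butterworth band-pass.

    Uses a forward-backward (``sosfiltfilt``) pass so the output has no phase
    lag, which matters because windows are labelled with the angle at their
    end time.  ``order`` is the design order of the underlying Butterworth
    filter; the two-pass application squares its magnitude response.
    """
    x = np.asarray(x, dtype=float)
    if not (0 < low < high):
        raise ParameterError("need 0 < low < high")
    if high >= fs / 2:
        raise ParameterError(f"high cutoff {high} Hz >= Nyquist {fs / 2} Hz")
    sos = sps.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, x, axis=-1)


def segment_windows(x, fs, window_ms=50.0, step_ms=20.0):
    """Cut a 1-D signal into overlapping analysis windows.

    Returns ``(windows, end_times)`` where ``windows`` has shape (N, n) with
    ``n = round(window_ms * fs / 1000)`` and consecutive rows advance by
    ``round(step_ms * fs / 1000)`` samples; ``end_times[i]`` is the time of the
    last sample in row ``i``.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ParameterError("signal must be 1-D")
    n = int(round(window_ms * fs / 1000.0))
    step = int(round(step_ms * fs / 1000.0))
    if n < 1 or step < 1:
        raise ParameterError("window and step must each span at least one sample")
    if x.size < n:
        raise EmptyInputError(f"signal of {x.size} samples shorter than one window ({n})")
    count = (x.size - n) // step + 1
    windows = np.lib.stride_tricks.sliding_window_view(x, n)[:: step][:count]
    starts = np.arange(count) * step
    end_times = (starts + n - 1) / fs
    return np.ascontiguousarray(windows), end_times


def align_targets(angle, angle_rate, window_end_times):
    """Angle target per window: linear interpolation at the window end time.

    No extrapolation: an end time outside ``[0, (len-1)/angle_rate]`` raises
    :class:`AlignmentError`.
    """
    angle = np.asarray(angle, dtype=float)
    t = np.asarray(window_end_times, dtype=float)
    span = (angle.size - 1) / angle_rate
    if t.size and (t.min() < -1e-12 or t.max() > span + 1e-12):
        raise AlignmentError(
            f"window end times span [{t.min():g}, {t.max():g}] s outside "
            f"angle stream span [0, {span:g}] s"
        )
    grid = np.arange(angle.size) / angle_rate
    return np.interp(t, grid, angle)


@dataclass
class AngleScaler:
    """Affine map between degrees and the tanh range [-1, 1].

    Fitted on training-fold extrema only; held-out targets may fall slightly
    outside [-1, 1] and are never clipped when computing metrics.
    """

    y_min: float
    y_max: float

    def __post_init__(self):
        if not self.y_max > self.y_min:
            raise DegenerateScaleError("y_max must exceed y_min")

    @classmethod
    def fit(cls, targets_deg) -> "AngleScaler":
        y = np.asarray(targets_deg, dtype=float)
        lo, hi = float(np.min(y)), float(np.max(y))
        if hi <= lo:
            raise DegenerateScaleError("constant targets cannot be scaled to [-1, 1]")
        return cls(lo, hi)

    def scale(self, deg):
        return (np.asarray(deg, dtype=float) - self.y_min) / (self.y_max - self.y_min) * 2.0 - 1.0

    def inverse(self, scaled, clip=False):
        s = np.asarray(scaled, dtype=float)
        if clip:
            s = np.clip(s, -1.0, 1.0)
        return (s + 1.0) / 2.0 * (self.y_max - self.y_min) + self.y_min


@dataclass
class WindowedDataset:
    """Fixed-length sEMG windows with one aligned angle target each."""

    windows: np.ndarray           # (N, n) millivolts
    targets_deg: np.ndarray       # (N,)
    window_end_times: np.ndarray  # (N,) seconds, within-trial
    trial_ids: np.ndarray         # (N,) integer trial index
    source_channel: str
    emg_rate: float
    fold_ids: np.ndarray | None = None

    def __post_init__(self):
        n = self.windows.shape[0]
        for name in ("targets_deg", "window_end_times", "trial_ids"):
            if getattr(self, name).shape[0] != n:
                raise FormatError(f"{name} length does not match window count {n}")

    def __len__(self):
        return self.windows.shape[0]

    @property
    def n_trials(self) -> int:
        return int(np.unique(self.trial_ids).size)


def build_windowed_dataset(
    recordings,
    channel,
    window_ms=50.0,
    step_ms=20.0,
    band=(10.0, 500.0),
    filter_order=4,
):
    """Filter, segment and label one sEMG channel across trials.

    Each trial is band-pass filtered and windowed independently (windows never
    straddle trial boundaries).  Windows whose end time falls beyond the angle
    stream's span are dropped rather than extrapolated.
    """
    all_w, all_y, all_t, all_trial = [], [], [], []
    for i, rec in enumerate(recordings):
        x = rec.channel(channel)
        if band is not None:
            x = bandpass_filter(x, rec.emg_rate, band[0], band[1], order=filter_order)
        w, end_t = segment_windows(x, rec.emg_rate, window_ms, step_ms)
        span = (rec.angle.size - 1) / rec.angle_rate
        keep = end_t <= span + 1e-12
        w, end_t = w[keep], end_t[keep]
        y = align_targets(rec.angle, rec.angle_rate, end_t)
        all_w.append(w)
        all_y.append(y)
        all_t.append(end_t)
        all_trial.append(np.full(w.shape[0], i, dtype=int))
    if not all_w:
        raise EmptyInputError("no recordings given")
    return WindowedDataset(
        windows=np.concatenate(all_w),
        targets_deg=np.concatenate(all_y),
        window_end_times=np.concatenate(all_t),
        trial_ids=np.concatenate(all_trial),
        source_channel=channel,
        emg_rate=recordings[0].emg_rate,
    )
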
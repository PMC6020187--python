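"""EMG and kinematic pre-processing for reach-to-grasp trials.

A trial couples multichannel surface EMG (12 muscles at 1000 Hz in the
reference montage: seven upper-arm and five forearm sites) with a single
elbow-goniometer angle trace.  This module turns raw EMG into normalized
linear envelopes (full-wave rectification followed by a low-pass 7th-order
Butterworth at 20 Hz, then per-channel division by the maximum observed over
a reference set of trials) and differentiates the goniometer angle into
angular velocity and acceleration for the phase segmentation downstream.

Envelope filtering is causal (single-pass) by default because the decoder
is meant to run online; zero-phase filtering is available for offline
analysis via ``zero_phase=True``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import signal

#: The 12 recorded muscles: 7 upper-arm sites followed by 5 forearm sites.
MUSCLES_12 = [
    "trapezius",
    "deltoid_anterior",
    "deltoid_medial",
    "deltoid_posterior",
    "biceps_brachii",
    "triceps_brachii",
    "brachialis",
    "flexor_digitorum_superficialis",
    "extensor_digitorum_communis",
    "flexor_carpi_ulnaris",
    "extensor_carpi_ulnaris",
    "flexor_carpi_radialis",
]
UPPER_ARM_SLICE = slice(0, 7)
FOREARM_SLICE = slice(7, 12)
FOREARM_MUSCLES = MUSCLES_12[FOREARM_SLICE]


@dataclass
class Trial:
    """One reach-to-grasp recording.

    Parameters
    ----------
    emg : ndarray of shape (n_channels, n_samples)
        Raw EMG (or generated envelope-level signal), arbitrary units.
    angle : ndarray of shape (n_samples,)
        Elbow-goniometer angle, degrees.
    fs : float
        Sampling rate, Hz.
    label : str
        Grasp-type class label.
    subject : str
        Subject identifier; classifiers are trained per subject.
    subject_kind : str
        ``"able_bodied"`` or ``"amputee"``.
    channel_names : list of str
        Muscle name per EMG channel.
    """

    emg: np.ndarray
    angle: np.ndarray
    fs: float
    label: str
    subject: str = "s01"
    subject_kind: str = "able_bodied"
    channel_names: list[str] = field(default_factory=lambda: list(MUSCLES_12))
    trial_id: str = ""

    def __post_init__(self) -> None:
        self.emg = np.asarray(self.emg, dtype=float)
        self.angle = np.asarray(self.angle, dtype=float)
        if self.emg.ndim != 2:
            raise ValueError("emg must be a (n_channels, n_samples) matrix")
        if self.emg.shape[1] != self.angle.shape[0]:
            raise ValueError(
                f"emg has {self.emg.shape[1]} samples but angle has "
                f"{self.angle.shape[0]}"
            )
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if len(self.channel_names) != self.emg.shape[0]:
            raise ValueError("channel_names length must equal n_channels")

    @property
    def n_channels(self) -> int:
        return self.emg.shape[0]

    @property
    def n_samples(self) -> int:
        return self.emg.shape[1]


@dataclass
class Envelope:
    """Linear EMG envelope: rectified, low-passed, optionally normalized."""

    data: np.ndarray  # (n_channels, n_samples)
    fs: float
    normalized: bool = False
    norm_constants: np.ndarray | None = None
    channel_names: list[str] = field(default_factory=list)

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class KinematicTrace:
    """Elbow angle with its first two time derivatives."""

    angle: np.ndarray  # degrees
    velocity: np.ndarray  # deg/s
    acceleration: np.ndarray  # deg/s^2
    fs: float


def compute_envelope(
    trial: Trial,
    cutoff_hz: float = 20.0,
    order: int = 7,
    zero_phase: bool = False,
) -> Envelope:
    """Full-wave rectify the EMG and smooth it with a low-pass Butterworth.

    Parameters
    ----------
    trial : Trial
        Input trial; ``trial.emg`` must be finite.
    cutoff_hz : float
        Low-pass cut-off, default 20 Hz.
    order : int
        Butterworth order, default 7.
    zero_phase : bool
        If True use forward-backward filtering (no group delay, offline
        only).  Default is causal single-pass filtering, suitable for
        online operation.

    Returns
    -------
    Envelope
        Same shape and sampling rate as the input, ``normalized`` False.
    """
    if trial.fs <= 2 * cutoff_hz:
        raise ValueError(
            f"sampling rate {trial.fs} Hz must exceed twice the cut-off "
            f"({2 * cutoff_hz} Hz)"
        )
    bad = ~np.isfinite(trial.emg).all(axis=1)
    if bad.any():
        idx = np.flatnonzero(bad).tolist()
        names = [trial.channel_names[i] for i in idx]
        raise ValueError(f"non-finite EMG samples in channels {idx} ({names})")
    rectified = np.abs(trial.emg)
    sos = signal.butter(order, cutoff_hz, btype="low", fs=trial.fs, output="sos")
    if zero_phase:
        data = signal.sosfiltfilt(sos, rectified, axis=1)
    else:
        data = signal.sosfilt(sos, rectified, axis=1)
    return Envelope(
        data=np.asarray(data),
        fs=trial.fs,
        normalized=False,
        channel_names=list(trial.channel_names),
    )


def bandpass_raw(
    emg: np.ndarray, fs: float, low_hz: float = 30.0, high_hz: float = 350.0,
    order: int = 4,
) -> np.ndarray:
    """Software 30-350 Hz band-pass for synthetic raw EMG.

    Recorded data are assumed band-passed at acquisition; this exists so a
    fully synthetic raw signal can be pushed through the same pipeline.
    """
    sos = signal.butter(order, [low_hz, high_hz], btype="band", fs=fs, output="sos")
    return np.asarray(signal.sosfilt(sos, emg, axis=-1))


def reference_maxima(reference: Iterable[Envelope]) -> np.ndarray:
    """Per-channel maximum over a set of envelopes."""
    maxima = None
    for env in reference:
        m = env.data.max(axis=1)
        maxima = m if maxima is None else np.maximum(maxima, m)
    if maxima is None:
        raise ValueError("reference set is empty")
    return maxima


def normalize_channels(
    envelope: Envelope, reference: Sequence[Envelope]
) -> Envelope:
    """Divide each channel by its maximum over the reference set.

    The reference set is typically the training trials (the default in the
    evaluation pipeline, avoiding test-set leakage); passing all trials
    reproduces normalization by the maximum over the whole session.
    """
    maxima = reference_maxima(reference)
    if maxima.shape[0] != envelope.n_channels:
        raise ValueError("reference channel count mismatch")
    zero = maxima <= 0
    if zero.any():
        idx = np.flatnonzero(zero)
        names = (
            [envelope.channel_names[i] for i in idx]
            if envelope.channel_names
            else list(idx)
        )
        raise ValueError(f"reference maximum is zero for channels {list(idx)} ({names})")
    return Envelope(
        data=envelope.data / maxima[:, None],
        fs=envelope.fs,
        normalized=True,
        norm_constants=maxima,
        channel_names=list(envelope.channel_names),
    )


def differentiate_angle(
    angle: np.ndarray, fs: float, smooth_window_ms: float = 50.0
) -> KinematicTrace:
    """Estimate angular velocity and acceleration from the goniometer angle.

    The angle is smoothed with a moving average of ``smooth_window_ms``
    (default 50 ms, stabilizing the 10 %-of-max threshold crossings) before
    centered finite differencing.
    """
    angle = np.asarray(angle, dtype=float)
    if angle.size < 3:
        raise ValueError("need at least 3 samples to differentiate")
    w = max(1, int(round(smooth_window_ms * fs / 1000.0)))
    if w > 1:
        kernel = np.ones(w) / w
        # reflect-pad so the edges do not decay toward zero
        padded = np.pad(angle, w, mode="reflect")
        smoothed = np.convolve(padded, kernel, mode="same")[w:-w]
    else:
        smoothed = angle
    velocity = np.gradient(smoothed) * fs
    acceleration = np.gradient(velocity) * fs
    return KinematicTrace(
        angle=angle, velocity=velocity, acceleration=acceleration, fs=fs
    )


# ---------------------------------------------------------------------------
# Trial on-disk format: delimited text + JSON sidecar, plus a dataset manifest
# ---------------------------------------------------------------------------

def save_trial(trial: Trial, directory: str | Path, trial_id: str) -> tuple[Path, Path]:
    """Write one trial as ``<id>.csv`` (time_s, angle_deg, channels) + ``<id>.json``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    t = np.arange(trial.n_samples) / trial.fs
    df = pd.DataFrame({"time_s": t, "angle_deg": trial.angle})
    for name, row in zip(trial.channel_names, trial.emg):
        df[name] = row
    csv_path = directory / f"{trial_id}.csv"
    df.to_csv(csv_path, index=False, float_format="%.6f")
    meta = {
        "subject": trial.subject,
        "subject_kind": trial.subject_kind,
        "label": trial.label,
        "fs": trial.fs,
        "trial_id": trial_id,
    }
    json_path = directory / f"{trial_id}.json"
    json_path.write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")
    return csv_path, json_path


def load_trial(csv_path: str | Path) -> Trial:
    csv_path = Path(csv_path)
    meta = json.loads(csv_path.with_suffix(".json").read_text())
    df = pd.read_csv(csv_path)
    channel_names = [c for c in df.columns if c not in ("time_s", "angle_deg")]
    return Trial(
        emg=df[channel_names].to_numpy().T,
        angle=df["angle_deg"].to_numpy(),
        fs=float(meta["fs"]),
        label=meta["label"],
        subject=meta["subject"],
        subject_kind=meta["subject_kind"],
        channel_names=channel_names,
        trial_id=meta.get("trial_id", csv_path.stem),
    )


def save_dataset(
    trials: Sequence[Trial], directory: str | Path, config: dict | None = None
) -> Path:
    """Write a directory of trials plus a ``manifest.json``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    files = []
    for i, trial in enumerate(trials):
        trial_id = trial.trial_id or f"trial_{i:03d}"
        save_trial(trial, directory, trial_id)
        files.append(f"{trial_id}.csv")
    manifest = {"files": files, "config": config or {}}
    path = directory / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path


def load_dataset(directory: str | Path) -> list[Trial]:
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    return [load_trial(directory / f) for f in manifest["files"]]
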
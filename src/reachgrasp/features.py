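"""Sliding-window EMG features: mean activation, waveform length, slope-sign changes.

Windows are 150 ms long with a 50 ms increment by default.  Each window
yields a feature vector of length 3 x n_channels ordered as
``[mean_activation x N, waveform_length x N, slope_sign_changes x N]``.
Features are computed on the normalized linear envelope; the classical
variant on raw EMG is available through ``allow_unnormalized``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .phase_segmentation import PhaseBoundaries, assign_phase
from .preprocessing import Envelope

DEFAULT_WINDOW_MS = 150.0
DEFAULT_STEP_MS = 50.0
#: slope-sign-change deadband: 1 % of the normalized envelope range
DEFAULT_SSC_EPS = 0.01


@dataclass
class WindowFeatures:
    start_idx: int
    end_idx: int  # exclusive
    t_end_s: float
    phase: object  # 'pre', 1, 2, 3 or 'post'
    features: np.ndarray  # (3 * n_channels,)
    label: str | None = None


def sliding_windows(
    n_samples: int,
    fs: float,
    window_ms: float = DEFAULT_WINDOW_MS,
    step_ms: float = DEFAULT_STEP_MS,
) -> list[tuple[int, int]]:
    """Half-open (start, end) index pairs at start = 0, step, 2*step, ..."""
    w = int(round(window_ms * fs / 1000.0))
    s = int(round(step_ms * fs / 1000.0))
    if w < 2 or s < 1:
        raise ValueError("window and step must span at least 2 and 1 samples")
    if n_samples < w:
        raise ValueError(
            f"signal of {n_samples} samples is shorter than one window ({w})"
        )
    starts = range(0, n_samples - w + 1, s)
    return [(start, start + w) for start in starts]


def mean_activation(window: np.ndarray) -> float:
    """Arithmetic mean of an (already rectified) envelope window."""
    window = np.asarray(window)
    if window.size == 0:
        raise ValueError("empty window")
    return float(window.mean())


def waveform_length(window: np.ndarray) -> float:
    """Sum of absolute successive differences."""
    window = np.asarray(window)
    if window.size < 2:
        raise ValueError("waveform length needs at least 2 samples")
    return float(np.abs(np.diff(window)).sum())


def slope_sign_changes(window: np.ndarray, eps: float = DEFAULT_SSC_EPS) -> int:
    """Count interior samples where the slope changes sign.

    A change is counted at sample i when
    ``(x_i - x_{i-1}) * (x_i - x_{i+1}) > 0`` and the larger of the two
    excursions is at least ``eps`` (noise deadband; ``eps=0`` recovers the
    raw count).
    """
    window = np.asarray(window)
    if window.size < 3:
        raise ValueError("slope-sign changes need at least 3 samples")
    if eps < 0:
        raise ValueError("eps must be non-negative")
    left = window[1:-1] - window[:-2]
    right = window[1:-1] - window[2:]
    flips = (left * right) > 0
    big = np.maximum(np.abs(left), np.abs(right)) >= eps
    return int(np.count_nonzero(flips & big))


def _window_feature_matrix(data: np.ndarray, eps: float) -> np.ndarray:
    """Features for a stack of windows, vectorized.

    Parameters
    ----------
    data : ndarray of shape (n_windows, n_channels, w)
    """
    ma = data.mean(axis=2)
    wl = np.abs(np.diff(data, axis=2)).sum(axis=2)
    left = data[:, :, 1:-1] - data[:, :, :-2]
    right = data[:, :, 1:-1] - data[:, :, 2:]
    ssc = np.count_nonzero(
        ((left * right) > 0) & (np.maximum(np.abs(left), np.abs(right)) >= eps),
        axis=2,
    ).astype(float)
    return np.concatenate([ma, wl, ssc], axis=1)


def extract_features(
    envelope: Envelope,
    boundaries: PhaseBoundaries | None = None,
    window_ms: float = DEFAULT_WINDOW_MS,
    step_ms: float = DEFAULT_STEP_MS,
    eps: float = DEFAULT_SSC_EPS,
    label: str | None = None,
    allow_unnormalized: bool = False,
) -> list[WindowFeatures]:
    """One WindowFeatures per sliding window of the envelope.

    Feature ordering within each vector is fixed:
    ``[mean_activation x N, waveform_length x N, slope_sign_changes x N]``
    with channels in envelope order inside each block.
    """
    if not envelope.normalized and not allow_unnormalized:
        raise ValueError(
            "envelope is not normalized; pass allow_unnormalized=True to override"
        )
    pairs = sliding_windows(envelope.n_samples, envelope.fs, window_ms, step_ms)
    stack = np.stack([envelope.data[:, s:e] for s, e in pairs])
    feats = _window_feature_matrix(stack, eps)
    out = []
    for (s, e), vec in zip(pairs, feats):
        phase = assign_phase(boundaries, s, e) if boundaries is not None else None
        out.append(
            WindowFeatures(
                start_idx=s,
                end_idx=e,
                t_end_s=e / envelope.fs,
                phase=phase,
                features=vec,
                label=label,
            )
        )
    return out


def feature_table(per_trial: list[list[WindowFeatures]]):
    """Stack per-trial WindowFeatures into flat arrays.

    Returns ``(X, y, phases, groups, t_end)`` where ``groups`` holds the
    trial index of each window (used for trial-level cross-validation
    folds).
    """
    X, y, phases, groups, t_end = [], [], [], [], []
    for i, wfs in enumerate(per_trial):
        for wf in wfs:
            X.append(wf.features)
            y.append(wf.label)
            phases.append(wf.phase)
            groups.append(i)
            t_end.append(wf.t_end_s)
    return (
        np.asarray(X),
        np.asarray(y, dtype=object),
        np.asarray(phases, dtype=object),
        np.asarray(groups),
        np.asarray(t_end),
    )
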
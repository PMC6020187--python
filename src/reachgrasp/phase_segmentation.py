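"""Three-phase segmentation of the reach-to-grasp motion.

The reach is segmented from the elbow angular-velocity profile:

* phase 1 — acceleration: from motion onset (velocity crosses a threshold
  set at 10 % of the subject's maximum angular velocity) to the velocity
  peak;
* phase 2 — deceleration: from the velocity peak until the velocity drops
  back below the threshold (end of the reach);
* phase 3 — post-reach hold: a further 25 % of the reach duration
  (onset to reach end) appended after the reach end.

Time within a trial is expressed as percent of the reaching cycle
(onset = 0 %, reach end = 100 %); values above 100 % refer to phase 3.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .preprocessing import KinematicTrace


class NoMotionError(ValueError):
    """Raised when the angular velocity never exceeds the motion threshold."""


@dataclass
class PhaseBoundaries:
    """Sample indices of the phase boundaries of one trial.

    ``incomplete`` flags trials whose velocity never re-crossed below the
    threshold after the peak (reach end forced to the last sample);
    ``clipped`` flags trials whose 25 % phase-3 extension ran past the end
    of the recording.
    """

    onset_idx: int
    peak_idx: int
    reach_end_idx: int
    phase3_end_idx: int
    v_max: float
    v_threshold: float
    incomplete: bool = False
    clipped: bool = False


def segment_phases(
    kin: KinematicTrace,
    v_max_subject: float | None = None,
    threshold_fraction: float = 0.10,
    phase3_fraction: float = 0.25,
) -> PhaseBoundaries:
    """Locate onset, velocity peak, reach end and phase-3 end.

    Parameters
    ----------
    kin : KinematicTrace
        Elbow kinematics of one trial.
    v_max_subject : float, optional
        The subject's maximum angular velocity (deg/s), normally taken over
        that subject's training trials.  Defaults to this trial's own
        maximum.
    threshold_fraction : float
        The velocity threshold as a fraction of ``v_max_subject``
        (default 0.10).
    phase3_fraction : float
        Length of phase 3 as a fraction of the reach duration
        (default 0.25).

    Notes
    -----
    The crossing samples themselves are included in the reach: onset is the
    first sample with velocity >= threshold and reach end the first sample
    after the peak with velocity <= threshold.
    """
    v = np.asarray(kin.velocity, dtype=float)
    if v_max_subject is None:
        v_max_subject = float(np.max(v)) if v.size else 0.0
    if v_max_subject <= 0:
        raise NoMotionError("no motion detected: non-positive maximum velocity")
    v_threshold = threshold_fraction * v_max_subject

    above = v >= v_threshold
    if not above.any():
        raise NoMotionError("no motion detected: velocity never exceeds threshold")
    onset = int(np.argmax(above))
    peak = onset + int(np.argmax(v[onset:]))

    incomplete = False
    below_after_peak = v[peak + 1 :] <= v_threshold
    if below_after_peak.any():
        reach_end = peak + 1 + int(np.argmax(below_after_peak))
    else:
        reach_end = v.size - 1
        incomplete = True
        warnings.warn("incomplete reach: velocity never re-crossed the threshold")

    phase3_end = reach_end + int(round(phase3_fraction * (reach_end - onset)))
    clipped = False
    if phase3_end > v.size - 1:
        phase3_end = v.size - 1
        clipped = True
        warnings.warn("phase-3 extension truncated at the end of the trial")

    return PhaseBoundaries(
        onset_idx=onset,
        peak_idx=peak,
        reach_end_idx=reach_end,
        phase3_end_idx=phase3_end,
        v_max=float(v_max_subject),
        v_threshold=float(v_threshold),
        incomplete=incomplete,
        clipped=clipped,
    )


def normalize_reach_time(boundaries: PhaseBoundaries, idx: int) -> float:
    """Sample index -> percent of the reaching cycle (onset 0 %, reach end 100 %)."""
    span = boundaries.reach_end_idx - boundaries.onset_idx
    if span <= 0:
        raise ValueError("degenerate reach: reach_end equals onset")
    return 100.0 * (idx - boundaries.onset_idx) / span


def phase_of_sample(boundaries: PhaseBoundaries, idx: int):
    """Phase containing one sample: 'pre', 1, 2, 3 or 'post'.

    Intervals are half-open on the left boundary of the next phase, so the
    peak sample belongs to phase 2 and the reach-end sample to phase 3;
    phase 3 is closed at ``phase3_end_idx``.
    """
    if idx < boundaries.onset_idx:
        return "pre"
    if idx < boundaries.peak_idx:
        return 1
    if idx < boundaries.reach_end_idx:
        return 2
    if idx <= boundaries.phase3_end_idx:
        return 3
    return "post"


def assign_phase(
    boundaries: PhaseBoundaries, window_start_idx: int, window_end_idx: int
):
    """Phase of a sliding window, decided by its final sample (causal rule).

    ``window_end_idx`` is exclusive, matching the (start, end) pairs from
    :func:`reachgrasp.features.sliding_windows`; the final sample is
    ``window_end_idx - 1``.
    """
    if window_start_idx >= window_end_idx:
        raise ValueError("window_start_idx must be < window_end_idx")
    return phase_of_sample(boundaries, window_end_idx - 1)
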
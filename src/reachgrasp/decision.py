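"""Majority-vote decision layer: when is the decoder confident enough to act?

Per-window classifier decisions enter a rolling buffer covering the last
0.5 s (10 votes at the 50 ms cadence).  The majority-vote winner is the
modal class in the buffer; its confidence is the modal count divided by
either the number of votes received so far (``denominator="occupancy"``,
matching "more than half of the votes") or the fixed buffer capacity
(``denominator="capacity"``, which withholds triggering during the first
0.5 s and reflects a deployed controller that waits for a full history).
The grasp command triggers at the first step where confidence strictly
exceeds the threshold (default 0.5); the trigger is immutable afterwards.

Time-to-confidence — the latency from motion onset to the trigger — is the
latency metric for prosthesis activation.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np

from .phase_segmentation import PhaseBoundaries
from .preprocessing import Envelope

DEFAULT_BUFFER_S = 0.5
DEFAULT_CONF_THRESHOLD = 0.5


def majority_vote(
    votes,
    buffer_s: float = DEFAULT_BUFFER_S,
    step_ms: float = 50.0,
    denominator: str = "occupancy",
):
    """Winner and confidence of the most recent votes.

    Only the last ``buffer_s / step_ms`` votes are considered.  Ties are
    broken toward the most recent vote among the tied classes.

    Returns
    -------
    (winner, confidence)
    """
    votes = list(votes)
    if not votes:
        raise ValueError("empty vote buffer")
    capacity = int(round(buffer_s * 1000.0 / step_ms))
    buf = votes[-capacity:]
    counts: dict = {}
    for v in buf:
        counts[v] = counts.get(v, 0) + 1
    top = max(counts.values())
    tied = {c for c, n in counts.items() if n == top}
    if len(tied) == 1:
        winner = tied.pop()
    else:  # most recent vote among the tied classes
        winner = next(v for v in reversed(buf) if v in tied)
    denom = capacity if denominator == "capacity" else len(buf)
    return winner, top / denom


@dataclass
class DecisionTrace:
    """Recorded decision stream of one trial."""

    window_times: np.ndarray  # seconds from trial start (window end)
    window_votes: np.ndarray  # per-window classifier decision
    mv_winner: np.ndarray  # per-step majority-vote winner
    mv_confidence: np.ndarray  # per-step confidence
    trigger_time_s: float | None  # seconds from motion onset, None if no trigger
    trigger_class: object | None
    true_label: object | None = None
    onset_time_s: float = 0.0
    extra: dict = field(default_factory=dict)

    @property
    def triggered(self) -> bool:
        return self.trigger_time_s is not None

    @property
    def correct(self) -> bool:
        return self.triggered and self.trigger_class == self.true_label


def stream_decide(
    model,
    envelope: Envelope,
    boundaries: PhaseBoundaries,
    conf_threshold: float = DEFAULT_CONF_THRESHOLD,
    buffer_s: float = DEFAULT_BUFFER_S,
    denominator: str = "occupancy",
    start_at_onset: bool = True,
    true_label=None,
) -> DecisionTrace:
    """Causally replay a trial through the majority-vote layer.

    Voting starts with the first window that ends at or after the detected
    motion onset (the controller is armed by the goniometer onset), and the
    trigger fires at the first step whose confidence strictly exceeds
    ``conf_threshold``.  ``trigger_time_s`` is measured from motion onset.
    """
    from .classifiers import predict_windows  # local import to avoid cycle

    preds = predict_windows(model, envelope)
    step_ms = model.step_ms
    capacity = int(round(buffer_s * 1000.0 / step_ms))
    onset_t = boundaries.onset_idx / envelope.fs

    times, votes_kept, winners, confidences = [], [], [], []
    buf: deque = deque(maxlen=capacity)
    trigger_time = None
    trigger_class = None
    for (s, e), vote in zip(preds.windows, preds.labels):
        t_end = e / envelope.fs
        if start_at_onset and e - 1 < boundaries.onset_idx:
            continue
        buf.append(vote)
        winner, conf = majority_vote(
            list(buf), buffer_s=buffer_s, step_ms=step_ms,
            denominator=denominator,
        )
        times.append(t_end)
        votes_kept.append(vote)
        winners.append(winner)
        confidences.append(conf)
        if trigger_time is None and conf > conf_threshold:
            trigger_time = t_end - onset_t
            trigger_class = winner
    return DecisionTrace(
        window_times=np.asarray(times),
        window_votes=np.asarray(votes_kept, dtype=object),
        mv_winner=np.asarray(winners, dtype=object),
        mv_confidence=np.asarray(confidences),
        trigger_time_s=trigger_time,
        trigger_class=trigger_class,
        true_label=true_label,
        onset_time_s=onset_t,
    )


@dataclass
class TimeToConfidence:
    """Summary of trigger latencies over a set of traces.

    ``n == 0`` is the explicit empty-result signal: no trace qualified
    (mean and sd are NaN in that case).
    """

    mean_s: float
    sd_s: float
    n: int
    n_no_trigger: int
    n_excluded_incorrect: int
    times_s: np.ndarray


def time_to_confidence(
    traces, correct_only: bool = True
) -> TimeToConfidence:
    """Mean +/- sd trigger latency; non-triggering traces counted separately."""
    times = []
    n_no_trigger = 0
    n_excluded = 0
    for tr in traces:
        if not tr.triggered:
            n_no_trigger += 1
            continue
        if correct_only and tr.trigger_class != tr.true_label:
            n_excluded += 1
            continue
        times.append(tr.trigger_time_s)
    times = np.asarray(times, dtype=float)
    if times.size == 0:
        return TimeToConfidence(
            mean_s=float("nan"), sd_s=float("nan"), n=0,
            n_no_trigger=n_no_trigger, n_excluded_incorrect=n_excluded,
            times_s=times,
        )
    return TimeToConfidence(
        mean_s=float(times.mean()),
        sd_s=float(times.std(ddof=1)) if times.size > 1 else 0.0,
        n=int(times.size),
        n_no_trigger=n_no_trigger,
        n_excluded_incorrect=n_excluded,
        times_s=times,
    )
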
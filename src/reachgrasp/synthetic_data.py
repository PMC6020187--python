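"""Synthetic reach-to-grasp trials with the statistical structure the decoder assumes.

Each generated trial couples a bell-shaped elbow-extension velocity profile
(90 deg -> 180 deg, peak placed at a configurable fraction of the reach,
default 30-45 % as observed in human reaching) with 12 channels of
envelope-level EMG.  The temporal activation profiles follow the two
subject archetypes:

* able-bodied — forearm activity peaks between 20-60 % of the reach and
  decays toward completion; upper-arm activity tracks the velocity bell;
* amputee — forearm activity ramps up gradually through the reach, then
  rises to the grasp squeeze during the post-reach hold; upper-arm
  activity tracks velocity up to the peak and then stays constant.

All profiles ride on a tonic activation level, and trial-to-trial
variability (overall effort, proximal/distal balance, per-channel gains,
slow within-trial effort wander) is modeled explicitly.

Grasp classes differ through per-muscle amplitude modulation: one
signature vector per phase (partially correlated across phases, so the
pattern morphs through the reach), expressed with per-phase strength
(phase 3 > phase 2 > phase 1 by default, zero before motion onset) and
scaled by ``class_separation``.  Setting
``class_separation = 0`` makes all classes identically distributed (a
chance-level control); zero noise with a fixed duration makes classes
perfectly separable.  Envelope-level signals are the default; a raw-EMG
mode emits 30-350 Hz amplitude-modulated noise whose rectified mean equals
the target envelope, to exercise the full pre-processing path.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from scipy import signal as sig

from .preprocessing import MUSCLES_12, Trial, KinematicTrace, save_dataset
from .phase_segmentation import segment_phases

#: The five grasp types of the classification task.
GRASP_TYPES = (
    "precision_disk",
    "palm_pinch",
    "lateral",
    "prismatic_4_fingers",
    "prismatic_2_fingers",
)

#: Default class-drop order for the 4- and 3-class experiments.
CLASS_DROP_ORDER = ("prismatic_2_fingers", "prismatic_4_fingers")


@dataclass
class SynthConfig:
    """Generator configuration.

    Defaults reflect the recorded protocol: 30 trials for each of five
    grasp types (150 trials), 4 s trials at 1000 Hz, self-paced reach
    durations of roughly 1.1 +/- 0.15 s (able-bodied) or 1.4 +/- 0.25 s
    (amputee), and the velocity peak at 30-45 % of the reach.
    ``class_separation`` scales the per-muscle class modulation (1.0 makes
    a 3-class problem solvable at >= 80 % accuracy from phase 2 on);
    ``noise_sd`` is the multiplicative envelope noise (fraction of the
    local amplitude).
    """

    classes: tuple = GRASP_TYPES
    n_trials_per_class: int = 30
    fs: float = 1000.0
    trial_length_s: float = 4.0
    subject: str = "synth01"
    subject_kind: str = "amputee"
    reach_duration_mean_s: float | None = None  # default 1.1 able / 1.4 amputee
    reach_duration_sd_s: float | None = None  # default 0.15 able / 0.25 amputee
    peak_position_range: tuple = (0.30, 0.45)
    class_separation: float = 1.0
    noise_sd: float = 0.35
    additive_noise_sd: float = 0.01
    trial_gain_sd: float = 0.10  # per-trial, per-channel log-normal gain spread
    effort_sd: float = 0.25  # per-trial scalar effort (common across channels)
    group_gain_sd: float = 0.25  # per-trial upper-arm / forearm balance spread
    effort_drift_sd: float = 0.20  # slow (~1.5 Hz) within-trial effort wander
    effort_drift_hz: float = 1.5
    baseline: float = 0.03
    phase_separation_schedule: tuple = (0.35, 0.75, 1.0)
    phase_pattern_correlation: tuple = (0.5, 0.2)  # (phase2-phase3, phase1-phase2)
    class_modulation_scale: float = 0.50
    amplitude_jitter_sd: float = 0.15
    reach_start_s: float = 0.3
    reach_start_jitter_s: float = 0.15
    raw_emg: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.class_separation < 0:
            raise ValueError("class_separation must be >= 0")
        if self.reach_duration_mean_s is None:
            self.reach_duration_mean_s = (
                1.4 if self.subject_kind == "amputee" else 1.1
            )
        if self.reach_duration_sd_s is None:
            self.reach_duration_sd_s = (
                0.25 if self.subject_kind == "amputee" else 0.15
            )
        lo, hi = self.peak_position_range
        if not (0 < lo <= hi < 1):
            raise ValueError("peak_position_range must satisfy 0 < lo <= hi < 1")


# ---------------------------------------------------------------------------
# Kinematics
# ---------------------------------------------------------------------------

def _beta_velocity(n_reach: int, peak_frac: float, kappa: float = 4.0) -> np.ndarray:
    tau = np.linspace(0.0, 1.0, n_reach)
    a = 1.0 + kappa * peak_frac
    b = 1.0 + kappa * (1.0 - peak_frac)
    v = tau ** (a - 1) * (1 - tau) ** (b - 1)
    return v / v.max()


def _measured_peak_frac(v: np.ndarray, threshold_fraction: float = 0.10) -> float:
    thr = threshold_fraction * v.max()
    above = np.flatnonzero(v >= thr)
    onset, end = above[0], above[-1]
    peak = int(np.argmax(v))
    return (peak - onset) / max(end - onset, 1)


def generate_kinematics(
    cfg: SynthConfig,
    duration_s: float,
    peak_frac: float,
    start_s: float | None = None,
    excursion_deg: float = 90.0,
) -> KinematicTrace:
    """Elbow extension 90 deg -> 180 deg along a skewed-bell velocity profile.

    ``peak_frac`` is the requested position of the velocity peak within the
    above-threshold (10 % of max) reach interval; the bell's shape
    parameter is iteratively adjusted so the realized peak lands there.
    """
    if not 0 < peak_frac < 1:
        raise ValueError(f"infeasible peak fraction {peak_frac}")
    start_s = cfg.reach_start_s if start_s is None else start_s
    n_total = int(round(cfg.trial_length_s * cfg.fs))
    n_reach = int(round(duration_s * cfg.fs))
    i0 = int(round(start_s * cfg.fs))
    if n_reach < 10 or i0 + n_reach > n_total:
        raise ValueError(
            f"reach of {duration_s} s starting at {start_s} s does not fit "
            f"a {cfg.trial_length_s} s trial"
        )
    p = peak_frac
    profile = _beta_velocity(n_reach, p)
    for _ in range(4):  # fixed-point correction of the realized peak position
        measured = _measured_peak_frac(profile)
        p = float(np.clip(p + (peak_frac - measured), 0.05, 0.95))
        profile = _beta_velocity(n_reach, p)

    velocity = np.zeros(n_total)
    velocity[i0 : i0 + n_reach] = profile
    velocity *= excursion_deg / np.trapezoid(velocity, dx=1.0 / cfg.fs)
    angle = 90.0 + np.concatenate(
        [[0.0], np.cumsum((velocity[1:] + velocity[:-1]) / 2.0)]
    ) / cfg.fs
    acceleration = np.gradient(velocity) * cfg.fs
    return KinematicTrace(
        angle=angle, velocity=velocity, acceleration=acceleration, fs=cfg.fs
    )


# ---------------------------------------------------------------------------
# EMG
# ---------------------------------------------------------------------------

def _smooth_noise(rng, n, fs, sd, cutoff_hz=15.0):
    """Band-limited Gaussian noise with the requested standard deviation."""
    if sd <= 0:
        return np.zeros(n)
    white = rng.standard_normal(n + 200)
    sos = sig.butter(2, cutoff_hz, btype="low", fs=fs, output="sos")
    smooth = sig.sosfilt(sos, white)[200:]
    s = smooth.std()
    return smooth * (sd / s) if s > 0 else np.zeros(n)


def _logistic(x):
    return 1.0 / (1.0 + np.exp(-x))


def _temporal_gains(cfg: SynthConfig, kin: KinematicTrace, boundaries):
    """Per-channel-group activation gain profiles over the trial."""
    n = kin.velocity.size
    tau = (
        (np.arange(n) - boundaries.onset_idx)
        / max(boundaries.reach_end_idx - boundaries.onset_idx, 1)
    )
    v_norm = kin.velocity / max(kin.velocity.max(), 1e-12)
    # Muscles are never silent during the reach: profiles ride on a tonic
    # level (phantom-limb effort / postural tone), with the phase-dependent
    # component on top.  Pre-onset activity relaxes to a low resting level.
    armed = _logistic(tau * 40.0)  # soft 0 -> 1 step at motion onset
    if cfg.subject_kind == "amputee":
        # forearm: gradual monotone ramp through the reach, then the grasp
        # squeeze itself during the post-reach hold, saturating in phase 3
        ramp = np.clip(tau, 0.0, 1.0)
        squeeze = _logistic((tau - 1.05) / 0.035)
        forearm = 0.15 + armed * (0.20 + 0.25 * ramp + 0.55 * squeeze)
        # upper arm: tonic + velocity-correlated, constant after the peak
        v_held = v_norm.copy()
        v_held[boundaries.peak_idx :] = v_norm[boundaries.peak_idx]
        upper = 0.15 + armed * (0.35 + 0.50 * v_held)
    else:
        # forearm: bump peaking at 20-60 % of the reach, decaying toward the end
        bump = np.exp(-0.5 * ((tau - 0.4) / 0.18) ** 2)
        forearm = 0.15 + armed * (0.15 + 0.70 * bump)
        upper = 0.15 + armed * (0.15 + 0.70 * v_norm)
    return upper, forearm


def _phase_weights(cfg: SynthConfig, n: int, boundaries, fs: float) -> np.ndarray:
    """(3, n) smoothed per-phase indicator weights, scaled by the schedule.

    Weight p at sample t says how strongly phase p's class pattern is
    expressed at t (0 before motion onset); transitions are smoothed over
    100 ms so the expressed pattern morphs continuously between phases.
    """
    sched = cfg.phase_separation_schedule
    w = np.zeros((3, n))
    w[0, boundaries.onset_idx : boundaries.peak_idx] = sched[0]
    w[1, boundaries.peak_idx : boundaries.reach_end_idx] = sched[1]
    w[2, boundaries.reach_end_idx :] = sched[2]
    m = max(1, int(round(0.1 * fs)))
    kernel = np.ones(m) / m
    for p in range(3):
        w[p] = np.convolve(np.pad(w[p], m, mode="edge"), kernel, mode="same")[m:-m]
    return w


def _dataset_params(cfg: SynthConfig, rng):
    """Per-dataset ("per-subject") amplitude templates and class directions.

    Class patterns are drawn per phase: the phase-2 pattern is partially
    correlated with phase 3 (the hand pre-shape converging to its final
    configuration) and phase 1 with phase 2, so each class's per-muscle
    signature morphs across the reach rather than merely growing.
    """
    template = np.concatenate(
        [np.full(7, 0.45), np.full(5, 0.60)]
    ) * np.exp(rng.normal(0.0, cfg.amplitude_jitter_sd, 12))
    k = len(cfg.classes)
    rho23, rho12 = cfg.phase_pattern_correlation

    def unit(v):
        return v / np.linalg.norm(v)

    def orthogonal_unit(v, basis):
        for b in basis:
            v = v - (v @ b) * b
        return unit(v)

    # Phase-3 signatures span a subspace; the phase-2/1 innovations are drawn
    # orthogonal to that whole span, so the correlation between any two
    # classes' *difference* directions across phases is exactly the nominal
    # rho (no dataset-to-dataset fluctuation of the cross-phase geometry).
    d3 = [unit(rng.standard_normal(12)) for _ in range(k)]
    basis3: list[np.ndarray] = []
    for v in d3:
        w = v.copy()
        for b in basis3:
            w = w - (w @ b) * b
        if np.linalg.norm(w) > 1e-9:
            basis3.append(unit(w))
    deltas = np.empty((k, 3, 12))
    for i in range(k):
        e2 = orthogonal_unit(rng.standard_normal(12), basis3)
        g2 = rho23 * d3[i] + np.sqrt(1 - rho23**2) * e2
        e1 = orthogonal_unit(rng.standard_normal(12), basis3)
        g1 = rho12 * g2 + np.sqrt(1 - rho12**2) * e1
        # rows scaled to unit RMS so class_modulation_scale is per-channel
        deltas[i] = np.stack([g1, g2, d3[i]]) * np.sqrt(12)
    return template, deltas


def generate_emg(
    cfg: SynthConfig,
    grasp: str,
    kin: KinematicTrace,
    rng,
    template: np.ndarray,
    deltas: np.ndarray,
) -> np.ndarray:
    """One trial's 12-channel envelope-level EMG for the given grasp class."""
    if grasp not in cfg.classes:
        raise ValueError(f"unknown class {grasp!r}; known: {list(cfg.classes)}")
    k = cfg.classes.index(grasp)
    boundaries = segment_phases(kin)
    n = kin.velocity.size
    upper, forearm = _temporal_gains(cfg, kin, boundaries)
    weights = _phase_weights(cfg, n, boundaries, cfg.fs)

    trial_gain = np.exp(rng.normal(0.0, cfg.trial_gain_sd, 12))
    trial_gain *= np.exp(rng.normal(0.0, cfg.effort_sd))  # overall effort level
    # proximal/distal balance also varies trial to trial
    trial_gain[:7] *= np.exp(rng.normal(0.0, cfg.group_gain_sd))
    trial_gain[7:] *= np.exp(rng.normal(0.0, cfg.group_gain_sd))
    # slow within-trial wander of overall contraction intensity
    effort_drift = np.exp(
        _smooth_noise(rng, n, cfg.fs, cfg.effort_drift_sd, cfg.effort_drift_hz)
    )
    emg = np.empty((12, n))
    for c in range(12):
        gain = upper if c < 7 else forearm
        pattern = weights.T @ deltas[k, :, c]  # (n,) morphing class signature
        modulation = 1.0 + (
            cfg.class_separation * cfg.class_modulation_scale * pattern
        )
        modulation = np.clip(modulation, 0.05, None)
        clean = cfg.baseline + (
            template[c] * trial_gain[c] * effort_drift * gain * modulation
        )
        mult = _smooth_noise(rng, n, cfg.fs, cfg.noise_sd)
        add = _smooth_noise(rng, n, cfg.fs, cfg.additive_noise_sd)
        emg[c] = np.clip(clean * (1.0 + mult) + add, 0.0, None)
    if cfg.raw_emg:
        emg = _amplitude_modulated_raw(emg, cfg.fs, rng)
    return emg


def _amplitude_modulated_raw(envelope: np.ndarray, fs: float, rng) -> np.ndarray:
    """Band-limited (30-350 Hz) carrier noise modulated by the envelope.

    The carrier is scaled so the rectified mean of the output recovers the
    envelope (E|Z| = sigma * sqrt(2/pi) for Gaussian Z).
    """
    sos = sig.butter(4, [30.0, 350.0], btype="band", fs=fs, output="sos")
    out = np.empty_like(envelope)
    for c in range(envelope.shape[0]):
        carrier = sig.sosfilt(sos, rng.standard_normal(envelope.shape[1] + 500))
        carrier = carrier[500:] / carrier[500:].std()
        out[c] = envelope[c] * carrier * np.sqrt(np.pi / 2.0)
    return out


# ---------------------------------------------------------------------------
# Dataset assembly
# ---------------------------------------------------------------------------

def generate_trial(cfg: SynthConfig, grasp: str, rng, template, deltas) -> Trial:
    duration = float(
        np.clip(
            rng.normal(cfg.reach_duration_mean_s, cfg.reach_duration_sd_s),
            0.5,
            cfg.trial_length_s - cfg.reach_start_s - cfg.reach_start_jitter_s - 0.6,
        )
    )
    peak_frac = float(rng.uniform(*cfg.peak_position_range))
    start = cfg.reach_start_s + float(rng.uniform(0, cfg.reach_start_jitter_s))
    kin = generate_kinematics(cfg, duration, peak_frac, start_s=start)
    emg = generate_emg(cfg, grasp, kin, rng, template, deltas)
    return Trial(
        emg=emg,
        angle=kin.angle,
        fs=cfg.fs,
        label=grasp,
        subject=cfg.subject,
        subject_kind=cfg.subject_kind,
        channel_names=list(MUSCLES_12),
    )


def generate_dataset(
    cfg: SynthConfig, out_dir: str | Path | None = None
) -> list[Trial]:
    """All trials of one synthetic subject, reproducible under ``cfg.seed``.

    Trials are generated class-by-class (``n_trials_per_class`` each).  If
    ``out_dir`` is given the trials and a manifest recording the config are
    written in the delimited-text trial format.
    """
    rng = np.random.default_rng(cfg.seed)
    template, deltas = _dataset_params(cfg, rng)
    trials = []
    i = 0
    for grasp in cfg.classes:
        for _ in range(cfg.n_trials_per_class):
            trial = generate_trial(cfg, grasp, rng, template, deltas)
            trial.trial_id = f"trial_{i:03d}"
            trials.append(trial)
            i += 1
    if out_dir is not None:
        config = asdict(cfg)
        config["classes"] = list(cfg.classes)
        save_dataset(trials, out_dir, config=config)
    return trials
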
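"""Experiment orchestration: offline per-phase analysis, accuracy-evolution
curves, muscle-set comparison, online replay, and group statistics.

All experiments share the same pipeline: envelopes are computed per trial,
normalized by the per-channel maxima of the *training* trials, phases are
segmented with the per-subject maximum velocity taken over the training
trials, and the chosen decoder is trained per the classification protocol.
Offline scoring uses the majority-vote output at each 50 ms step (not the
raw window votes); online replay streams each test trial through the
confidence-triggered decision layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .classifiers import (
    ClassifierModel,
    HyperParams,
    TrainTestSplit,
    make_split,
    predict_windows,
    train_esn,
    train_lda,
    train_svm,
)
from .decision import DecisionTrace, TimeToConfidence, majority_vote, stream_decide, time_to_confidence
from .features import extract_features, feature_table
from .phase_analysis import (
    ManovaResult,
    PhaseGmm,
    fit_gmm_bic,
    manova_one_way,
    pca_project,
    phase_means,
    phase_overlap_report,
    phase_window_vectors,
)
from .phase_segmentation import PhaseBoundaries, assign_phase, segment_phases
from .preprocessing import (
    FOREARM_SLICE,
    Envelope,
    Trial,
    compute_envelope,
    differentiate_angle,
    normalize_channels,
    reference_maxima,
)

CLASSIFIER_KINDS = ("lda", "svm_linear", "svm_rbf", "esn")


@dataclass
class ProcessedTrial:
    trial: Trial
    envelope: Envelope  # normalized, channel subset applied
    boundaries: PhaseBoundaries


def _subset_envelope(env: Envelope, muscle_set: str) -> Envelope:
    if muscle_set == "all":
        return env
    if muscle_set != "forearm":
        raise ValueError("muscle_set must be 'all' or 'forearm'")
    if env.n_channels != 12:
        raise ValueError("forearm subset requires the 12-channel montage")
    return Envelope(
        data=env.data[FOREARM_SLICE],
        fs=env.fs,
        normalized=env.normalized,
        norm_constants=(
            env.norm_constants[FOREARM_SLICE]
            if env.norm_constants is not None
            else None
        ),
        channel_names=env.channel_names[FOREARM_SLICE],
    )


def prepare_trials(
    trials: list[Trial],
    split: TrainTestSplit,
    muscle_set: str = "all",
    zero_phase: bool = False,
    normalization: str = "train",
) -> list[ProcessedTrial]:
    """Envelope + kinematics + phase boundaries for every trial.

    Normalization maxima and the per-subject maximum velocity are taken
    over the training trials only (``normalization="train"``, the default)
    or over all trials (``normalization="all"``).
    """
    kins = [differentiate_angle(t.angle, t.fs) for t in trials]
    ref_idx = (
        split.trainval_trials
        if normalization == "train"
        else list(range(len(trials)))
    )
    v_max_subject: dict[str, float] = {}
    for i in ref_idx:
        s = trials[i].subject
        v = float(kins[i].velocity.max())
        v_max_subject[s] = max(v_max_subject.get(s, 0.0), v)
    envelopes = [compute_envelope(t, zero_phase=zero_phase) for t in trials]
    reference = [envelopes[i] for i in ref_idx]
    maxima = reference_maxima(reference)
    processed = []
    for trial, kin, env in zip(trials, kins, envelopes):
        norm = normalize_channels(
            env, [Envelope(data=maxima[:, None], fs=env.fs)]
        )
        boundaries = segment_phases(
            kin, v_max_subject=v_max_subject.get(trial.subject)
        )
        processed.append(
            ProcessedTrial(
                trial=trial,
                envelope=_subset_envelope(norm, muscle_set),
                boundaries=boundaries,
            )
        )
    return processed


def _train_decoder(
    processed: list[ProcessedTrial],
    split: TrainTestSplit,
    classifier_kind: str,
    hp: HyperParams,
    seed: int,
    phase3_only: bool = False,
) -> ClassifierModel:
    train = [processed[i] for i in split.trainval_trials]
    if classifier_kind == "esn":
        if phase3_only:
            seqs = [
                p.envelope.data.T[
                    p.boundaries.reach_end_idx : p.boundaries.phase3_end_idx + 1
                ]
                for p in train
            ]
        else:
            seqs = [p.envelope.data.T for p in train]
        labels = [p.trial.label for p in train]
        return train_esn(seqs, labels, fs=train[0].envelope.fs, hp=hp, seed=seed)

    per_trial = [
        extract_features(p.envelope, p.boundaries, label=p.trial.label)
        for p in train
    ]
    if phase3_only:
        per_trial = [[wf for wf in wfs if wf.phase == 3] for wfs in per_trial]
        if any(len(wfs) == 0 for wfs in per_trial):
            raise ValueError("a training trial has no phase-3 windows")
    X, y, _, groups, _ = feature_table(per_trial)
    if classifier_kind == "lda":
        return train_lda(X, y)
    if classifier_kind in ("svm_linear", "svm_rbf"):
        return train_svm(X, y, groups, classifier_kind.split("_")[1], hp, seed)
    raise ValueError(f"unknown classifier kind {classifier_kind!r}")


# ---------------------------------------------------------------------------
# Offline evaluation
# ---------------------------------------------------------------------------

@dataclass
class ExperimentReport:
    """Per-phase confusions, accuracy-evolution curve and per-trial records.

    Confusion matrices are raw counts (row = ground truth, column =
    prediction); ``confusion_normalized`` divides each row by its count.
    The curve is the mean +/- standard error of majority-vote correctness
    at each 50 ms step after motion onset, padded per trial with its final
    decision state.
    """

    classes: list
    classifier_kind: str
    muscle_set: str
    seed: int
    confusion: dict  # phase -> (k, k) counts
    phase_accuracy: dict  # phase -> float
    curve_times: np.ndarray
    curve_mean: np.ndarray
    curve_se: np.ndarray
    per_trial: list  # dicts: label, per-phase (hits, total), step records
    hyperparams: dict
    model: ClassifierModel | None = None

    @property
    def confusion_normalized(self) -> dict:
        out = {}
        for phase, mat in self.confusion.items():
            rows = mat.sum(axis=1, keepdims=True)
            out[phase] = np.divide(
                mat, rows, out=np.zeros_like(mat, dtype=float), where=rows > 0
            )
        return out


def _mv_steps(model, proc: ProcessedTrial, denominator: str = "occupancy"):
    """Majority-vote winner at each post-onset step with its phase and time."""
    preds = predict_windows(model, proc.envelope)
    buf = []
    steps = []
    for (s, e), vote in zip(preds.windows, preds.labels):
        if e - 1 < proc.boundaries.onset_idx:
            continue
        buf.append(vote)
        winner, conf = majority_vote(
            buf, step_ms=model.step_ms, denominator=denominator
        )
        steps.append(
            {
                "t_rel_s": (e - proc.boundaries.onset_idx) / proc.envelope.fs,
                "phase": assign_phase(proc.boundaries, s, e),
                "winner": winner,
                "confidence": conf,
            }
        )
    return steps


def run_offline(
    trials: list[Trial],
    classifier_kind: str = "svm_rbf",
    classes: list | None = None,
    muscle_set: str = "all",
    hp: HyperParams | None = None,
    seed: int = 0,
    n_test: int = 10,
    n_trainval: int = 20,
    curve_horizon_s: float = 2.0,
    keep_model: bool = False,
) -> ExperimentReport:
    """Train one decoder and score every test window, aggregated by phase and time."""
    hp = hp or HyperParams()
    if classes is not None:
        trials = [t for t in trials if t.label in classes]
        if not trials:
            raise ValueError("class subset left no trials")
    labels = [t.label for t in trials]
    class_list = sorted(set(labels), key=str)
    split = make_split(labels, seed, n_test=n_test, n_trainval=n_trainval)
    processed = prepare_trials(trials, split, muscle_set=muscle_set)
    model = _train_decoder(processed, split, classifier_kind, hp, seed)

    k = len(class_list)
    confusion = {ph: np.zeros((k, k)) for ph in (1, 2, 3)}
    per_trial = []
    step_dt = model.step_ms / 1000.0
    bins = np.arange(step_dt, curve_horizon_s + 1e-9, step_dt)
    curves = []
    for i in split.test_trials:
        proc = processed[i]
        truth = proc.trial.label
        ti = class_list.index(truth)
        steps = _mv_steps(model, proc)
        phase_hits = {ph: [0, 0] for ph in (1, 2, 3)}
        for st in steps:
            if st["phase"] in confusion:
                confusion[st["phase"]][ti, class_list.index(st["winner"])] += 1
                phase_hits[st["phase"]][0] += int(st["winner"] == truth)
                phase_hits[st["phase"]][1] += 1
        t_rel = np.array([st["t_rel_s"] for st in steps])
        correct = np.array([st["winner"] == truth for st in steps], dtype=float)
        pos = np.searchsorted(t_rel, bins + 1e-9) - 1
        pos = np.clip(pos, 0, len(steps) - 1)  # pad both ends with edge state
        curves.append(correct[pos])
        per_trial.append(
            {"label": truth, "phase_hits": phase_hits, "n_steps": len(steps)}
        )
    curves = np.asarray(curves)
    phase_accuracy = {
        ph: float(np.trace(confusion[ph]) / confusion[ph].sum())
        if confusion[ph].sum() > 0
        else float("nan")
        for ph in (1, 2, 3)
    }
    return ExperimentReport(
        classes=class_list,
        classifier_kind=classifier_kind,
        muscle_set=muscle_set,
        seed=seed,
        confusion=confusion,
        phase_accuracy=phase_accuracy,
        curve_times=bins,
        curve_mean=curves.mean(axis=0),
        curve_se=curves.std(axis=0, ddof=1) / np.sqrt(curves.shape[0]),
        per_trial=per_trial,
        hyperparams=dict(model.hyperparams),
        model=model if keep_model else None,
    )


# ---------------------------------------------------------------------------
# Muscle-set comparison
# ---------------------------------------------------------------------------

@dataclass
class MuscleSetComparison:
    report_all: ExperimentReport
    report_forearm: ExperimentReport
    phase_delta: dict  # phase -> accuracy(all) - accuracy(forearm)
    phase_p: dict  # phase -> paired t-test p-value
    phase_t: dict


def _per_trial_phase_accuracy(report: ExperimentReport, phase: int) -> np.ndarray:
    vals = []
    for rec in report.per_trial:
        hits, total = rec["phase_hits"][phase]
        vals.append(hits / total if total else np.nan)
    return np.asarray(vals)


def compare_muscle_sets(
    trials: list[Trial],
    classifier_kind: str = "svm_rbf",
    hp: HyperParams | None = None,
    seed: int = 0,
    **kwargs,
) -> MuscleSetComparison:
    """All-12 vs forearm-5 channels under the identical split and seed."""
    rep_all = run_offline(
        trials, classifier_kind, muscle_set="all", hp=hp, seed=seed, **kwargs
    )
    rep_f = run_offline(
        trials, classifier_kind, muscle_set="forearm", hp=hp, seed=seed, **kwargs
    )
    delta, pvals, tvals = {}, {}, {}
    for ph in (1, 2, 3):
        a = _per_trial_phase_accuracy(rep_all, ph)
        b = _per_trial_phase_accuracy(rep_f, ph)
        ok = ~np.isnan(a) & ~np.isnan(b)
        delta[ph] = float(np.nanmean(a[ok] - b[ok]))
        if np.allclose(a[ok], b[ok]):
            tvals[ph], pvals[ph] = 0.0, 1.0
        else:
            t, p = stats.ttest_rel(a[ok], b[ok])
            tvals[ph], pvals[ph] = float(t), float(p)
    return MuscleSetComparison(
        report_all=rep_all, report_forearm=rep_f,
        phase_delta=delta, phase_p=pvals, phase_t=tvals,
    )


# ---------------------------------------------------------------------------
# Online replay
# ---------------------------------------------------------------------------

@dataclass
class OnlineReport:
    training_mode: str
    traces: list[DecisionTrace]
    correct: np.ndarray  # per test trial (no trigger counts as incorrect)
    accuracy: float
    ttc: TimeToConfidence
    n_no_trigger: int
    seed: int


def run_online_simulation(
    trials: list[Trial],
    training_mode: str = "all_phases",
    classifier_kind: str = "svm_rbf",
    hp: HyperParams | None = None,
    seed: int = 0,
    n_test: int = 10,
    n_trainval: int = 20,
    conf_threshold: float = 0.5,
    denominator: str = "capacity",
    muscle_set: str = "all",
) -> OnlineReport:
    """Stream every test trial through the confidence-triggered decision layer.

    ``training_mode="third_phase_only"`` restricts the training windows to
    phase 3 (the static-posture protocol); ``"all_phases"`` uses the whole
    reach.  The majority-vote confidence uses the fixed buffer capacity as
    its denominator here, reflecting a controller that waits for a full
    0.5 s history before acting.
    """
    if training_mode not in ("all_phases", "third_phase_only"):
        raise ValueError("training_mode must be 'all_phases' or 'third_phase_only'")
    hp = hp or HyperParams()
    labels = [t.label for t in trials]
    split = make_split(labels, seed, n_test=n_test, n_trainval=n_trainval)
    processed = prepare_trials(trials, split, muscle_set=muscle_set)
    model = _train_decoder(
        processed, split, classifier_kind, hp, seed,
        phase3_only=(training_mode == "third_phase_only"),
    )
    traces = []
    for i in split.test_trials:
        proc = processed[i]
        traces.append(
            stream_decide(
                model, proc.envelope, proc.boundaries,
                conf_threshold=conf_threshold, denominator=denominator,
                true_label=proc.trial.label,
            )
        )
    correct = np.asarray([tr.correct for tr in traces], dtype=float)
    ttc = time_to_confidence(traces, correct_only=True)
    return OnlineReport(
        training_mode=training_mode,
        traces=traces,
        correct=correct,
        accuracy=float(correct.mean()),
        ttc=ttc,
        n_no_trigger=sum(not tr.triggered for tr in traces),
        seed=seed,
    )


@dataclass
class OnlineComparison:
    report_all: OnlineReport
    report_third: OnlineReport
    accuracy_t: float
    accuracy_p: float
    time_t: float
    time_p: float


def run_online_comparison(
    trials: list[Trial], seed: int = 0, **kwargs
) -> OnlineComparison:
    """All-phases vs third-phase-only training, identical split, with t-tests."""
    rep_all = run_online_simulation(trials, "all_phases", seed=seed, **kwargs)
    rep_third = run_online_simulation(trials, "third_phase_only", seed=seed, **kwargs)
    acc = compare_conditions(rep_all.correct, rep_third.correct)
    times = compare_conditions(rep_all.ttc.times_s, rep_third.ttc.times_s)
    return OnlineComparison(
        report_all=rep_all,
        report_third=rep_third,
        accuracy_t=acc.statistic,
        accuracy_p=acc.p_value,
        time_t=times.statistic,
        time_p=times.p_value,
    )


# ---------------------------------------------------------------------------
# Group statistics
# ---------------------------------------------------------------------------

@dataclass
class ComparisonResult:
    test: str  # "t" or "anova"
    statistic: float
    p_value: float
    group_means: list


def compare_conditions(*groups) -> ComparisonResult:
    """Two-sample t-test (2 groups) or one-way ANOVA (> 2 groups), alpha 0.05.

    Degenerate variance takes an exact-equality fast path: p = 1 if all
    groups are identical constants, p = 0 if they are distinct constants.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(g.size < 2 for g in groups):
        raise ValueError("need at least 2 samples per group")
    if all(np.ptp(g) == 0 for g in groups):
        means = [float(g.mean()) for g in groups]
        same = all(m == means[0] for m in means)
        return ComparisonResult(
            test="t" if len(groups) == 2 else "anova",
            statistic=0.0 if same else float("inf"),
            p_value=1.0 if same else 0.0,
            group_means=means,
        )
    if len(groups) == 2:
        t, p = stats.ttest_ind(groups[0], groups[1])
        return ComparisonResult(
            "t", float(t), float(p), [float(g.mean()) for g in groups]
        )
    f, p = stats.f_oneway(*groups)
    return ComparisonResult(
        "anova", float(f), float(p), [float(g.mean()) for g in groups]
    )


# ---------------------------------------------------------------------------
# Phase-structure analysis over a dataset
# ---------------------------------------------------------------------------

@dataclass
class PhaseAnalysisReport:
    muscle_set: str
    manova_phases: ManovaResult  # phase factor, classes pooled
    manova_per_class: dict  # label -> ManovaResult
    pca_explained: np.ndarray
    coords: dict  # phase -> (n, 2) projected window vectors
    gmms: dict  # phase -> PhaseGmm
    overlap: np.ndarray  # 3x3 Bhattacharyya overlap (phases 1, 2, 3)


def analyze_phase_structure(
    trials: list[Trial],
    muscle_set: str = "all",
    seed: int = 0,
    k_max: int = 5,
) -> PhaseAnalysisReport:
    """MANOVA across phases, phase-3 PCA projection, per-phase GMMs and overlap.

    Uses all trials as the normalization reference (this is an offline
    descriptive analysis, not a decoding experiment).
    """
    split = TrainTestSplit(
        test_trials=[], trainval_trials=list(range(len(trials))), seed=seed
    )
    processed = prepare_trials(trials, split, muscle_set=muscle_set,
                               normalization="all")
    by_phase_means: dict[int, list] = {1: [], 2: [], 3: []}
    by_phase_class: dict = {}
    by_phase_windows: dict[int, list] = {1: [], 2: [], 3: []}
    for proc in processed:
        pms = phase_means(
            proc.envelope, proc.boundaries, muscle_set="all",
            trial_id=proc.trial.trial_id, label=proc.trial.label,
        )
        for pm in pms:
            by_phase_means[pm.phase].append(pm.means)
            by_phase_class.setdefault(pm.label, {1: [], 2: [], 3: []})[
                pm.phase
            ].append(pm.means)
        wv = phase_window_vectors(proc.envelope, proc.boundaries, muscle_set="all")
        for ph in (1, 2, 3):
            if wv[ph].size:
                by_phase_windows[ph].append(wv[ph])

    manova_phases = manova_one_way(
        [np.asarray(by_phase_means[ph]) for ph in (1, 2, 3)]
    )
    manova_per_class = {
        label: manova_one_way([np.asarray(d[ph]) for ph in (1, 2, 3)])
        for label, d in sorted(by_phase_class.items())
    }
    windows = {ph: np.vstack(by_phase_windows[ph]) for ph in (1, 2, 3)}
    p3_2d, (p1_2d, p2_2d), pca = pca_project(
        windows[3], [windows[1], windows[2]]
    )
    coords = {1: p1_2d, 2: p2_2d, 3: p3_2d}
    gmms = {
        ph: fit_gmm_bic(coords[ph], range(1, k_max + 1), seed=seed, phase=ph)
        for ph in (1, 2, 3)
    }
    overlap = phase_overlap_report([gmms[1], gmms[2], gmms[3]], seed=seed)
    return PhaseAnalysisReport(
        muscle_set=muscle_set,
        manova_phases=manova_phases,
        manova_per_class=manova_per_class,
        pca_explained=pca.explained_variance_ratio_,
        coords=coords,
        gmms=gmms,
        overlap=overlap,
    )


# ---------------------------------------------------------------------------
# Optional figures
# ---------------------------------------------------------------------------

def plot_accuracy_curve(report: ExperimentReport, path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(report.curve_times, report.curve_mean, color="tab:blue")
    ax.fill_between(
        report.curve_times,
        report.curve_mean - report.curve_se,
        report.curve_mean + report.curve_se,
        alpha=0.3,
    )
    ax.axhline(1.0 / len(report.classes), ls="--", c="gray", label="chance")
    ax.set_xlabel("time after motion onset (s)")
    ax.set_ylabel("majority-vote accuracy")
    ax.set_ylim(0, 1.02)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_confusions(report: ExperimentReport, path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    normed = report.confusion_normalized
    fig, axes = plt.subplots(1, 3, figsize=(13, 4))
    for ax, ph in zip(axes, (1, 2, 3)):
        im = ax.imshow(normed[ph], vmin=0, vmax=1, cmap="viridis")
        ax.set_title(f"phase {ph}")
        ax.set_xticks(range(len(report.classes)))
        ax.set_yticks(range(len(report.classes)))
        ax.set_xticklabels(report.classes, rotation=45, ha="right", fontsize=7)
        ax.set_yticklabels(report.classes, fontsize=7)
        ax.set_xlabel("prediction")
    axes[0].set_ylabel("ground truth")
    fig.colorbar(im, ax=axes, shrink=0.8)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
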
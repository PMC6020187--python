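"""The four grasp decoders: LDA, linear SVM, RBF SVM and an echo state network.

Protocol
--------
Per subject, 10 trials per class form the test set and the remaining 20 the
train+validation set; hyper-parameters (SVM ``C``/``gamma``; ESN reservoir
size, spectral radius ``rho`` and ridge ``lambda``) are selected by 4-fold
cross-validation on the train+validation windows and the winning model is
refit on all of them.  Folds are stratified by *trial* (all windows of a
trial stay together) so temporally overlapping windows never leak across
folds.  Grid ties are broken toward the smallest hyper-parameter values.

The LDA and the ESN are implemented here (the ESN readout is a ridge
regression on reservoir states driven directly by the normalized envelopes,
with no feature extraction); the SVMs wrap scikit-learn's SVC with
one-vs-one multiclass handling.
"""

from __future__ import annotations

import pickle
import warnings
from dataclasses import dataclass, field
from itertools import product
from pathlib import Path

import numpy as np
from scipy import linalg
from sklearn.covariance import ledoit_wolf
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .features import (
    DEFAULT_SSC_EPS,
    DEFAULT_STEP_MS,
    DEFAULT_WINDOW_MS,
    extract_features,
    sliding_windows,
)
from .preprocessing import Envelope


@dataclass
class TrainTestSplit:
    """Stratified per-class split of trial indices."""

    test_trials: list[int]
    trainval_trials: list[int]
    seed: int


@dataclass
class HyperParams:
    """Search grids for the grid-searched decoders.

    The defaults span the usual orders of magnitude for EMG pattern
    recognition; :meth:`small` gives a reduced grid for quick experiments.
    """

    svm_C: tuple = (0.01, 0.1, 1.0, 10.0, 100.0)
    svm_gamma: tuple = (1e-3, 1e-2, 1e-1, 1.0, 10.0)
    esn_n_neurons: tuple = (100, 300, 500)
    esn_spectral_radius: tuple = (0.5, 0.8, 0.9, 0.99)
    esn_ridge_lambda: tuple = (1e-6, 1e-4, 1e-2, 1.0)
    cv_folds: int = 4

    def __post_init__(self) -> None:
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        for name in ("svm_C", "svm_gamma", "esn_n_neurons",
                     "esn_spectral_radius", "esn_ridge_lambda"):
            if len(getattr(self, name)) == 0:
                raise ValueError(f"{name} grid is empty")
        if any(r <= 0 for r in self.esn_spectral_radius):
            raise ValueError("spectral radius values must be positive")

    @classmethod
    def small(cls) -> "HyperParams":
        return cls(
            svm_C=(1.0, 10.0),
            svm_gamma=(0.01, 0.1),
            esn_n_neurons=(100,),
            esn_spectral_radius=(0.9,),
            esn_ridge_lambda=(1e-4, 1e-2),
        )


@dataclass
class ClassifierModel:
    """A trained decoder plus the configuration it was trained under."""

    kind: str  # lda | svm_linear | svm_rbf | esn
    impl: object
    classes: list
    n_channels: int
    input_kind: str  # "features" | "envelope"
    n_features: int | None = None
    window_ms: float = DEFAULT_WINDOW_MS
    step_ms: float = DEFAULT_STEP_MS
    eps: float = DEFAULT_SSC_EPS
    hyperparams: dict = field(default_factory=dict)


@dataclass
class WindowPredictions:
    windows: list  # (start, end) pairs
    labels: np.ndarray
    scores: np.ndarray  # (n_windows, n_classes)
    classes: list
    t_end_s: np.ndarray


# ---------------------------------------------------------------------------
# Split and fold construction
# ---------------------------------------------------------------------------

def make_split(
    labels: list, seed: int, n_test: int = 10, n_trainval: int = 20
) -> TrainTestSplit:
    """Random stratified split: ``n_test``/``n_trainval`` trials per class.

    ``labels`` is the grasp label of each trial, in trial order.
    Reproducible under ``seed``.
    """
    labels = np.asarray(labels, dtype=object)
    rng = np.random.default_rng(seed)
    counts = {c: int((labels == c).sum()) for c in sorted(set(labels), key=str)}
    short = {c: n for c, n in counts.items() if n < n_test + n_trainval}
    if short:
        raise ValueError(
            f"need {n_test + n_trainval} trials per class, got {counts}"
        )
    test, trainval = [], []
    for c in sorted(counts, key=str):
        idx = np.flatnonzero(labels == c)
        idx = rng.permutation(idx)
        test.extend(int(i) for i in idx[:n_test])
        trainval.extend(int(i) for i in idx[n_test : n_test + n_trainval])
    return TrainTestSplit(test_trials=sorted(test), trainval_trials=sorted(trainval),
                          seed=seed)


def trial_folds(trial_labels, n_folds: int, seed: int) -> list[np.ndarray]:
    """Class-stratified folds over trials (round-robin within each class)."""
    trial_labels = np.asarray(trial_labels, dtype=object)
    rng = np.random.default_rng(seed)
    folds: list[list[int]] = [[] for _ in range(n_folds)]
    for c in sorted(set(trial_labels), key=str):
        idx = rng.permutation(np.flatnonzero(trial_labels == c))
        if idx.size < n_folds:
            raise ValueError(
                f"class {c!r} has {idx.size} trials, fewer than {n_folds} folds"
            )
        for j, i in enumerate(idx):
            folds[j % n_folds].append(int(i))
    return [np.asarray(sorted(f)) for f in folds]


# ---------------------------------------------------------------------------
# Linear discriminant analysis
# ---------------------------------------------------------------------------

@dataclass
class LdaParams:
    classes: list
    means: np.ndarray  # (k, d)
    covariance: np.ndarray  # (d, d) pooled, possibly shrunk
    priors: np.ndarray  # (k,)
    shrinkage: float


def train_lda(
    X: np.ndarray,
    y,
    shrinkage: str | float | None = "ledoit",
) -> ClassifierModel:
    """Gaussian LDA with pooled covariance and optional shrinkage.

    ``shrinkage="ledoit"`` (default) applies Ledoit-Wolf scalar shrinkage
    toward the identity, estimated from the pooled class residuals; a float
    fixes the shrinkage intensity; ``None`` uses the raw pooled covariance
    and raises if it is singular.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=object)
    classes = sorted(set(y), key=str)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    n, d = X.shape
    means = np.empty((len(classes), d))
    priors = np.empty(len(classes))
    residuals = np.empty_like(X)
    for i, c in enumerate(classes):
        mask = y == c
        if mask.sum() < 2:
            raise ValueError(f"class {c!r} has fewer than 2 samples")
        means[i] = X[mask].mean(axis=0)
        priors[i] = mask.mean()
        residuals[mask] = X[mask] - means[i]
    S = residuals.T @ residuals / max(n - len(classes), 1)

    if shrinkage is None:
        if np.linalg.cond(S) > 1e12:
            raise np.linalg.LinAlgError(
                "singular pooled covariance; enable shrinkage "
                "(shrinkage='ledoit' or a float in (0, 1])"
            )
        cov, delta = S, 0.0
    else:
        if shrinkage == "ledoit":
            _, delta = ledoit_wolf(residuals, assume_centered=True)
        else:
            delta = float(shrinkage)
        mu = np.trace(S) / d
        if mu <= 0:  # zero within-class scatter: fall back to nearest-mean
            mu = 1e-12
            delta = 1.0
        cov = (1 - delta) * S + delta * mu * np.eye(d)

    params = LdaParams(
        classes=classes, means=means, covariance=cov, priors=priors,
        shrinkage=float(delta),
    )
    return ClassifierModel(
        kind="lda", impl=params, classes=classes, n_channels=-1,
        input_kind="features", n_features=d,
        hyperparams={"shrinkage": float(delta)},
    )


def lda_log_posteriors(params: LdaParams, X: np.ndarray) -> np.ndarray:
    """Unnormalized log posteriors log p(x | k) + log prior(k)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    cho = linalg.cho_factor(params.covariance)
    logdet = 2.0 * np.sum(np.log(np.diag(cho[0])))
    d = X.shape[1]
    out = np.empty((X.shape[0], len(params.classes)))
    for i, mu in enumerate(params.means):
        diff = X - mu
        maha = np.sum(diff * linalg.cho_solve(cho, diff.T).T, axis=1)
        out[:, i] = (
            -0.5 * (maha + logdet + d * np.log(2 * np.pi))
            + np.log(params.priors[i])
        )
    return out


def lda_predict_proba(params: LdaParams, X: np.ndarray) -> np.ndarray:
    logpost = lda_log_posteriors(params, X)
    logpost -= logpost.max(axis=1, keepdims=True)
    p = np.exp(logpost)
    return p / p.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# Support vector machines with grid-searched hyper-parameters
# ---------------------------------------------------------------------------

def _cv_window_accuracy(fit_predict, folds, groups, y) -> float:
    """Mean validation-window accuracy over trial-stratified folds."""
    accs = []
    for fold in folds:
        val = np.isin(groups, fold)
        train = ~val
        pred = fit_predict(train, val)
        accs.append(float(np.mean(pred == y[val])))
    return float(np.mean(accs))


def train_svm(
    X: np.ndarray,
    y,
    groups,
    kernel: str,
    hp: HyperParams | None = None,
    seed: int = 0,
) -> ClassifierModel:
    """Grid-searched SVC (one-vs-one); ``kernel`` is 'linear' or 'rbf'.

    The best (C[, gamma]) is the one maximizing mean 4-fold CV window
    accuracy; ties go to the smallest values (grid scanned in ascending
    order, strict improvement required).
    """
    if kernel not in ("linear", "rbf"):
        raise ValueError("kernel must be 'linear' or 'rbf'")
    hp = hp or HyperParams()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=object)
    groups = np.asarray(groups)
    trial_ids = np.unique(groups)
    tlabels = [y[groups == t][0] for t in trial_ids]
    folds_t = trial_folds(tlabels, hp.cv_folds, seed)
    folds = [trial_ids[f] for f in folds_t]

    if kernel == "linear":
        grid = [(c, None) for c in sorted(hp.svm_C)]
    else:
        grid = list(product(sorted(hp.svm_C), sorted(hp.svm_gamma)))

    def make_svc(C, gamma):
        kwargs = {
            "kernel": kernel, "C": C, "cache_size": 256,
            "decision_function_shape": "ovo",
        }
        if gamma is not None:
            kwargs["gamma"] = gamma
        return make_pipeline(StandardScaler(), SVC(**kwargs))

    best, best_acc = None, -np.inf
    for C, gamma in grid:
        def fit_predict(train, val, C=C, gamma=gamma):
            clf = make_svc(C, gamma)
            clf.fit(X[train], y[train].astype(str))
            return clf.predict(X[val]).astype(object)

        acc = _cv_window_accuracy(fit_predict, folds, groups, y)
        if acc > best_acc:  # strict: earlier (smaller) grid points win ties
            best, best_acc = (C, gamma), acc

    C, gamma = best
    clf = make_svc(C, gamma)
    clf.fit(X, y.astype(str))
    classes = sorted(set(y), key=str)
    hyper = {"C": C, "cv_accuracy": best_acc}
    if gamma is not None:
        hyper["gamma"] = gamma
    return ClassifierModel(
        kind=f"svm_{kernel}", impl=clf, classes=classes, n_channels=-1,
        input_kind="features", n_features=X.shape[1], hyperparams=hyper,
    )


def _svc_scores(clf, X: np.ndarray, classes: list) -> np.ndarray:
    """Normalized one-vs-one vote shares (sum to 1; not calibrated posteriors)."""
    dec = clf.decision_function(X)  # OVO pairwise margins
    if dec.ndim == 1:  # binary: single margin
        votes = np.zeros((X.shape[0], 2))
        votes[:, 0] = dec < 0
        votes[:, 1] = dec >= 0
    else:
        k = len(clf.classes_)
        votes = np.zeros((X.shape[0], k))
        col = 0
        for i in range(k):
            for j in range(i + 1, k):
                votes[:, i] += dec[:, col] > 0
                votes[:, j] += dec[:, col] <= 0
                col += 1
    votes += 1e-9
    votes /= votes.sum(axis=1, keepdims=True)
    order = [list(clf.classes_).index(str(c)) for c in classes]
    return votes[:, order]


# ---------------------------------------------------------------------------
# Echo state network
# ---------------------------------------------------------------------------

@dataclass
class Reservoir:
    W: np.ndarray  # (n, n) recurrent weights, rescaled to spectral radius
    W_in: np.ndarray  # (n, input_dim)
    spectral_radius: float
    connectivity: float
    input_scaling: float
    seed: int


def build_reservoir(
    n_neurons: int,
    spectral_radius: float,
    input_dim: int,
    seed: int,
    connectivity: float = 0.1,
    input_scaling: float = 1.0,
) -> Reservoir:
    """Sparse random reservoir rescaled to an exact spectral radius."""
    if spectral_radius <= 0:
        raise ValueError("spectral radius must be positive")
    if not 0 < connectivity <= 1:
        raise ValueError("connectivity must be in (0, 1]")
    rng = np.random.default_rng(seed)
    for attempt in range(10):
        W = rng.uniform(-1, 1, size=(n_neurons, n_neurons))
        W *= rng.random((n_neurons, n_neurons)) < connectivity
        radius = float(np.max(np.abs(np.linalg.eigvals(W))))
        if radius > 0:
            break
        warnings.warn("raw reservoir had zero spectral radius; regenerating")
    else:
        raise RuntimeError("could not generate a reservoir with nonzero radius")
    W *= spectral_radius / radius
    W_in = rng.uniform(-1, 1, size=(n_neurons, input_dim)) * input_scaling
    return Reservoir(
        W=W, W_in=W_in, spectral_radius=spectral_radius,
        connectivity=connectivity, input_scaling=input_scaling, seed=seed,
    )


def esn_states(
    reservoir: Reservoir, inputs: np.ndarray, x0: np.ndarray | None = None
) -> np.ndarray:
    """Run the reservoir: x(t) = tanh(W_in u(t) + W x(t-1)), x(0) = 0."""
    U = np.asarray(inputs, dtype=float)
    if U.ndim != 2 or U.shape[1] != reservoir.W_in.shape[1]:
        raise ValueError(
            f"inputs must be (n_samples, {reservoir.W_in.shape[1]})"
        )
    if not np.isfinite(U).all():
        raise ValueError("non-finite input to the reservoir")
    n = reservoir.W.shape[0]
    x = np.zeros(n) if x0 is None else np.asarray(x0, dtype=float)
    states = np.empty((U.shape[0], n))
    Wt, Wint = reservoir.W.T, reservoir.W_in.T
    for t in range(U.shape[0]):
        x = np.tanh(U[t] @ Wint + x @ Wt)
        states[t] = x
    return states


def _esn_states_batch(reservoir: Reservoir, U: np.ndarray) -> np.ndarray:
    """States for a stack of equal-length trials, advanced in lock-step."""
    B, T, _ = U.shape
    n = reservoir.W.shape[0]
    X = np.zeros((B, n))
    out = np.empty((B, T, n))
    Wt, Wint = reservoir.W.T, reservoir.W_in.T
    for t in range(T):
        X = np.tanh(U[:, t] @ Wint + X @ Wt)
        out[:, t] = X
    return out


def _states_per_trial(reservoir: Reservoir, envelopes: list[np.ndarray]):
    """Group equal-length trials for batched state computation."""
    lengths = {}
    for i, env in enumerate(envelopes):
        lengths.setdefault(env.shape[0], []).append(i)
    states: list[np.ndarray | None] = [None] * len(envelopes)
    for T, idxs in lengths.items():
        batch = np.stack([envelopes[i] for i in idxs])
        S = _esn_states_batch(reservoir, batch)
        for j, i in enumerate(idxs):
            states[i] = S[j]
    return states


@dataclass
class EsnReadout:
    reservoir: Reservoir
    beta: np.ndarray  # (n_neurons + 1, n_classes) ridge readout with bias
    classes: list
    washout: int  # samples discarded from the start of each trial
    ridge_lambda: float


def _ridge_readout(grams, crosses, idxs, lam: float, n: int, k: int) -> np.ndarray:
    G = sum(grams[i] for i in idxs) + lam * np.eye(n + 1)
    C = sum(crosses[i] for i in idxs)
    if lam <= 0:
        if np.linalg.cond(G) > 1e12:
            raise np.linalg.LinAlgError(
                "singular normal equations at lambda=0; use lambda > 0"
            )
    return np.linalg.solve(G, C)


def _window_scores_from_states(states, beta, fs, window_ms, step_ms):
    aug = np.hstack([states, np.ones((states.shape[0], 1))])
    outputs = aug @ beta
    pairs = sliding_windows(states.shape[0], fs, window_ms, step_ms)
    scores = np.stack([outputs[s:e].mean(axis=0) for s, e in pairs])
    return pairs, scores


def train_esn(
    envelopes: list[np.ndarray],
    labels,
    fs: float,
    hp: HyperParams | None = None,
    seed: int = 0,
    washout_ms: float = 100.0,
    connectivity: float = 0.1,
    input_scaling: float = 1.0,
    window_ms: float = DEFAULT_WINDOW_MS,
    step_ms: float = DEFAULT_STEP_MS,
) -> ClassifierModel:
    """Train the ESN decoder on raw (normalized) envelope sequences.

    ``envelopes`` holds one (n_samples, n_channels) array per trial.  The
    readout is a ridge regression from reservoir states to one-hot class
    targets; per-window scores are the mean readout output over the
    window's samples.  Reservoir size, spectral radius and ridge lambda are
    grid-searched with trial-stratified 4-fold CV; states are computed once
    per reservoir and reused across lambdas and folds.
    """
    hp = hp or HyperParams()
    labels = np.asarray(labels, dtype=object)
    classes = sorted(set(labels), key=str)
    k = len(classes)
    d = envelopes[0].shape[1]
    washout = int(round(washout_ms * fs / 1000.0))
    Y_onehot = np.eye(k)[[classes.index(c) for c in labels]]
    folds = trial_folds(labels, hp.cv_folds, seed)

    best = None
    best_acc = -np.inf
    for n_neurons in sorted(hp.esn_n_neurons):
        for rho in sorted(hp.esn_spectral_radius):
            res = build_reservoir(
                n_neurons, rho, input_dim=d, seed=seed,
                connectivity=connectivity, input_scaling=input_scaling,
            )
            states = _states_per_trial(res, envelopes)
            grams, crosses = [], []
            for i, S in enumerate(states):
                Sw = np.hstack(
                    [S[washout:], np.ones((S.shape[0] - washout, 1))]
                )
                grams.append(Sw.T @ Sw)
                crosses.append(Sw.T @ np.tile(Y_onehot[i], (Sw.shape[0], 1)))
            for lam in sorted(hp.esn_ridge_lambda):
                accs = []
                for fold in folds:
                    train_idx = np.setdiff1d(np.arange(len(envelopes)), fold)
                    beta = _ridge_readout(
                        grams, crosses, train_idx, lam, n_neurons, k
                    )
                    hits = total = 0
                    for i in fold:
                        _, scores = _window_scores_from_states(
                            states[i], beta, fs, window_ms, step_ms
                        )
                        pred = np.argmax(scores, axis=1)
                        hits += int(np.sum(pred == classes.index(labels[i])))
                        total += scores.shape[0]
                    accs.append(hits / total)
                acc = float(np.mean(accs))
                if acc > best_acc:
                    best_acc = acc
                    best = (n_neurons, rho, lam, res, grams, crosses)

    n_neurons, rho, lam, res, grams, crosses = best
    beta = _ridge_readout(
        grams, crosses, np.arange(len(envelopes)), lam, n_neurons, k
    )
    readout = EsnReadout(
        reservoir=res, beta=beta, classes=classes, washout=washout,
        ridge_lambda=lam,
    )
    return ClassifierModel(
        kind="esn", impl=readout, classes=classes, n_channels=d,
        input_kind="envelope", window_ms=window_ms, step_ms=step_ms,
        hyperparams={
            "n_neurons": n_neurons, "spectral_radius": rho,
            "ridge_lambda": lam, "cv_accuracy": best_acc,
        },
    )


# ---------------------------------------------------------------------------
# Unified per-window prediction
# ---------------------------------------------------------------------------

def predict_windows(
    model: ClassifierModel, envelope: Envelope
) -> WindowPredictions:
    """Per-window class labels and score vectors for one trial, in time order.

    Deterministic given the model and input; raises on a channel/feature
    configuration mismatch with the model's training fingerprint.
    """
    if model.input_kind == "features":
        wfs = extract_features(
            envelope,
            window_ms=model.window_ms,
            step_ms=model.step_ms,
            eps=model.eps,
            allow_unnormalized=True,
        )
        X = np.stack([wf.features for wf in wfs])
        if X.shape[1] != model.n_features:
            raise ValueError(
                f"feature dimension {X.shape[1]} does not match the model's "
                f"training configuration ({model.n_features})"
            )
        pairs = [(wf.start_idx, wf.end_idx) for wf in wfs]
        if model.kind == "lda":
            scores = lda_predict_proba(model.impl, X)
        else:
            scores = _svc_scores(model.impl, X, model.classes)
        labels = np.asarray(
            [model.classes[i] for i in np.argmax(scores, axis=1)], dtype=object
        )
    elif model.input_kind == "envelope":
        if envelope.n_channels != model.n_channels:
            raise ValueError(
                f"envelope has {envelope.n_channels} channels; model expects "
                f"{model.n_channels}"
            )
        readout: EsnReadout = model.impl
        states = esn_states(readout.reservoir, envelope.data.T)
        pairs, scores = _window_scores_from_states(
            states, readout.beta, envelope.fs, model.window_ms, model.step_ms
        )
        labels = np.asarray(
            [model.classes[i] for i in np.argmax(scores, axis=1)], dtype=object
        )
    else:
        raise ValueError(f"unknown input kind {model.input_kind!r}")
    t_end = np.asarray([e / envelope.fs for _, e in pairs])
    return WindowPredictions(
        windows=pairs, labels=labels, scores=scores, classes=model.classes,
        t_end_s=t_end,
    )


def save_model(model: ClassifierModel, path: str | Path) -> None:
    Path(path).write_bytes(pickle.dumps(model))


def load_model(path: str | Path) -> ClassifierModel:
    return pickle.loads(Path(path).read_bytes())
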
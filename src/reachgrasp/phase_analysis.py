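"""Phase-structure statistics of the muscular activity.

Quantifies how the EMG distribution differs across the three motion phases:
per-phase mean activation vectors, a one-way MANOVA (Wilks' Lambda and
Pillai-Bartlett trace with their standard F approximations), a PCA fitted
on phase-3 data with phases 1-2 projected into the same plane, and per-phase
Gaussian mixture models whose component count is selected by BIC.  Both the
complete 12-muscle set and the 5 forearm muscles are supported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.mixture import GaussianMixture

from .features import DEFAULT_STEP_MS, DEFAULT_WINDOW_MS, sliding_windows
from .phase_segmentation import PhaseBoundaries, assign_phase
from .preprocessing import FOREARM_SLICE, Envelope


def _muscle_indices(muscle_set: str, n_channels: int) -> np.ndarray:
    if muscle_set == "all":
        return np.arange(n_channels)
    if muscle_set == "forearm":
        if n_channels != 12:
            raise ValueError("forearm subset requires the 12-channel montage")
        return np.arange(12)[FOREARM_SLICE]
    raise ValueError("muscle_set must be 'all' or 'forearm'")


@dataclass
class PhaseMeanVector:
    trial_id: str
    phase: int
    means: np.ndarray  # (N,) per-channel average envelope over the phase
    label: str | None = None


def phase_means(
    envelope: Envelope,
    boundaries: PhaseBoundaries,
    muscle_set: str = "all",
    trial_id: str = "",
    label: str | None = None,
) -> list[PhaseMeanVector]:
    """Per-channel time-average of the envelope over each of the three phases."""
    idx = _muscle_indices(muscle_set, envelope.n_channels)
    intervals = {
        1: (boundaries.onset_idx, boundaries.peak_idx),
        2: (boundaries.peak_idx, boundaries.reach_end_idx),
        3: (boundaries.reach_end_idx, boundaries.phase3_end_idx + 1),
    }
    out = []
    for phase, (s, e) in intervals.items():
        if e <= s:
            raise ValueError(f"phase {phase} interval is empty ({s}, {e})")
        out.append(
            PhaseMeanVector(
                trial_id=trial_id, phase=phase,
                means=envelope.data[idx, s:e].mean(axis=1), label=label,
            )
        )
    return out


# ---------------------------------------------------------------------------
# One-way MANOVA
# ---------------------------------------------------------------------------

@dataclass
class ManovaResult:
    wilks_lambda: float
    pillai_trace: float
    wilks_F: float
    wilks_df: tuple[float, float]
    wilks_p: float
    pillai_F: float
    pillai_df: tuple[float, float]
    pillai_p: float
    n_groups: int
    n_total: int
    dim: int

    def significant(self, alpha: float = 0.05) -> bool:
        return self.wilks_p < alpha


def manova_one_way(groups) -> ManovaResult:
    """One-way MANOVA from the within/between scatter matrices.

    ``groups`` is a sequence of (n_g, p) arrays.  Wilks' Lambda is
    det(E)/det(E+H) and the Pillai-Bartlett trace tr(H (H+E)^-1), with E
    the pooled within-group scatter and H the between-group scatter; both
    are converted to F statistics with the standard approximations (Rao's
    for Wilks, exact when min(p, g-1) <= 2).
    """
    groups = [np.atleast_2d(np.asarray(g, dtype=float)) for g in groups]
    g = len(groups)
    if g < 2:
        raise ValueError("need at least 2 groups")
    p = groups[0].shape[1]
    if any(grp.shape[1] != p for grp in groups):
        raise ValueError("groups must share dimensionality")
    n = sum(grp.shape[0] for grp in groups)
    if n <= p + g:
        raise ValueError(
            f"need more than dim + n_groups = {p + g} samples in total, got {n}"
        )
    grand = np.vstack(groups).mean(axis=0)
    H = np.zeros((p, p))
    E = np.zeros((p, p))
    for grp in groups:
        m = grp.mean(axis=0)
        d = (m - grand)[:, None]
        H += grp.shape[0] * (d @ d.T)
        r = grp - m
        E += r.T @ r
    sign, logdet_E = np.linalg.slogdet(E)
    if sign <= 0:
        raise np.linalg.LinAlgError(
            "singular within-group scatter; reduce dimensionality or add samples"
        )
    _, logdet_T = np.linalg.slogdet(E + H)
    wilks = float(np.exp(logdet_E - logdet_T))
    pillai = float(np.trace(H @ np.linalg.inv(H + E)))

    q = g - 1
    # Rao's F approximation for Wilks' Lambda
    denom = p**2 + q**2 - 5
    t = np.sqrt((p**2 * q**2 - 4) / denom) if denom > 0 else 1.0
    w = n - g - (p - q + 1) / 2.0
    df1_w = p * q
    df2_w = w * t - (p * q - 2) / 2.0
    lam_t = wilks ** (1.0 / t)
    wilks_F = (1 - lam_t) / lam_t * df2_w / df1_w if lam_t > 0 else np.inf
    wilks_p = float(stats.f.sf(wilks_F, df1_w, df2_w))

    s = min(p, q)
    m = (abs(p - q) - 1) / 2.0
    nn = (n - g - p - 1) / 2.0
    df1_p = s * (2 * m + s + 1)
    df2_p = s * (2 * nn + s + 1)
    if pillai >= s:  # perfect separation
        pillai_F = np.inf
        pillai_p = 0.0
    else:
        pillai_F = (2 * nn + s + 1) / (2 * m + s + 1) * pillai / (s - pillai)
        pillai_p = float(stats.f.sf(pillai_F, df1_p, df2_p))

    return ManovaResult(
        wilks_lambda=wilks,
        pillai_trace=pillai,
        wilks_F=float(wilks_F),
        wilks_df=(df1_w, df2_w),
        wilks_p=wilks_p,
        pillai_F=float(pillai_F),
        pillai_df=(df1_p, df2_p),
        pillai_p=pillai_p,
        n_groups=g,
        n_total=n,
        dim=p,
    )


# ---------------------------------------------------------------------------
# PCA on phase 3 + projection of phases 1-2
# ---------------------------------------------------------------------------

def pca_project(phase3_vectors: np.ndarray, other_vectors):
    """Fit a 2-component PCA on phase-3 vectors; project everything into it.

    Centering uses the phase-3 mean for all phases, so the phase-3 cloud is
    centered at the origin.  Returns ``(phase3_2d, [others_2d...], pca)``.
    """
    phase3_vectors = np.asarray(phase3_vectors, dtype=float)
    if phase3_vectors.shape[0] < 3:
        raise ValueError("need at least 3 phase-3 samples")
    centered = phase3_vectors - phase3_vectors.mean(axis=0)
    if np.linalg.matrix_rank(centered) < 2:
        raise ValueError("phase-3 data has fewer than 2 non-degenerate directions")
    pca = PCA(n_components=2)
    phase3_2d = pca.fit_transform(phase3_vectors)
    others_2d = [
        pca.transform(np.asarray(v, dtype=float)) for v in other_vectors
    ]
    return phase3_2d, others_2d, pca


def phase_window_vectors(
    envelope: Envelope,
    boundaries: PhaseBoundaries,
    muscle_set: str = "all",
    window_ms: float = DEFAULT_WINDOW_MS,
    step_ms: float = DEFAULT_STEP_MS,
) -> dict[int, np.ndarray]:
    """Sliding-window mean-activation vectors per phase (1, 2, 3).

    The signal is first cut at the phase boundaries and windows slide
    within each phase interval, so no window mixes samples of two phases.
    Phases shorter than one window contribute no vectors.
    """
    idx = _muscle_indices(muscle_set, envelope.n_channels)
    intervals = {
        1: (boundaries.onset_idx, boundaries.peak_idx),
        2: (boundaries.peak_idx, boundaries.reach_end_idx),
        3: (boundaries.reach_end_idx, boundaries.phase3_end_idx + 1),
    }
    out: dict[int, list] = {1: [], 2: [], 3: []}
    w = int(round(window_ms * envelope.fs / 1000.0))
    for ph, (a, b) in intervals.items():
        if b - a < w:
            continue
        for s, e in sliding_windows(b - a, envelope.fs, window_ms, step_ms):
            out[ph].append(envelope.data[idx, a + s : a + e].mean(axis=1))
    return {ph: np.asarray(v) for ph, v in out.items()}


# ---------------------------------------------------------------------------
# Per-phase GMMs with BIC-selected component count
# ---------------------------------------------------------------------------

@dataclass
class PhaseGmm:
    phase: int | None
    n_components: int
    weights: np.ndarray
    means: np.ndarray
    covariances: np.ndarray
    bic_curve: dict = field(default_factory=dict)
    model: GaussianMixture | None = None


def fit_gmm_bic(
    points: np.ndarray,
    k_candidates=range(1, 6),
    seed: int = 0,
    n_restarts: int = 10,
    phase: int | None = None,
    reg_covar: float = 1e-6,
) -> PhaseGmm:
    """EM fits over candidate component counts; keep the minimum-BIC model.

    Ties in BIC go to the smaller k.  ``reg_covar`` floors the covariance
    diagonals against collapsing components.
    """
    points = np.asarray(points, dtype=float)
    bic_curve = {}
    best = None
    best_k = None
    for k in k_candidates:
        gm = GaussianMixture(
            n_components=k, covariance_type="full", n_init=n_restarts,
            random_state=seed, reg_covar=reg_covar,
        )
        gm.fit(points)
        bic_curve[k] = float(gm.bic(points))
        if best is None or bic_curve[k] < bic_curve[best_k]:
            best, best_k = gm, k
    return PhaseGmm(
        phase=phase,
        n_components=best_k,
        weights=best.weights_,
        means=best.means_,
        covariances=best.covariances_,
        bic_curve=bic_curve,
        model=best,
    )


def phase_overlap_report(
    gmms, n_samples: int = 4000, seed: int = 0
) -> np.ndarray:
    """Pairwise Bhattacharyya-coefficient overlap between phase mixtures.

    Estimated by Monte-Carlo: BC(p, q) = E_p[sqrt(q/p)] averaged
    symmetrically with E_q[sqrt(p/q)].  1 for identical mixtures, -> 0 for
    well-separated ones.
    """
    models = [g.model for g in gmms]
    if any(m is None for m in models):
        raise ValueError("PhaseGmm objects must carry their fitted model")
    k = len(models)
    out = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            vals = []
            for a, b in ((models[i], models[j]), (models[j], models[i])):
                X, _ = a.sample(n_samples)
                log_a = a.score_samples(X)
                log_b = b.score_samples(X)
                vals.append(np.mean(np.exp(0.5 * (log_b - log_a))))
            out[i, j] = out[j, i] = float(np.clip(np.mean(vals), 0.0, 1.0))
    return out
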
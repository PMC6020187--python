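import numpy as np
import pytest

from reachgrasp import (
    fit_gmm_bic,
    manova_one_way,
    pca_project,
    phase_means,
    phase_overlap_report,
    phase_window_vectors,
)
from reachgrasp.phase_segmentation import PhaseBoundaries
from reachgrasp.preprocessing import Envelope


def boundaries():
    return PhaseBoundaries(
        onset_idx=100, peak_idx=400, reach_end_idx=800, phase3_end_idx=999,
        v_max=100.0, v_threshold=10.0,
    )


class TestPhaseMeans:
    def test_constant_envelope(self):
        env = Envelope(data=np.full((12, 1200), 0.3), fs=1000.0, normalized=True)
        pms = phase_means(env, boundaries())
        assert [pm.phase for pm in pms] == [1, 2, 3]
        for pm in pms:
            np.testing.assert_allclose(pm.means, 0.3)
            assert pm.means.shape == (12,)

    def test_forearm_subset_has_5_channels(self):
        env = Envelope(data=np.random.default_rng(0).random((12, 1200)),
                       fs=1000.0, normalized=True)
        pms = phase_means(env, boundaries(), muscle_set="forearm")
        assert pms[0].means.shape == (5,)

    def test_step_envelope(self):
        data = np.zeros((2, 1200))
        data[:, 400:] = 1.0  # 0 through phase 1, 1 in phases 2-3
        env = Envelope(data=data, fs=1000.0, normalized=True)
        pms = phase_means(env, boundaries())
        np.testing.assert_allclose(pms[0].means, 0.0)
        np.testing.assert_allclose(pms[1].means, 1.0)
        np.testing.assert_allclose(pms[2].means, 1.0)

    def test_empty_phase_raises(self):
        b = boundaries()
        b.peak_idx = b.onset_idx
        env = Envelope(data=np.ones((2, 1200)), fs=1000.0, normalized=True)
        with pytest.raises(ValueError, match="phase 1"):
            phase_means(env, b)


class TestManova:
    def test_identical_groups(self, rng):
        g = rng.standard_normal((30, 4))
        res = manova_one_way([g, g.copy(), g.copy()])
        assert res.wilks_lambda == pytest.approx(1.0)
        assert res.pillai_trace == pytest.approx(0.0, abs=1e-12)
        assert res.wilks_p == pytest.approx(1.0)

    def test_1d_wilks_F_equals_anova_F(self, rng):
        from scipy.stats import f_oneway

        groups = [rng.normal(m, 1.0, (25, 1)) for m in (0.0, 0.5, 1.0)]
        res = manova_one_way(groups)
        F, p = f_oneway(*[g[:, 0] for g in groups])
        assert res.wilks_F == pytest.approx(F, rel=1e-10)
        assert res.wilks_p == pytest.approx(p, rel=1e-8)

    def test_matches_statsmodels(self, rng):
        from statsmodels.multivariate.manova import MANOVA

        groups = [rng.normal(m, 1.0, (20, 3)) for m in (0.0, 0.3, 0.6)]
        res = manova_one_way(groups)
        X = np.vstack(groups)
        labels = np.repeat(["a", "b", "c"], 20)
        sm = MANOVA(X, np.array(
            [[1.0, g == "b", g == "c"] for g in labels], dtype=float
        ))
        tab = sm.mv_test(
            [("group", np.array([[0.0, 1, 0], [0, 0, 1]]))]
        ).results["group"]["stat"]
        assert res.wilks_lambda == pytest.approx(
            tab.loc["Wilks' lambda", "Value"], rel=1e-8
        )
        assert res.pillai_trace == pytest.approx(
            tab.loc["Pillai's trace", "Value"], rel=1e-8
        )
        assert res.wilks_F == pytest.approx(
            tab.loc["Wilks' lambda", "F Value"], rel=1e-6
        )
        assert res.pillai_F == pytest.approx(
            tab.loc["Pillai's trace", "F Value"], rel=1e-6
        )

    def test_affine_invariance(self, rng):
        groups = [rng.normal(m, 1.0, (20, 3)) for m in (0.0, 0.5, 1.0)]
        res1 = manova_one_way(groups)
        A = rng.standard_normal((3, 3)) + 3 * np.eye(3)
        b = rng.standard_normal(3)
        res2 = manova_one_way([g @ A.T + b for g in groups])
        assert res1.wilks_lambda == pytest.approx(res2.wilks_lambda, rel=1e-8)
        assert res1.pillai_trace == pytest.approx(res2.pillai_trace, rel=1e-8)

    def test_singular_scatter_raises(self):
        g = np.zeros((10, 3))
        with pytest.raises(np.linalg.LinAlgError):
            manova_one_way([g, g + 1.0, g + 2.0])


class TestPcaProject:
    def test_axis_aligned_recovered_up_to_sign(self, rng):
        pts = np.zeros((100, 4))
        pts[:, 0] = rng.normal(0, 5, 100)
        pts[:, 1] = rng.normal(0, 1, 100)
        p3, others, _ = pca_project(pts, [])
        corr = np.corrcoef(np.abs(p3[:, 0]), np.abs(pts[:, 0]))[0, 1]
        assert corr > 0.99

    def test_phase3_mean_maps_to_origin(self, rng):
        pts = rng.standard_normal((50, 3)) + 5
        _, others, _ = pca_project(pts, [pts.mean(axis=0, keepdims=True)])
        np.testing.assert_allclose(others[0], 0.0, atol=1e-10)

    def test_pc1_variance_dominates(self, rng):
        pts = rng.standard_normal((200, 5)) * np.array([3, 1, 1, 1, 1])
        p3, _, _ = pca_project(pts, [])
        assert p3[:, 0].var() >= p3[:, 1].var()

    def test_degenerate_data_raises(self):
        pts = np.tile([1.0, 2.0, 3.0], (10, 1))
        with pytest.raises(ValueError):
            pca_project(pts, [])


class TestGmmBic:
    def test_single_cluster_selects_k1(self, rng):
        pts = rng.standard_normal((500, 2))
        out = fit_gmm_bic(pts, range(1, 6), seed=0)
        assert out.n_components == 1
        assert out.weights.sum() == pytest.approx(1.0)

    def test_two_far_clusters_select_k2(self, rng):
        pts = np.vstack([
            rng.standard_normal((250, 2)),
            rng.standard_normal((250, 2)) + [10, 0],
        ])
        out = fit_gmm_bic(pts, range(1, 6), seed=0)
        assert out.n_components == 2
        assert out.n_components == min(out.bic_curve, key=out.bic_curve.get)

    def test_covariances_positive_definite(self, rng):
        pts = rng.standard_normal((300, 2))
        out = fit_gmm_bic(pts, range(1, 4), seed=1)
        for cov in out.covariances:
            assert np.all(np.linalg.eigvalsh(cov) > 0)


class TestOverlap:
    def _gmm(self, shift, rng):
        pts = rng.standard_normal((400, 2)) + shift
        return fit_gmm_bic(pts, [1, 2], seed=0)

    def test_identical_mixture_overlap_one(self, rng):
        g = self._gmm(0.0, rng)
        out = phase_overlap_report([g, g])
        assert out[0, 1] == pytest.approx(1.0, abs=0.05)

    def test_far_mixtures_near_zero(self, rng):
        a = self._gmm(0.0, rng)
        b = self._gmm(20.0, rng)
        out = phase_overlap_report([a, b])
        assert out[0, 1] < 0.01

    def test_symmetric_within_mc_tolerance(self, rng):
        a = self._gmm(0.0, rng)
        b = self._gmm(1.5, rng)
        # estimate the two Monte-Carlo directions independently
        Xa, _ = a.model.sample(4000)
        Xb, _ = b.model.sample(4000)
        ab = np.mean(np.exp(0.5 * (b.model.score_samples(Xa)
                                   - a.model.score_samples(Xa))))
        ba = np.mean(np.exp(0.5 * (a.model.score_samples(Xb)
                                   - b.model.score_samples(Xb))))
        assert ab == pytest.approx(ba, abs=0.1)


def test_phase_window_vectors_are_phase_pure(rng):
    data = np.zeros((2, 1200))
    data[:, :400] = 0.1   # through phase 1 (ends at peak 400)
    data[:, 400:800] = 0.5
    data[:, 800:] = 0.9
    env = Envelope(data=data, fs=1000.0, normalized=True)
    out = phase_window_vectors(env, boundaries())
    np.testing.assert_allclose(out[1], 0.1)
    np.testing.assert_allclose(out[2], 0.5)
    np.testing.assert_allclose(out[3], 0.9)


def test_phase3_separates_in_weak_separation_regime():
    """With weak class modulation (the regime matching recorded-data accuracy
    levels), the post-reach phase's mixture overlaps the two reaching phases
    less than they overlap each other."""
    from reachgrasp import SynthConfig, analyze_phase_structure, generate_dataset

    cfg = SynthConfig(seed=1, class_separation=0.3, effort_sd=0.1,
                      effort_drift_sd=0.1, trial_gain_sd=0.05, noise_sd=0.2)
    rep = analyze_phase_structure(generate_dataset(cfg), seed=0)
    o = rep.overlap
    assert o[0, 1] > max(o[0, 2], o[1, 2])
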
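import numpy as np
import pytest
from scipy.stats import multivariate_normal

from reachgrasp import (
    HyperParams,
    build_reservoir,
    esn_states,
    make_split,
    predict_windows,
    train_esn,
    train_lda,
    train_svm,
)
from reachgrasp.classifiers import (
    lda_predict_proba,
    load_model,
    save_model,
    trial_folds,
)
from reachgrasp.preprocessing import Envelope


class TestMakeSplit:
    def test_default_protocol_counts(self):
        labels = [c for c in "abcde" for _ in range(30)]
        split = make_split(labels, seed=0)
        assert len(split.test_trials) == 50
        assert len(split.trainval_trials) == 100
        assert not set(split.test_trials) & set(split.trainval_trials)

    def test_same_seed_identical(self):
        labels = [c for c in "ab" for _ in range(30)]
        s1, s2 = make_split(labels, 3), make_split(labels, 3)
        assert s1.test_trials == s2.test_trials
        assert s1.trainval_trials == s2.trainval_trials

    def test_insufficient_trials_lists_counts(self):
        labels = ["a"] * 30 + ["b"] * 25
        with pytest.raises(ValueError, match="'b': 25"):
            make_split(labels, 0)

    def test_stratified(self):
        labels = [c for c in "ab" for _ in range(30)]
        split = make_split(labels, 1, n_test=5, n_trainval=10)
        test_labels = [labels[i] for i in split.test_trials]
        assert test_labels.count("a") == 5 and test_labels.count("b") == 5


class TestTrialFolds:
    def test_each_fold_has_every_class(self):
        labels = [c for c in "abc" for _ in range(8)]
        folds = trial_folds(labels, 4, seed=0)
        for f in folds:
            assert {labels[i] for i in f} == {"a", "b", "c"}

    def test_too_few_trials_per_class(self):
        with pytest.raises(ValueError):
            trial_folds(["a"] * 3 + ["b"] * 8, 4, seed=0)


class TestLda:
    def test_1d_symmetric_boundary_at_zero(self, rng):
        x = np.concatenate([rng.normal(-1, 0.3, 50), rng.normal(1, 0.3, 50)])
        y = ["neg"] * 50 + ["pos"] * 50
        model = train_lda(x[:, None], y)
        p = lda_predict_proba(model.impl, np.array([[-0.05], [0.05]]))
        assert p[0, 0] > 0.5 and p[1, 1] > 0.5
        np.testing.assert_allclose(model.impl.priors, [0.5, 0.5])

    def test_well_separated_gaussians(self, rng):
        mu = np.array([[0.0, 0.0], [10.0, 0.0]])  # 10 sigma apart
        X = np.vstack([rng.normal(m, 1.0, (200, 2)) for m in mu])
        y = ["a"] * 200 + ["b"] * 200
        Xt = np.vstack([rng.normal(m, 1.0, (100, 2)) for m in mu])
        yt = np.array(["a"] * 100 + ["b"] * 100, dtype=object)
        model = train_lda(X, y)
        pred = np.array(model.impl.classes, dtype=object)[
            np.argmax(lda_predict_proba(model.impl, Xt), axis=1)
        ]
        assert (pred == yt).mean() >= 0.99

    def test_posteriors_match_density_ratio_oracle(self, rng):
        # brute-force Bayes rule through scipy densities, shared covariance
        X = rng.standard_normal((40, 3))
        y = np.array(["a", "b"] * 20, dtype=object)
        model = train_lda(X, y, shrinkage=0.1)
        p = model.impl
        dens = np.stack(
            [
                multivariate_normal.pdf(X, mean=m, cov=p.covariance)
                for m in p.means
            ],
            axis=1,
        )
        post = dens * p.priors
        post /= post.sum(axis=1, keepdims=True)
        np.testing.assert_allclose(lda_predict_proba(p, X), post, atol=1e-8)

    def test_matches_sklearn_lda(self, rng):
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        X = rng.standard_normal((120, 4))
        X[:60] += 1.5
        y = np.array(["a"] * 60 + ["b"] * 60, dtype=object)
        mine = train_lda(X, y, shrinkage=None)
        ref = LinearDiscriminantAnalysis(solver="svd").fit(X, y.astype(str))
        np.testing.assert_allclose(
            lda_predict_proba(mine.impl, X), ref.predict_proba(X), atol=1e-6
        )

    def test_singular_covariance_without_shrinkage(self):
        X = np.zeros((20, 3))
        X[10:, 0] = 1.0
        y = ["a"] * 10 + ["b"] * 10
        with pytest.raises(np.linalg.LinAlgError, match="shrinkage"):
            train_lda(X, y, shrinkage=None)


def _grouped(X, y, trials_of=5):
    groups = np.repeat(np.arange(len(y) // trials_of), trials_of)
    return groups


class TestSvm:
    def test_separable_ties_break_to_smallest_C(self, rng):
        X = np.vstack([rng.normal(-5, 0.1, (40, 2)), rng.normal(5, 0.1, (40, 2))])
        y = np.array(["a"] * 40 + ["b"] * 40, dtype=object)
        groups = np.repeat(np.arange(16), 5)
        hp = HyperParams(svm_C=(0.1, 1.0, 10.0))
        model = train_svm(X, y, groups, "linear", hp, seed=0)
        assert model.hyperparams["C"] == 0.1
        assert model.hyperparams["cv_accuracy"] == 1.0

    def test_rbf_beats_linear_on_xor(self, rng):
        centers = np.array([[0, 0], [1, 1], [0, 1], [1, 0]], float) * 4
        X = np.vstack([rng.normal(c, 0.3, (30, 2)) for c in centers])
        y = np.array(["a"] * 60 + ["b"] * 60, dtype=object)
        groups = np.repeat(np.arange(24), 5)
        hp = HyperParams(svm_C=(1.0, 10.0), svm_gamma=(0.1, 1.0))
        lin = train_svm(X, y, groups, "linear", hp, seed=0)
        rbf = train_svm(X, y, groups, "rbf", hp, seed=0)
        assert rbf.hyperparams["cv_accuracy"] > lin.hyperparams["cv_accuracy"] + 0.2

    def test_single_grid_point_selected(self, rng):
        X = rng.standard_normal((40, 2))
        X[20:] += 3
        y = np.array(["a"] * 20 + ["b"] * 20, dtype=object)
        groups = np.repeat(np.arange(8), 5)
        hp = HyperParams(svm_C=(7.0,), svm_gamma=(0.2,))
        model = train_svm(X, y, groups, "rbf", hp, seed=0)
        assert model.hyperparams == {
            "C": 7.0, "gamma": 0.2,
            "cv_accuracy": model.hyperparams["cv_accuracy"],
        }

    def test_invalid_kernel(self):
        with pytest.raises(ValueError):
            train_svm(np.zeros((4, 2)), ["a", "a", "b", "b"], [0, 0, 1, 1],
                      "poly", None, 0)


class TestReservoir:
    def test_spectral_radius_exact(self):
        res = build_reservoir(80, 0.9, input_dim=3, seed=0)
        radius = np.max(np.abs(np.linalg.eigvals(res.W)))
        assert radius == pytest.approx(0.9, abs=1e-9)

    def test_same_seed_identical(self):
        a = build_reservoir(50, 0.8, input_dim=2, seed=42)
        b = build_reservoir(50, 0.8, input_dim=2, seed=42)
        np.testing.assert_array_equal(a.W, b.W)
        np.testing.assert_array_equal(a.W_in, b.W_in)

    def test_connectivity_nonzero_count(self):
        counts = [
            np.count_nonzero(build_reservoir(100, 0.9, 1, seed=s,
                                             connectivity=0.1).W)
            for s in range(5)
        ]
        # binomial(10000, 0.1): mean 1000, sd ~30
        assert 850 < np.mean(counts) < 1150

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            build_reservoir(10, 0.0, input_dim=1, seed=0)
        with pytest.raises(ValueError):
            build_reservoir(10, 0.9, input_dim=1, seed=0, connectivity=1.5)


class TestEsnStates:
    def test_zero_input_zero_state(self):
        res = build_reservoir(40, 0.9, input_dim=2, seed=1)
        states = esn_states(res, np.zeros((100, 2)))
        assert np.allclose(states, 0.0)

    def test_fading_memory_at_rho_09(self, rng):
        res = build_reservoir(100, 0.9, input_dim=2, seed=3)
        u = rng.standard_normal((800, 2))
        s1 = esn_states(res, u, x0=np.zeros(100))
        s2 = esn_states(res, u, x0=rng.uniform(-1, 1, 100))
        dist = np.linalg.norm(s1 - s2, axis=1)
        assert dist[-1] < 1e-6

    def test_no_contraction_guarantee_at_rho_5(self, rng):
        res = build_reservoir(100, 5.0, input_dim=2, seed=3)
        u = 0.01 * rng.standard_normal((800, 2))
        s1 = esn_states(res, u, x0=np.zeros(100))
        s2 = esn_states(res, u, x0=rng.uniform(-1, 1, 100))
        dist = np.linalg.norm(s1 - s2, axis=1)
        assert dist[-1] > 1e-6  # echo-state property violated

    def test_nan_input_rejected(self):
        res = build_reservoir(10, 0.9, input_dim=1, seed=0)
        bad = np.ones((20, 1))
        bad[5] = np.nan
        with pytest.raises(ValueError):
            esn_states(res, bad)

    def test_linear_readout_of_linear_target(self, rng):
        # small rho + weak input: states ~ linear in u, so a linear target
        # is recoverable with near-zero error
        res = build_reservoir(50, 0.01, input_dim=1, seed=5)
        u = 0.01 * rng.standard_normal((500, 1))
        states = esn_states(res, u)
        target = 2.0 * u[:, 0]
        aug = np.hstack([states, np.ones((500, 1))])
        beta, *_ = np.linalg.lstsq(aug, target, rcond=None)
        mse = np.mean((aug @ beta - target) ** 2)
        assert mse < 1e-10


class TestTrainEsn:
    def _class_constant_data(self, n_per=8, T=600):
        seqs, labels = [], []
        for level, lab in ((0.2, "low"), (0.8, "high")):
            for _ in range(n_per):
                seqs.append(np.full((T, 3), level))
                labels.append(lab)
        return seqs, labels

    def test_class_constant_sequences_perfectly_decoded(self):
        seqs, labels = self._class_constant_data()
        hp = HyperParams(esn_n_neurons=(40,), esn_spectral_radius=(0.9,),
                         esn_ridge_lambda=(1e-6,))
        model = train_esn(seqs, labels, fs=1000.0, hp=hp, seed=0)
        held = Envelope(data=np.full((3, 600), 0.8).astype(float), fs=1000.0,
                        normalized=True)
        preds = predict_windows(model, held)
        assert (preds.labels == "high").all()

    def test_large_lambda_shrinks_readout(self):
        seqs, labels = self._class_constant_data(n_per=4, T=300)
        hp = HyperParams(esn_n_neurons=(30,), esn_spectral_radius=(0.9,),
                         esn_ridge_lambda=(1e9,))
        model = train_esn(seqs, labels, fs=1000.0, hp=hp, seed=0)
        assert np.abs(model.impl.beta).max() < 1e-3


class TestPredictWindows:
    def test_deterministic_and_scores_sum_to_one(self, rng):
        X = rng.random((60, 6))
        X[30:] += 2
        y = np.array(["a"] * 30 + ["b"] * 30, dtype=object)
        model = train_lda(X, y)
        model.n_features = 6
        # an envelope with 2 channels -> 3 features x 2 channels = 6
        env = Envelope(data=rng.random((2, 800)), fs=1000.0, normalized=True)
        p1 = predict_windows(model, env)
        p2 = predict_windows(model, env)
        np.testing.assert_array_equal(p1.labels, p2.labels)
        np.testing.assert_allclose(p1.scores.sum(axis=1), 1.0)

    def test_fingerprint_mismatch_raises(self, rng):
        X = rng.random((40, 6))
        y = np.array(["a", "b"] * 20, dtype=object)
        model = train_lda(X, y)
        env = Envelope(data=rng.random((5, 800)), fs=1000.0, normalized=True)
        with pytest.raises(ValueError, match="does not match"):
            predict_windows(model, env)


def test_model_roundtrip(tmp_path, rng):
    X = rng.random((40, 6))
    X[20:] += 1
    y = np.array(["a"] * 20 + ["b"] * 20, dtype=object)
    model = train_lda(X, y)
    path = tmp_path / "model.pkl"
    save_model(model, path)
    back = load_model(path)
    assert back.kind == "lda"
    np.testing.assert_allclose(back.impl.means, model.impl.means)
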
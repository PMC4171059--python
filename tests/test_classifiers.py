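"""ELM interpolation/prediction and prototype matching."""

import numpy as np
import pytest

import biomotion as bm
from biomotion import classifiers


def _logistic(z):
    return 1.0 / (1.0 + np.exp(-z))


class TestHiddenOutput:
    def test_sigmoid_zero_params(self):
        model = classifiers.ELMModel(
            a=np.zeros((1, 3)), b=np.zeros(1), beta_out=np.zeros((1, 2)),
            node_type="sigmoid", classes=np.array([0, 1]), rng_seed=0)
        out = bm.hidden_output(model, np.array([5.0, -2.0, 1.0]))
        assert out[0] == pytest.approx(0.5)

    def test_rbf_apex(self):
        a = np.array([[0.3, -0.7]])
        model = classifiers.ELMModel(
            a=a, b=np.array([2.0]), beta_out=np.zeros((1, 2)),
            node_type="rbf", classes=np.array([0, 1]), rng_seed=0)
        assert bm.hidden_output(model, a[0])[0] == pytest.approx(1.0)

    @pytest.mark.parametrize("node_type", ["sigmoid", "rbf", "wavelet"])
    def test_matches_scalar_closed_form(self, node_type):
        rng = np.random.default_rng(7)
        a = rng.uniform(-1, 1, size=(4, 5))
        b = rng.uniform(0.1, 1, size=4)
        x = rng.standard_normal(5)
        model = classifiers.ELMModel(
            a=a, b=b, beta_out=np.zeros((4, 2)), node_type=node_type,
            classes=np.array([0, 1]), rng_seed=0)
        out = bm.hidden_output(model, x)
        for i in range(4):
            if node_type == "sigmoid":
                expect = _logistic(a[i] @ x + b[i])
            elif node_type == "rbf":
                expect = np.exp(-b[i] * np.sum((x - a[i]) ** 2))
            else:
                z = np.linalg.norm(x - a[i]) / b[i]
                expect = (1 - z**2) * np.exp(-(z**2) / 2)
            assert out[i] == pytest.approx(expect, abs=1e-12)

    def test_dimension_mismatch_rejected(self):
        model = classifiers.ELMModel(
            a=np.zeros((2, 3)), b=np.zeros(2), beta_out=np.zeros((2, 2)),
            node_type="sigmoid", classes=np.array([0, 1]), rng_seed=0)
        with pytest.raises(ValueError):
            bm.hidden_output(model, np.zeros(4))


class TestELMTrain:
    def test_zero_training_error_when_overparameterised(self):
        """L >= N distinct samples interpolate exactly: H beta = T."""
        rng = np.random.default_rng(0)
        X = rng.standard_normal((5, 3))
        y = np.array([0, 1, 2, 0, 1])
        model = bm.elm_train(X, y, L=20, node_type="sigmoid", seed=1)
        labels, scores = bm.elm_predict(model, X)
        assert np.array_equal(labels, y)
        H = classifiers._hidden_matrix(model.a, model.b, X, "sigmoid")
        T = np.zeros((5, 3))
        T[np.arange(5), y] = 1.0
        assert np.abs(H @ model.beta_out - T).max() < 1e-6

    def test_xor_is_interpolated(self):
        X = np.array([[0, 0], [0, 1], [1, 0], [1, 1]], dtype=float)
        y = np.array([0, 1, 1, 0])
        model = bm.elm_train(X, y, L=20, node_type="sigmoid", seed=1)
        labels, _ = bm.elm_predict(model, X)
        assert np.array_equal(labels, y)

    def test_single_sample(self):
        model = bm.elm_train(np.array([[1.0, 2.0]]), np.array(["a"]), L=3, seed=0)
        labels, _ = bm.elm_predict(model, np.array([[1.0, 2.0]]))
        assert labels[0] == "a"

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((6, 2))
        y = np.array([0, 1] * 3)
        m1 = bm.elm_train(X, y, L=10, seed=42)
        m2 = bm.elm_train(X, y, L=10, seed=42)
        np.testing.assert_array_equal(m1.a, m2.a)
        np.testing.assert_array_equal(m1.beta_out, m2.beta_out)

    def test_target_scale_equivariance(self):
        """Least squares is linear: doubling T doubles beta exactly."""
        rng = np.random.default_rng(1)
        X = rng.standard_normal((8, 3))
        y = np.array([0, 1] * 4)
        model = bm.elm_train(X, y, L=6, seed=3)
        H = classifiers._hidden_matrix(model.a, model.b, X, "sigmoid")
        T = np.zeros((8, 2))
        T[np.arange(8), y] = 1.0
        beta2 = np.linalg.pinv(H) @ (2 * T)
        np.testing.assert_allclose(beta2, 2 * model.beta_out, atol=1e-10)

    def test_interpolation_across_seeds(self):
        """Zero training error holds across 20 hidden-layer draws."""
        rng = np.random.default_rng(10)
        X = rng.standard_normal((10, 4))
        y = rng.integers(0, 3, size=10)
        for seed in range(20):
            model = bm.elm_train(X, y, L=40, seed=seed)
            labels, _ = bm.elm_predict(model, X)
            assert np.array_equal(labels, y)

    def test_rbf_outputs_bounded(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((6, 3))
        model = bm.elm_train(X, np.array([0, 1] * 3), L=12, node_type="rbf", seed=0)
        H = classifiers._hidden_matrix(model.a, model.b, X, "rbf")
        assert np.all(H > 0) and np.all(H <= 1)

    def test_invalid_L_rejected(self):
        with pytest.raises(ValueError):
            bm.elm_train(np.zeros((2, 2)), np.array([0, 1]), L=0)


class TestELMPredict:
    def test_row_permutation_equivariance(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((7, 3))
        model = bm.elm_train(X, np.array([0, 1, 2, 0, 1, 2, 0]), L=15, seed=2)
        perm = rng.permutation(7)
        l1, _ = bm.elm_predict(model, X)
        l2, _ = bm.elm_predict(model, X[perm])
        assert np.array_equal(l1[perm], l2)

    def test_scores_match_loop_oracle(self):
        rng = np.random.default_rng(6)
        X = rng.standard_normal((4, 3))
        model = bm.elm_train(X, np.array([0, 1, 0, 1]), L=5, seed=9)
        _, scores = bm.elm_predict(model, X)
        H = classifiers._hidden_matrix(model.a, model.b, X, "sigmoid")
        for i in range(4):
            for j in range(2):
                expect = sum(H[i, l] * model.beta_out[l, j] for l in range(5))
                assert scores[i, j] == pytest.approx(expect, abs=1e-10)


class TestPrototypeScore:
    def _bank(self):
        rng = np.random.default_rng(0)
        protos = {}
        for name in ("alpha", "beta"):
            p = rng.standard_normal((5, 6, 6))
            p /= np.linalg.norm(p.reshape(5, -1), axis=1)[:, None, None]
            protos[name] = p
        return classifiers.PrototypeSet(prototypes=protos, class_names=("alpha", "beta"))

    def test_autocorrelation_scores_one(self):
        bank = self._bank()
        scores = bm.prototype_score(bank, bank.prototypes["alpha"][2])
        assert scores["alpha"] == pytest.approx(1.0)

    def test_negated_prototype_scores_minus_one(self):
        bank = self._bank()
        desc = -bank.prototypes["beta"][0]
        best_single = max(
            np.corrcoef(desc.ravel(), p.ravel())[0, 1]
            for p in bank.prototypes["beta"]
        )
        assert bm.prototype_score(bank, desc)["beta"] == pytest.approx(best_single, abs=1e-10)

    def test_zero_variance_descriptor_scores_zero(self):
        bank = self._bank()
        scores = bm.prototype_score(bank, np.full((6, 6), 3.0))
        assert all(v == 0.0 for v in scores.values())

    def test_matches_direct_formula(self):
        bank = self._bank()
        rng = np.random.default_rng(3)
        x = rng.standard_normal((6, 6))
        scores = bm.prototype_score(bank, x)
        for name in bank.class_names:
            direct = max(
                np.corrcoef(x.ravel(), p.ravel())[0, 1]
                for p in bank.prototypes[name]
            )
            assert scores[name] == pytest.approx(direct, abs=1e-10)

    def test_five_prototypes_enforced(self):
        with pytest.raises(ValueError):
            classifiers.PrototypeSet(
                prototypes={"x": np.zeros((4, 3, 3))}, class_names=("x",))


class TestELMSerialization:
    def test_bit_exact_round_trip(self, tmp_path):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((6, 4))
        model = bm.elm_train(X, np.array(["u", "v"] * 3), L=7,
                             node_type="wavelet", seed=5)
        path = tmp_path / "elm.zip"
        classifiers.save_elm(model, path)
        back = classifiers.load_elm(path)
        np.testing.assert_array_equal(back.a, model.a)
        np.testing.assert_array_equal(back.b, model.b)
        np.testing.assert_array_equal(back.beta_out, model.beta_out)
        assert back.node_type == model.node_type
        assert list(back.classes) == list(model.classes)
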
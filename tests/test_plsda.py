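"""NIPALS PLS-DA: fitting, prediction, VIP scores."""

import numpy as np
import pytest

import imsnose as ims
from imsnose.errors import MalformedInputError, ParameterError
from imsnose.plsda import PLSModel, encode_labels, fit_pls, predict, vip_scores


def make_problem(rng, n=20, p=8, classes=("a", "b", "c")):
    X = rng.normal(size=(n, p))
    y = np.array([classes[i % len(classes)] for i in range(n)], dtype=object)
    enc = encode_labels(y, classes)
    return X, y, enc


class TestEncodeLabels:
    def test_one_hot_rows_follow_class_order(self):
        enc = encode_labels(["EVOO", "LVOO"], ["EVOO", "VOO", "LVOO"])
        np.testing.assert_array_equal(enc.Y,
                                      [[1, 0, 0], [0, 0, 1]])

    def test_single_class(self):
        enc = encode_labels(["x", "x"], ["x"])
        np.testing.assert_array_equal(enc.Y, [[1.0], [1.0]])

    def test_unknown_label_rejected(self):
        with pytest.raises(MalformedInputError):
            encode_labels(["OLIVE"], ["EVOO", "VOO"])


class TestFitPLS:
    def test_rank_one_problem_is_solved_with_one_component(self, rng):
        direction = rng.normal(size=10)
        scores = np.concatenate([rng.uniform(1, 2, 8),
                                 rng.uniform(-2, -1, 8)])
        X = np.outer(scores, direction)
        y = np.array(["pos"] * 8 + ["neg"] * 8, dtype=object)
        enc = encode_labels(y, ["pos", "neg"])
        model = fit_pls(X, enc.Y, 1, class_names=enc.class_names)
        labels, _ = predict(model, X)
        assert np.all(labels == y)

    def test_matches_reference_pls2(self, rng):
        # independent cross-check against scikit-learn's NIPALS PLS2
        # (which additionally deflates Y; predictions coincide)
        sklearn = pytest.importorskip("sklearn.cross_decomposition")
        X, y, enc = make_problem(rng)
        model = fit_pls(X, enc.Y, 3, class_names=enc.class_names)
        _, Yhat = predict(model, X)
        ref = sklearn.PLSRegression(n_components=3, scale=False,
                                    tol=1e-12, max_iter=5000).fit(X, enc.Y)
        assert np.abs(ref.predict(X) - Yhat).max() < 1e-6

    def test_scores_mutually_orthogonal(self, rng):
        X, y, enc = make_problem(rng, n=30, p=12)
        model = fit_pls(X, enc.Y, 5, class_names=enc.class_names)
        G = model.T.T @ model.T
        norms = np.sqrt(np.diag(G))
        off = G / np.outer(norms, norms) - np.eye(model.A)
        assert np.abs(off).max() < 1e-6

    def test_weights_unit_norm(self, rng):
        X, y, enc = make_problem(rng)
        model = fit_pls(X, enc.Y, 3)
        np.testing.assert_allclose(np.linalg.norm(model.W, axis=0), 1.0,
                                   atol=1e-12)

    def test_too_many_components_rejected(self, rng):
        X, y, enc = make_problem(rng, n=5, p=3)
        with pytest.raises(ParameterError):
            fit_pls(X, enc.Y, 5)

    def test_zero_variance_rejected(self):
        X = np.ones((6, 4))
        Y = np.eye(3)[[0, 1, 2, 0, 1, 2]]
        with pytest.raises(ParameterError):
            fit_pls(X, Y, 1)

    def test_full_rank_limit_equals_least_squares(self, rng):
        # with A = min(n-1, p) on full-rank X, PLS spans the full column
        # space and reproduces the least-squares training fit
        X, y, enc = make_problem(rng, n=12, p=5)
        model = fit_pls(X, enc.Y, 5, class_names=enc.class_names)
        _, Yhat = predict(model, X)
        Xc = X - X.mean(axis=0)
        Yc = enc.Y - enc.Y.mean(axis=0)
        beta, *_ = np.linalg.lstsq(Xc, Yc, rcond=None)
        np.testing.assert_allclose(Yhat, enc.Y.mean(axis=0) + Xc @ beta,
                                   atol=1e-8)


class TestPredict:
    def _toy_model(self, q_row):
        # hand-built one-component model: feature 1 carries the score
        e1 = np.zeros(4)
        e1[0] = 1.0
        return PLSModel(
            x_mean=np.zeros(4), y_mean=np.zeros(3),
            W=e1[:, None], P=e1[:, None],
            Q=np.asarray(q_row, dtype=float)[:, None],
            T=np.array([[1.0], [-1.0]]), A=1,
            class_names=["c0", "c1", "c2"],
        )

    def test_argmax_rule(self):
        model = self._toy_model([0.9, 0.3, -0.1])
        labels, _ = predict(model, np.array([[1.0, 0, 0, 0]]))
        assert labels[0] == "c0"

    def test_ties_break_to_lowest_class_index(self):
        model = self._toy_model([0.5, 0.5, 0.1])
        labels, _ = predict(model, np.array([[1.0, 0, 0, 0]]))
        assert labels[0] == "c0"

    def test_invariant_to_constant_feature_shift(self, rng):
        X, y, enc = make_problem(rng)
        model = fit_pls(X, enc.Y, 3, class_names=enc.class_names)
        shifted = fit_pls(X + 100.0, enc.Y, 3, class_names=enc.class_names)
        _, Yhat = predict(model, X)
        _, Yhat_s = predict(shifted, X + 100.0)
        np.testing.assert_allclose(Yhat, Yhat_s, atol=1e-8)

    def test_feature_mismatch_rejected(self, rng):
        X, y, enc = make_problem(rng)
        model = fit_pls(X, enc.Y, 2)
        with pytest.raises(MalformedInputError):
            predict(model, X[:, :4])

    def test_perfect_training_data_classified_perfectly(self, rng):
        X = np.vstack([rng.normal(0, 0.1, size=(10, 6)),
                       rng.normal(5, 0.1, size=(10, 6))])
        y = np.array(["lo"] * 10 + ["hi"] * 10, dtype=object)
        enc = encode_labels(y, ["lo", "hi"])
        model = fit_pls(X, enc.Y, 2, class_names=enc.class_names)
        labels, _ = predict(model, X)
        assert np.all(labels == y)


def vip_bruteforce(model):
    """Naive loop evaluation of the Wold VIP formula."""
    j, a_total = model.W.shape
    ss = np.array([
        float(model.T[:, a] @ model.T[:, a]) * float(model.Q[:, a] @ model.Q[:, a])
        for a in range(a_total)
    ])
    vip = np.zeros(j)
    for jj in range(j):
        num = 0.0
        for a in range(a_total):
            wnorm = model.W[:, a] / np.linalg.norm(model.W[:, a])
            num += ss[a] * wnorm[jj] ** 2
        vip[jj] = np.sqrt(j * num / ss.sum())
    return vip


class TestVIP:
    def test_normalization_identity(self, rng):
        X, y, enc = make_problem(rng, n=30, p=15)
        model = fit_pls(X, enc.Y, 4, class_names=enc.class_names)
        v = vip_scores(model)
        assert abs((v**2).sum() - model.n_features) < 1e-8

    def test_single_feature_component(self):
        j = 9
        e1 = np.zeros(j)
        e1[0] = 1.0
        model = PLSModel(x_mean=np.zeros(j), y_mean=np.zeros(2),
                         W=e1[:, None], P=e1[:, None],
                         Q=np.array([[1.0], [0.5]]),
                         T=np.arange(1.0, 5.0)[:, None], A=1,
                         class_names=["a", "b"])
        v = vip_scores(model)
        assert v[0] == pytest.approx(np.sqrt(j))
        np.testing.assert_allclose(v[1:], 0.0, atol=1e-12)

    def test_matches_bruteforce_formula(self, rng):
        X, y, enc = make_problem(rng, n=25, p=12)
        model = fit_pls(X, enc.Y, 4, class_names=enc.class_names)
        assert np.abs(vip_scores(model) - vip_bruteforce(model)).max() < 1e-10


class TestAverageVIPMap:
    def test_identical_models_average_to_single_vip(self, rng):
        X, y, enc = make_problem(rng, n=20, p=12)
        model = fit_pls(X, enc.Y, 3, class_names=enc.class_names)
        vm = ims.average_vip_map([model, model, model], (3, 4))
        np.testing.assert_allclose(vm.vip, vip_scores(model), atol=1e-12)

    def test_reshape_roundtrip(self, rng):
        X, y, enc = make_problem(rng, n=20, p=12)
        model = fit_pls(X, enc.Y, 2, class_names=enc.class_names)
        vm = ims.average_vip_map([model], (4, 3))
        np.testing.assert_array_equal(vm.map.ravel(order="C"), vm.vip)

    def test_inconsistent_feature_counts_rejected(self, rng):
        X, y, enc = make_problem(rng, n=20, p=12)
        m1 = fit_pls(X, enc.Y, 2)
        m2 = fit_pls(X[:, :8], enc.Y, 2)
        with pytest.raises(MalformedInputError):
            ims.average_vip_map([m1, m2], (3, 4))


class TestSerialization:
    def test_model_roundtrip(self, tmp_path, rng):
        X, y, enc = make_problem(rng)
        model = fit_pls(X, enc.Y, 3, class_names=enc.class_names)
        path = tmp_path / "model.h5"
        ims.save_model(model, path)
        back = ims.load_model(path)
        _, Yhat = predict(model, X)
        _, Yhat_back = predict(back, X)
        np.testing.assert_allclose(Yhat, Yhat_back, rtol=1e-12)
        assert back.class_names == model.class_names
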
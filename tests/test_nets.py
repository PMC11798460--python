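import numpy as np
import pytest

from cropvote import autodiff as ad
from cropvote.autodiff import Tensor
from cropvote.nets import (
    BiGRUClassifier,
    CNNClassifier,
    ConvLayerSpec,
    ModelError,
    TrainConfig,
    bigru_encode,
    cnn_forward,
    conv_layer,
    ensemble_predict,
    gru_step,
    train_member,
    vote,
)


def zero_gru_params(n_in, hidden):
    return {
        f"{w}_{g}": Tensor(np.zeros((hidden + n_in, hidden)) if w == "W" else np.zeros(hidden))
        for g in ("F", "r", "c")
        for w in ("W", "b")
    }


def scalar_gru_oracle(xs, params):
    """Pure-python single-unit GRU unroll for oracle comparison."""

    def sig(v):
        return 1.0 / (1.0 + np.exp(-v))

    h = 0.0
    for x in xs:
        WF, bF = params["W_F"].data[:, 0], float(params["b_F"].data[0])
        Wr, br = params["W_r"].data[:, 0], float(params["b_r"].data[0])
        Wc, bc = params["W_c"].data[:, 0], float(params["b_c"].data[0])
        F = sig(WF[0] * h + WF[1] * x + bF)
        r = sig(Wr[0] * h + Wr[1] * x + br)
        htil = np.tanh(Wc[0] * (r * h) + Wc[1] * x + bc)
        h = (1 - F) * h + F * htil
    return h


class TestAutodiff:
    def test_gradients_match_finite_differences(self):
        rng = np.random.default_rng(0)
        W = Tensor(rng.standard_normal((3, 2)), requires_grad=True)
        x = np.array([[0.3, -0.5, 0.2]])

        def loss_of(Wdata):
            Wt = Tensor(Wdata, requires_grad=True)
            out = ad.tanh(Tensor(x) @ Wt)
            return ad.softmax_cross_entropy(out, np.array([1]))

        loss = loss_of(W.data)
        # rebuild to capture grads on a fresh tensor
        Wt = Tensor(W.data.copy(), requires_grad=True)
        out = ad.tanh(Tensor(x) @ Wt)
        loss = ad.softmax_cross_entropy(out, np.array([1]))
        loss.backward()
        eps = 1e-6
        for i in range(3):
            for j in range(2):
                Wp = W.data.copy(); Wp[i, j] += eps
                Wm = W.data.copy(); Wm[i, j] -= eps
                fd = (float(loss_of(Wp).data) - float(loss_of(Wm).data)) / (2 * eps)
                assert Wt.grad[i, j] == pytest.approx(fd, abs=1e-6)

    def test_maximum_routes_gradient_to_larger(self):
        a = Tensor(np.array([[2.0, 1.0]]), requires_grad=True)
        b = Tensor(np.array([[1.0, 3.0]]), requires_grad=True)
        ad.maximum(a, b).mean().backward()
        np.testing.assert_allclose(a.grad, [[0.5, 0.0]])
        np.testing.assert_allclose(b.grad, [[0.0, 0.5]])

    def test_bias_broadcast_gradient_sums_over_batch(self):
        b = Tensor(np.zeros(2), requires_grad=True)
        x = Tensor(np.ones((4, 2)))
        (x + b).mean().backward()
        np.testing.assert_allclose(b.grad, [0.5, 0.5])


class TestGRUStep:
    def test_zero_parameters_halve_previous_state(self):
        # F = sigma(0) = 0.5, candidate = tanh(0) = 0, so h = 0.5 * h_prev
        params = zero_gru_params(1, 1)
        h = gru_step(np.array([[2.0]]), np.array([[1.0]]), params)
        assert h.data[0, 0] == pytest.approx(0.5)

    def test_zero_state_is_fixed_point_of_zero_weights(self):
        params = zero_gru_params(2, 3)
        h = gru_step(np.zeros((1, 2)), np.zeros((1, 3)), params)
        np.testing.assert_allclose(h.data, 0.0)

    def test_two_step_unroll_matches_hand_oracle(self):
        rng = np.random.default_rng(3)
        params = {
            f"{w}_{g}": Tensor(rng.standard_normal((2, 1)) if w == "W" else rng.standard_normal(1))
            for g in ("F", "r", "c")
            for w in ("W", "b")
        }
        xs = [0.7, -0.4]
        h = Tensor(np.zeros((1, 1)))
        for x in xs:
            h = gru_step(np.array([[x]]), h, params)
        assert h.data[0, 0] == pytest.approx(scalar_gru_oracle(xs, params), abs=1e-10)

    def test_state_bounded_by_convex_combination(self):
        rng = np.random.default_rng(5)
        params = {
            f"{w}_{g}": Tensor(rng.standard_normal((5 + 3, 5)) if w == "W" else rng.standard_normal(5))
            for g in ("F", "r", "c")
            for w in ("W", "b")
        }
        h_prev = rng.uniform(-2, 2, (4, 5))
        h = gru_step(rng.standard_normal((4, 3)), h_prev, params)
        assert (np.abs(h.data) <= np.maximum(np.abs(h_prev), 1.0) + 1e-12).all()

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ModelError):
            gru_step(np.zeros((2, 1)), np.zeros((3, 1)), zero_gru_params(1, 1))


class TestBiGRU:
    def test_output_length_is_twice_hidden(self, rng):
        f = zero_gru_params(4, 6)
        b = zero_gru_params(4, 6)
        enc = bigru_encode(rng.standard_normal((3, 5, 4)), f, b, hidden=6)
        assert enc.shape == (3, 12)

    def test_palindrome_with_shared_weights_symmetric(self, rng):
        params = {
            f"{w}_{g}": Tensor(rng.standard_normal((3, 2)) if w == "W" else rng.standard_normal(2))
            for g in ("F", "r", "c")
            for w in ("W", "b")
        }
        seq = np.array([[0.5], [-1.0], [0.5]])  # palindromic
        enc = bigru_encode(seq, params, params, hidden=2).data[0]
        np.testing.assert_allclose(enc[:2], enc[2:], atol=1e-12)

    def test_length_one_sequence_directions_agree(self, rng):
        params = {
            f"{w}_{g}": Tensor(rng.standard_normal((4, 2)) if w == "W" else rng.standard_normal(2))
            for g in ("F", "r", "c")
            for w in ("W", "b")
        }
        enc = bigru_encode(np.ones((1, 1, 2)), params, params, hidden=2).data[0]
        np.testing.assert_allclose(enc[:2], enc[2:], atol=1e-14)

    def test_empty_sequence_errors(self):
        with pytest.raises(ModelError):
            bigru_encode(np.empty((1, 0, 2)), zero_gru_params(2, 2),
                         zero_gru_params(2, 2), hidden=2)


class TestCNN:
    def test_identity_filter_reproduces_input(self):
        layers = [(Tensor(np.array([[1.0]])), Tensor(np.zeros(1)),
                   ConvLayerSpec(1, 1, "identity", None))]
        seq = np.array([[3.0], [5.0], [9.0]])
        out = cnn_forward(seq, layers)
        np.testing.assert_allclose(out.data[0], [3.0, 5.0, 9.0])

    def test_hand_convolution_difference_filter(self):
        # filter (1, -1) over (3, 5, 9) -> (3-5, 5-9) = (-2, -4)
        layers = [(Tensor(np.array([[1.0], [-1.0]])), Tensor(np.zeros(1)),
                   ConvLayerSpec(1, 2, "identity", None))]
        out = cnn_forward(np.array([[3.0], [5.0], [9.0]]), layers)
        np.testing.assert_allclose(out.data[0], [-2.0, -4.0])

    def test_maxpool_of_two(self):
        layers = [(Tensor(np.array([[1.0], [-1.0]])), Tensor(np.zeros(1)),
                   ConvLayerSpec(1, 2, "identity", 2))]
        out = cnn_forward(np.array([[3.0], [5.0], [9.0]]), layers)
        np.testing.assert_allclose(out.data[0], [-2.0])  # max(-2, -4)

    def test_matches_nested_loop_oracle(self, rng):
        """Random weights/input: conv + relu + pool equals an explicit
        nested-loop reimplementation to 1e-10."""
        T, C, K, W = 7, 3, 2, 4
        weight = rng.standard_normal((K * C, W))
        bias = rng.standard_normal(W)
        x = rng.standard_normal((T, C))
        layers = [(Tensor(weight), Tensor(bias), ConvLayerSpec(W, K, "relu", 2))]
        got = cnn_forward(x, layers).data[0]

        conv = np.zeros((T - K + 1, W))
        for t in range(T - K + 1):
            window = x[t : t + K].reshape(-1)
            for w in range(W):
                conv[t, w] = max(0.0, window @ weight[:, w] + bias[w])
        pooled = np.array([
            conv[s : s + 2].max(axis=0) for s in range(0, T - K, 2)
        ])
        np.testing.assert_allclose(got, pooled.reshape(-1), atol=1e-10)

    def test_too_short_sequence_names_required_length(self):
        with pytest.raises(ModelError, match="length"):
            CNNClassifier(n_features=2, window=1,
                          layer_specs=[ConvLayerSpec(4, 3, "relu", None)])


class TestTraining:
    def make_separable(self, rng, n=60):
        X = rng.standard_normal((n, 4, 3))
        y = (X[:, -1, 0] > 0).astype(int)
        X[:, :, 0] += 3.0 * (2 * y - 1)[:, None]  # strong, linear signal
        return X, y

    def test_zero_learning_rate_leaves_parameters(self, rng):
        X, y = self.make_separable(rng)
        model = BiGRUClassifier(3, hidden=4, seed=0)
        before = [p.data.copy() for p in model.params]
        train_member(model, X, y, TrainConfig(epochs=2, lr=0.0, seed=0))
        for p, b in zip(model.params, before):
            np.testing.assert_array_equal(p.data, b)

    def test_fixed_seed_identical_loss_trace(self, rng):
        X, y = self.make_separable(rng)
        traces = []
        for _ in range(2):
            model = CNNClassifier(3, window=4, seed=1)
            traces.append(train_member(model, X, y, TrainConfig(epochs=5, seed=2)))
        assert traces[0] == traces[1]

    @pytest.mark.parametrize("cls", [BiGRUClassifier, CNNClassifier])
    def test_separable_sequences_learned(self, rng, cls):
        X, y = self.make_separable(rng, n=100)
        model = cls(3, hidden=8, seed=0) if cls is BiGRUClassifier else cls(3, window=4, seed=0)
        train_member(model, X, y, TrainConfig(epochs=50, seed=0))
        acc = (model.predict(X) == y).mean()
        assert acc >= 0.95

    def test_smoothed_loss_trace_non_increasing_on_strong_signal(self, rng):
        X, y = self.make_separable(rng, n=120)
        model = BiGRUClassifier(3, hidden=8, seed=3)
        trace = np.array(train_member(model, X, y, TrainConfig(epochs=25, seed=3)))
        smooth = np.convolve(trace, np.ones(5) / 5, mode="valid")
        assert (np.diff(smooth) <= 1e-3).all()

    def test_save_load_round_trip(self, rng, tmp_path):
        X, y = self.make_separable(rng)
        model = CNNClassifier(3, window=4, seed=0)
        train_member(model, X, y, TrainConfig(epochs=3, seed=0))
        model.save(tmp_path / "m")
        clone = CNNClassifier(3, window=4, seed=99)
        clone.load_arrays(tmp_path / "m")
        np.testing.assert_array_equal(model.predict(X), clone.predict(X))


class TestVote:
    def test_two_of_three_majority(self):
        """Committee votes (1, 1, 0): class 1 wins the plurality."""
        pred = vote([(1, [0.2, 0.8]), (1, [0.4, 0.6]), (0, [0.9, 0.1])])
        assert pred.label == 1 and not pred.tie
        assert pred.tally == {0: 1, 1: 2}

    def test_unanimous_zero(self):
        pred = vote([(0, [0.8, 0.2]), (0, [0.7, 0.3])])
        assert pred.label == 0 and not pred.tie

    def test_tie_falls_back_to_probability_sum(self):
        pred = vote([(0, [0.9, 0.1]), (1, [0.4, 0.6])])
        assert pred.label == 0 and pred.tie  # sums (1.3, 0.7)

    def test_residual_tie_lowest_class_index(self):
        pred = vote([(0, [0.5, 0.5]), (1, [0.5, 0.5])])
        assert pred.label == 0 and pred.tie

    def test_exhaustive_three_voter_tally_oracle(self):
        for a in (0, 1):
            for b in (0, 1):
                for c in (0, 1):
                    members = [(v, [0.9, 0.1] if v == 0 else [0.1, 0.9])
                               for v in (a, b, c)]
                    expected = int(a + b + c >= 2)
                    assert vote(members).label == expected

    def test_inconsistent_class_sets_rejected(self):
        with pytest.raises(ModelError):
            vote([(0, [1.0]), (1, [0.5, 0.5])])

    def test_single_member_rejected(self):
        with pytest.raises(ModelError):
            vote([(0, [0.6, 0.4])])


class TestEnsemble:
    def test_identical_members_agree_without_tie(self, rng):
        X = rng.standard_normal((5, 4, 3))
        a = BiGRUClassifier(3, hidden=4, seed=0)
        b = BiGRUClassifier(3, hidden=4, seed=0)
        for p in ensemble_predict([a, b], X):
            assert p.member_labels[0] == p.member_labels[1] == p.label
            assert not p.tie

    def test_ensemble_label_among_member_labels(self, rng):
        X = rng.standard_normal((20, 4, 3))
        a = BiGRUClassifier(3, hidden=4, seed=1)
        b = CNNClassifier(3, window=4, seed=2)
        for p in ensemble_predict([a, b], X):
            assert p.label in p.member_labels

    def test_ensemble_at_least_min_member_accuracy(self, rng):
        rngl = np.random.default_rng(0)
        X = rngl.standard_normal((150, 4, 3))
        y = (X[:, -1, 0] > 0).astype(int)
        X[:, :, 0] += 2.0 * (2 * y - 1)[:, None]
        members = [BiGRUClassifier(3, hidden=8, seed=0), CNNClassifier(3, window=4, seed=1)]
        for m in members:
            train_member(m, X, y, TrainConfig(epochs=30, seed=0))
        ens = np.array([p.label for p in ensemble_predict(members, X)])
        accs = [(m.predict(X) == y).mean() for m in members]
        assert (ens == y).mean() >= min(accs)
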
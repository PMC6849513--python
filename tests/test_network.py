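import numpy as np
import pytest

from multicue.network import (
    Hyperparameters,
    NetworkWeights,
    bptt_gradients,
    forward,
    init_weights,
    sgd_update,
    sse_loss,
)

PARAM_GROUPS = (
    "input_to_hidden",
    "hidden_to_hidden",
    "hidden_to_semantic",
    "hidden_bias",
    "semantic_bias",
)


def finite_difference_gradients(w, x, target, hp, eps=1e-6):
    """Central-difference oracle for every parameter entry."""
    grads = {}
    for name in PARAM_GROUPS:
        arr = getattr(w, name)
        g = np.zeros_like(arr)
        for idx in np.ndindex(arr.shape):
            orig = arr[idx]
            arr[idx] = orig + eps
            lp = sse_loss(forward(w, x, hp), target, hp)
            arr[idx] = orig - eps
            lm = sse_loss(forward(w, x, hp), target, hp)
            arr[idx] = orig
            g[idx] = (lp - lm) / (2 * eps)
        grads[name] = g
    return grads


def zero_weights(hp):
    return NetworkWeights(
        input_to_hidden=np.zeros((hp.n_hidden, hp.n_input)),
        hidden_to_hidden=np.zeros((hp.n_hidden, hp.n_hidden)),
        hidden_to_semantic=np.zeros((hp.n_semantic, hp.n_hidden)),
        hidden_bias=np.zeros(hp.n_hidden),
        semantic_bias=np.zeros(hp.n_semantic),
    )


class TestHyperparameters:
    def test_defaults(self):
        hp = Hyperparameters()
        assert hp.n_input == 82 and hp.n_hidden == 100 and hp.n_semantic == 100
        assert hp.timesteps == 6 and hp.error_window == (3, 6)

    def test_error_window_must_fit_timesteps(self):
        with pytest.raises(ValueError):
            Hyperparameters(timesteps=4, error_window=(3, 6))

    def test_positive_rates_required(self):
        with pytest.raises(ValueError):
            Hyperparameters(learning_rate=0.0)
        with pytest.raises(ValueError):
            Hyperparameters(init_range=-1.0)


class TestInitWeights:
    def test_same_seed_identical(self, tiny_hp):
        a = init_weights(tiny_hp, np.random.default_rng(4))
        b = init_weights(tiny_hp, np.random.default_rng(4))
        for name in PARAM_GROUPS:
            assert np.array_equal(getattr(a, name), getattr(b, name))

    def test_entries_within_init_range(self):
        hp = Hyperparameters(n_input=5, n_hidden=3, n_semantic=2, init_range=0.1)
        w = init_weights(hp, np.random.default_rng(0))
        for name in PARAM_GROUPS:
            arr = getattr(w, name)
            assert np.all(arr >= -0.1) and np.all(arr <= 0.1)

    def test_different_seeds_differ(self, tiny_hp):
        a = init_weights(tiny_hp, np.random.default_rng(1))
        b = init_weights(tiny_hp, np.random.default_rng(2))
        assert not np.array_equal(a.input_to_hidden, b.input_to_hidden)

    def test_shapes_validate(self, tiny_hp):
        init_weights(tiny_hp, np.random.default_rng(0)).validate(tiny_hp)


class TestForward:
    def test_zero_weights_give_half_everywhere(self, tiny_hp):
        trace = forward(zero_weights(tiny_hp), np.ones(5), tiny_hp)
        assert np.allclose(trace.hidden, 0.5)
        assert np.allclose(trace.semantic, 0.5)

    def test_first_semantic_step_independent_of_input(self, tiny_hp, rng):
        w = init_weights(tiny_hp, rng)
        a = forward(w, np.zeros(5), tiny_hp)
        b = forward(w, np.ones(5), tiny_hp)
        assert np.array_equal(a.semantic[0], b.semantic[0])

    def test_semantic_step3_depends_on_input(self, tiny_hp):
        # the signal reaches the output by the start of the error window
        w = init_weights(tiny_hp, np.random.default_rng(8))
        x = np.zeros(5)
        x2 = x.copy()
        x2[0] = 1.0
        a = forward(w, x, tiny_hp)
        b = forward(w, x2, tiny_hp)
        assert not np.allclose(a.semantic[2], b.semantic[2])

    def test_purely_functional(self, tiny_hp, rng):
        w = init_weights(tiny_hp, rng)
        x = rng.random(5)
        a = forward(w, x, tiny_hp)
        b = forward(w, x, tiny_hp)
        assert np.array_equal(a.hidden, b.hidden)
        assert np.array_equal(a.semantic, b.semantic)

    def test_trace_lengths_and_open_interval(self, tiny_hp, rng):
        w = init_weights(tiny_hp, rng)
        trace = forward(w, rng.random(5), tiny_hp)
        assert trace.hidden.shape == (6, 3) and trace.semantic.shape == (6, 2)
        for arr in (trace.hidden, trace.semantic):
            assert np.all(arr > 0) and np.all(arr < 1)

    def test_dimension_mismatch_rejected(self, tiny_hp, rng):
        w = init_weights(tiny_hp, rng)
        with pytest.raises(ValueError):
            forward(w, np.ones(7), tiny_hp)

    def test_slot_permutation_symmetry(self, lexicon10, rng):
        # permuting the two slots of each channel together with the matching
        # input-weight columns leaves the computation invariant
        hp = Hyperparameters(n_input=82, n_hidden=7, n_semantic=10)
        w = init_weights(hp, rng)
        x = np.zeros(82)
        x[:20] = lexicon10[0].form
        x[20:40] = lexicon10[1].form
        x[40:60] = lexicon10[2].referent
        x[60:80] = lexicon10[3].referent
        perm = np.concatenate([np.arange(20, 40), np.arange(0, 20), np.arange(60, 80), np.arange(40, 60), [80, 81]])
        w2 = w.copy()
        w2.input_to_hidden = w.input_to_hidden[:, perm]
        x2 = x[perm]
        target = np.eye(10)[0]
        a = sse_loss(forward(w, x, hp), target, hp)
        b = sse_loss(forward(w2, x2, hp), target, hp)
        assert a == pytest.approx(b, rel=1e-12)


class TestSseLoss:
    def test_exact_fit_zero(self, tiny_hp):
        trace = forward(zero_weights(tiny_hp), np.zeros(5), tiny_hp)
        target = np.full(2, 0.5)
        assert sse_loss(trace, target, tiny_hp) == pytest.approx(0.0)

    def test_half_unit_error_single_step(self, tiny_hp):
        from multicue.network import ActivationTrace

        sem = np.tile([1.0, 0.0], (6, 1))
        sem[3, 0] = 0.5  # one unit off by 0.5 at one window step
        trace = ActivationTrace(hidden=np.zeros((6, 3)), semantic=sem)
        assert sse_loss(trace, np.array([1.0, 0.0]), tiny_hp) == pytest.approx(0.25)

    def test_all_zero_output_vs_localist_target(self, tiny_hp):
        from multicue.network import ActivationTrace

        trace = ActivationTrace(hidden=np.zeros((6, 3)), semantic=np.zeros((6, 2)))
        assert sse_loss(trace, np.array([1.0, 0.0]), tiny_hp) == pytest.approx(4.0)

    def test_error_outside_window_ignored(self, tiny_hp):
        from multicue.network import ActivationTrace

        sem = np.tile([1.0, 0.0], (6, 1))
        sem[0] = [0.0, 1.0]  # steps 1-2 are outside the window
        sem[1] = [0.0, 1.0]
        trace = ActivationTrace(hidden=np.zeros((6, 3)), semantic=sem)
        assert sse_loss(trace, np.array([1.0, 0.0]), tiny_hp) == pytest.approx(0.0)


class TestBpttGradients:
    def test_matches_finite_differences(self, tiny_hp):
        rng = np.random.default_rng(17)
        w = init_weights(tiny_hp, rng)
        x = rng.random(5)
        target = np.array([1.0, 0.0])
        g = bptt_gradients(w, x, target, tiny_hp)
        fd = finite_difference_gradients(w, x, target, tiny_hp)
        for name in PARAM_GROUPS:
            np.testing.assert_allclose(getattr(g, name), fd[name], rtol=1e-5, atol=1e-9)

    def test_zero_loss_zero_gradients(self, tiny_hp):
        # at exact fit, the SSE is at a stationary point
        w = zero_weights(tiny_hp)
        target = np.full(2, 0.5)
        g = bptt_gradients(w, np.zeros(5), target, tiny_hp)
        for name in PARAM_GROUPS:
            assert np.allclose(getattr(g, name), 0.0)

    def test_one_step_window_matches_analytic_chain_rule(self):
        # with a (2,2) window the loss is ||sigma(W_out h1) - y||^2 with
        # h1 = sigma(W_in x + b); the input-weight gradient is analytic
        hp = Hyperparameters(n_input=4, n_hidden=3, n_semantic=2, timesteps=2, error_window=(2, 2))
        rng = np.random.default_rng(3)
        w = init_weights(hp, rng)
        x = rng.random(4)
        y = np.array([0.0, 1.0])
        g = bptt_gradients(w, x, y, hp)

        h1 = 1 / (1 + np.exp(-(w.input_to_hidden @ x + w.hidden_bias)))
        s2 = 1 / (1 + np.exp(-(w.hidden_to_semantic @ h1 + w.semantic_bias)))
        ds = 2 * (s2 - y) * s2 * (1 - s2)
        dh = (w.hidden_to_semantic.T @ ds) * h1 * (1 - h1)
        np.testing.assert_allclose(g.input_to_hidden, np.outer(dh, x), rtol=1e-10)
        # doubling one input entry doubles exactly that column of the gradient
        # (holding the step-1 activations fixed analytically)
        np.testing.assert_allclose(np.outer(dh, 2 * x)[:, 1], 2 * g.input_to_hidden[:, 1], rtol=1e-10)

    @pytest.mark.parametrize("seed", range(5))
    def test_oracle_equivalence_many_seeds(self, tiny_hp, seed):
        rng = np.random.default_rng(seed)
        w = init_weights(tiny_hp, rng)
        x = rng.random(5) * 2
        target = np.zeros(2)
        target[int(rng.integers(2))] = 1.0
        g = bptt_gradients(w, x, target, tiny_hp)
        fd = finite_difference_gradients(w, x, target, tiny_hp)
        for name in PARAM_GROUPS:
            np.testing.assert_allclose(getattr(g, name), fd[name], rtol=1e-5, atol=1e-9)


class TestCheckpoints:
    def test_round_trip(self, tiny_hp, rng, tmp_path):
        from multicue.network import load_checkpoint, save_checkpoint

        w = init_weights(tiny_hp, rng)
        path = tmp_path / "ckpt.json"
        save_checkpoint(path, w, tiny_hp, seeds={"master_seed": 7})
        w2, hp2, seeds = load_checkpoint(path)
        assert hp2 == tiny_hp
        assert seeds == {"master_seed": 7}
        for name in PARAM_GROUPS:
            np.testing.assert_array_equal(getattr(w, name), getattr(w2, name))


class TestSgdUpdate:
    def test_zero_gradient_no_change(self, tiny_hp, rng):
        w = init_weights(tiny_hp, rng)
        w2 = sgd_update(w, zero_weights(tiny_hp), lr=0.5)
        for name in PARAM_GROUPS:
            assert np.array_equal(getattr(w, name), getattr(w2, name))

    def test_zero_lr_no_change(self, tiny_hp, rng):
        w = init_weights(tiny_hp, rng)
        g = bptt_gradients(w, rng.random(5), np.array([1.0, 0.0]), tiny_hp)
        w2 = sgd_update(w, g, lr=0.0)
        for name in PARAM_GROUPS:
            assert np.array_equal(getattr(w, name), getattr(w2, name))

    def test_descent_on_repeated_trial(self, tiny_hp):
        # with a small step, SSE is non-increasing in >= 95 of 100 steps
        rng = np.random.default_rng(21)
        w = init_weights(tiny_hp, rng)
        x = rng.random(5)
        target = np.array([1.0, 0.0])
        losses = []
        for _ in range(101):
            losses.append(sse_loss(forward(w, x, tiny_hp), target, tiny_hp))
            g = bptt_gradients(w, x, target, tiny_hp)
            w = sgd_update(w, g, lr=0.01)
        drops = sum(b <= a + 1e-12 for a, b in zip(losses, losses[1:]))
        assert drops >= 95
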
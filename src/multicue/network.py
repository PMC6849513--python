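"""Hub-and-spoke recurrent network: forward dynamics, loss, BPTT, SGD.

The network has a single integrative hidden layer that receives all 82 input
units (two 20-unit phonological slots, two 20-unit visual slots, 2
distributional units), is fully self-connected, and projects to a localist
semantic output layer. All units use the logistic activation.

Dynamics (1-based steps, input clamped throughout, hidden state zeroed
before step 1):

    hidden(t)   = sigmoid(W_in @ x + W_rec @ hidden(t-1) + b_hidden)
    semantic(t) = sigmoid(W_out @ hidden(t-1) + b_semantic)

so activation needs two steps to travel input -> hidden -> semantic. Error
is the sum squared difference between semantic output and the localist
target, accumulated over the error window (steps 3-6 of 6 by default), and
gradients are computed by unrolled backpropagation through time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from multicue.trials import InputVector

__all__ = [
    "Hyperparameters",
    "NetworkWeights",
    "Gradients",
    "ActivationTrace",
    "init_weights",
    "forward",
    "sse_loss",
    "bptt_gradients",
    "sgd_update",
]


def sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


@dataclass(frozen=True)
class Hyperparameters:
    """Network sizes, dynamics, and training constants.

    ``error_window`` is an inclusive (first, last) pair of 1-based time
    steps at which output error is injected.
    """

    n_input: int = 82
    n_hidden: int = 100
    n_semantic: int = 100
    timesteps: int = 6
    error_window: tuple[int, int] = (3, 6)
    learning_rate: float = 0.1
    init_range: float = 0.5
    master_seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.error_window
        if not (1 <= lo <= hi <= self.timesteps):
            raise ValueError(
                f"error_window {self.error_window} must be a nonempty 1-based "
                f"range within 1..timesteps={self.timesteps}"
            )
        if self.learning_rate <= 0 or self.init_range <= 0:
            raise ValueError("learning_rate and init_range must be positive")

    @property
    def error_steps(self) -> range:
        return range(self.error_window[0], self.error_window[1] + 1)


@dataclass
class NetworkWeights:
    """All connection matrices and biases, stored output-major (rows = post-units)."""

    input_to_hidden: np.ndarray  # (n_hidden, n_input)
    hidden_to_hidden: np.ndarray  # (n_hidden, n_hidden)
    hidden_to_semantic: np.ndarray  # (n_semantic, n_hidden)
    hidden_bias: np.ndarray  # (n_hidden,)
    semantic_bias: np.ndarray  # (n_semantic,)

    def copy(self) -> "NetworkWeights":
        return NetworkWeights(
            input_to_hidden=self.input_to_hidden.copy(),
            hidden_to_hidden=self.hidden_to_hidden.copy(),
            hidden_to_semantic=self.hidden_to_semantic.copy(),
            hidden_bias=self.hidden_bias.copy(),
            semantic_bias=self.semantic_bias.copy(),
        )

    def validate(self, hp: Hyperparameters) -> None:
        shapes = {
            "input_to_hidden": (hp.n_hidden, hp.n_input),
            "hidden_to_hidden": (hp.n_hidden, hp.n_hidden),
            "hidden_to_semantic": (hp.n_semantic, hp.n_hidden),
            "hidden_bias": (hp.n_hidden,),
            "semantic_bias": (hp.n_semantic,),
        }
        for name, shape in shapes.items():
            arr = getattr(self, name)
            if arr.shape != shape:
                raise ValueError(f"{name}: expected shape {shape}, got {arr.shape}")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name}: non-finite entries")


#: Gradients carry the same structure as the weights they differentiate.
Gradients = NetworkWeights


@dataclass(frozen=True)
class ActivationTrace:
    """Per-time-step hidden and semantic activations for one clamped input."""

    hidden: np.ndarray  # (timesteps, n_hidden), step t at row t-1
    semantic: np.ndarray  # (timesteps, n_semantic)
    input: np.ndarray = field(repr=False, default=None)  # (n_input,) clamped input


def _as_input_array(x) -> np.ndarray:
    if isinstance(x, InputVector):
        return x.as_array()
    return np.asarray(x, dtype=np.float64)


def init_weights(hp: Hyperparameters, rng: np.random.Generator) -> NetworkWeights:
    """Sample all weights and biases uniformly from [-init_range, +init_range]."""
    r = hp.init_range
    u = lambda *shape: rng.uniform(-r, r, size=shape)
    return NetworkWeights(
        input_to_hidden=u(hp.n_hidden, hp.n_input),
        hidden_to_hidden=u(hp.n_hidden, hp.n_hidden),
        hidden_to_semantic=u(hp.n_semantic, hp.n_hidden),
        hidden_bias=u(hp.n_hidden),
        semantic_bias=u(hp.n_semantic),
    )


def forward(w: NetworkWeights, x, hp: Hyperparameters) -> ActivationTrace:
    """Run the clamped-input dynamics for ``hp.timesteps`` steps."""
    xv = _as_input_array(x)
    if xv.shape != (w.input_to_hidden.shape[1],):
        raise ValueError(
            f"input has shape {xv.shape}, expected ({w.input_to_hidden.shape[1]},)"
        )
    T = hp.timesteps
    hidden = np.empty((T, w.hidden_bias.shape[0]))
    semantic = np.empty((T, w.semantic_bias.shape[0]))
    drive = w.input_to_hidden @ xv + w.hidden_bias
    h_prev = np.zeros(w.hidden_bias.shape[0])
    for t in range(T):
        semantic[t] = sigmoid(w.hidden_to_semantic @ h_prev + w.semantic_bias)
        hidden[t] = sigmoid(drive + w.hidden_to_hidden @ h_prev)
        h_prev = hidden[t]
    return ActivationTrace(hidden=hidden, semantic=semantic, input=xv)


def sse_loss(trace: ActivationTrace, target: np.ndarray, hp: Hyperparameters) -> float:
    """Sum of squared semantic error over the error-window time steps."""
    target = np.asarray(target, dtype=np.float64)
    if target.shape != trace.semantic.shape[1:]:
        raise ValueError("target length must match the semantic layer")
    err = trace.semantic[hp.error_window[0] - 1 : hp.error_window[1]] - target
    return float(np.sum(err * err))


def bptt_gradients(
    w: NetworkWeights, x, target: np.ndarray, hp: Hyperparameters
) -> Gradients:
    """Exact gradient of ``sse_loss`` by unrolled backpropagation through time."""
    xv = _as_input_array(x)
    target = np.asarray(target, dtype=np.float64)
    trace = forward(w, xv, hp)
    T = hp.timesteps
    h = trace.hidden
    s = trace.semantic
    in_window = np.zeros(T + 1, dtype=bool)
    in_window[hp.error_window[0] : hp.error_window[1] + 1] = True

    g_in = np.zeros_like(w.input_to_hidden)
    g_rec = np.zeros_like(w.hidden_to_hidden)
    g_out = np.zeros_like(w.hidden_to_semantic)
    g_bh = np.zeros_like(w.hidden_bias)
    g_bs = np.zeros_like(w.semantic_bias)

    def h_at(t: int) -> np.ndarray:  # hidden state after step t; h(0) = 0
        return h[t - 1] if t >= 1 else np.zeros_like(w.hidden_bias)

    # dL/dh(t), accumulated while walking t = T..1
    gh_next = np.zeros_like(w.hidden_bias)  # dL/dh(t) for current t
    for t in range(T, 0, -1):
        gh = gh_next
        # semantic output at step t reads h(t-1)
        if in_window[t]:
            ds = 2.0 * (s[t - 1] - target) * s[t - 1] * (1.0 - s[t - 1])
            g_out += np.outer(ds, h_at(t - 1))
            g_bs += ds
            gh_prev_from_out = w.hidden_to_semantic.T @ ds
        else:
            gh_prev_from_out = 0.0
        dpre = gh * h[t - 1] * (1.0 - h[t - 1])
        g_in += np.outer(dpre, xv)
        g_rec += np.outer(dpre, h_at(t - 1))
        g_bh += dpre
        gh_next = w.hidden_to_hidden.T @ dpre + gh_prev_from_out
    return Gradients(
        input_to_hidden=g_in,
        hidden_to_hidden=g_rec,
        hidden_to_semantic=g_out,
        hidden_bias=g_bh,
        semantic_bias=g_bs,
    )


def save_checkpoint(path, w: NetworkWeights, hp: Hyperparameters, seeds: dict | None = None) -> None:
    """Write weights + hyperparameters (+ seed provenance) to a JSON container."""
    import dataclasses
    import json

    doc = {
        "hyperparameters": dataclasses.asdict(hp),
        "seeds": seeds or {},
        "weights": {
            name: getattr(w, name).tolist()
            for name in (
                "input_to_hidden",
                "hidden_to_hidden",
                "hidden_to_semantic",
                "hidden_bias",
                "semantic_bias",
            )
        },
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def load_checkpoint(path) -> tuple[NetworkWeights, Hyperparameters, dict]:
    """Read a checkpoint written by :func:`save_checkpoint`; validates shapes."""
    import json

    with open(path) as fh:
        doc = json.load(fh)
    hp_kw = dict(doc["hyperparameters"])
    hp_kw["error_window"] = tuple(hp_kw["error_window"])
    hp = Hyperparameters(**hp_kw)
    w = NetworkWeights(**{k: np.array(v, dtype=np.float64) for k, v in doc["weights"].items()})
    w.validate(hp)
    return w, hp, doc.get("seeds", {})


def sgd_update(w: NetworkWeights, g: Gradients, lr: float) -> NetworkWeights:
    """Plain gradient-descent step ``w - lr * g`` on every parameter group."""
    if lr < 0:
        raise ValueError("learning rate must be nonnegative")
    return NetworkWeights(
        input_to_hidden=w.input_to_hidden - lr * g.input_to_hidden,
        hidden_to_hidden=w.hidden_to_hidden - lr * g.hidden_to_hidden,
        hidden_to_semantic=w.hidden_to_semantic - lr * g.hidden_to_semantic,
        hidden_bias=w.hidden_bias - lr * g.hidden_bias,
        semantic_bias=w.semantic_bias - lr * g.semantic_bias,
    )
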
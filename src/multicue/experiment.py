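"""Experiment harness: conditions, epochs, learning criterion, robustness, replicates.

A condition fixes the per-trial presence probability of each cue. Training
runs in epochs in which every word is the target exactly once, in random
order; per-epoch accuracy is the proportion of the epoch's own trials whose
target semantic unit is the strict maximum of the output layer on the
forward pass before that trial's weight update. Learning has reached
criterion at the first epoch starting a run of ``criterion_run`` consecutive
all-correct epochs. After training, robustness is the cue-free test accuracy
over fresh foil/slot draws from a dedicated evaluation seed.

Seeding: every random stream derives from ``(master_seed, condition key,
replicate, stream, [epoch])`` via ``numpy.random.SeedSequence`` spawn keys,
so lexica, initial weights, trial order, and evaluation draws are all
independently reproducible.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

from multicue.lexicon import Lexicon, build_lexicon
from multicue.network import ActivationTrace, Hyperparameters, NetworkWeights, bptt_gradients, forward, init_weights, sgd_update
from multicue.trials import CueFlags, EpochBatch, assemble_batch, sample_epoch

__all__ = [
    "ConditionConfig",
    "RunRecord",
    "TABLE1_CONDITIONS",
    "classify_output",
    "run_epoch",
    "detect_criterion",
    "robustness_test",
    "run_condition",
    "run_matched_training",
    "times_to_criterion",
]

# seed-stream tags
_STREAM_LEXICON = 0
_STREAM_WEIGHTS = 1
_STREAM_TRIALS = 2
_STREAM_EVAL = 3


@dataclass(frozen=True)
class ConditionConfig:
    """One training condition: cue reliabilities plus training bounds."""

    name: str
    p_distributional: float = 0.0
    p_prosody: float = 0.0
    p_gesture: float = 0.0
    max_epochs: int = 100_000
    criterion_run: int = 5

    def __post_init__(self) -> None:
        for p in (self.p_distributional, self.p_prosody, self.p_gesture):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"cue reliability {p} outside [0, 1]")
        if self.max_epochs < 1 or self.criterion_run < 1:
            raise ValueError("max_epochs and criterion_run must be >= 1")

    @property
    def key(self) -> int:
        """Stable integer id for seed derivation (CRC32 of the name)."""
        return zlib.crc32(self.name.encode("utf-8")) & 0x7FFFFFFF


def _grid(name, d, p, g, **kw) -> ConditionConfig:
    return ConditionConfig(name=name, p_distributional=d, p_prosody=p, p_gesture=g, **kw)


#: The eight named conditions of the cue-reliability grid.
TABLE1_CONDITIONS: dict[str, ConditionConfig] = {
    c.name: c
    for c in [
        _grid("no_cue", 0.0, 0.0, 0.0),
        _grid("dist_cue", 1.0, 0.0, 0.0),
        _grid("prosodic_cue", 0.0, 1.0, 0.0),
        _grid("gestural_cue", 0.0, 0.0, 1.0),
        _grid("combined_0.25", 0.25, 0.25, 0.25),
        _grid("combined_0.50", 0.50, 0.50, 0.50),
        _grid("combined_0.75", 0.75, 0.75, 0.75),
        _grid("combined_1.00", 1.0, 1.0, 1.0),
    ]
}


@dataclass
class RunRecord:
    """Per-replicate learning history and outcome measures."""

    replicate_id: int
    condition: str
    accuracy_by_epoch: np.ndarray
    epochs_to_criterion: int | None  # None = censored (never reached criterion)
    robustness_accuracy: float
    seeds: dict = field(default_factory=dict)

    @property
    def censored(self) -> bool:
        return self.epochs_to_criterion is None


def _rng(master_seed: int, *spawn_key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(master_seed, spawn_key=spawn_key))


def classify_output(trace: ActivationTrace, target_index: int) -> bool:
    """True iff the target unit is the strict maximum of the final-step output."""
    out = trace.semantic[-1]
    target_act = out[target_index]
    others = np.delete(out, target_index)
    return bool(np.all(target_act > others))


def _strict_argmax_correct(outputs: np.ndarray, targets: np.ndarray) -> np.ndarray:
    """Rowwise strict-max test: target strictly exceeds every other unit."""
    tgt_act = outputs[np.arange(outputs.shape[0]), targets]
    exceeded = outputs >= tgt_act[:, None]
    # the target column always 'ties' with itself; strict win means exactly one hit
    return exceeded.sum(axis=1) == 1


def _batched_final_output(w: NetworkWeights, X: np.ndarray, hp: Hyperparameters) -> np.ndarray:
    """Final-step semantic output for many clamped inputs at once (no updates)."""
    drive = X @ w.input_to_hidden.T + w.hidden_bias
    h_prev = np.zeros((X.shape[0], w.hidden_bias.shape[0]))
    s = None
    for _ in range(hp.timesteps):
        s = 1.0 / (1.0 + np.exp(-(h_prev @ w.hidden_to_semantic.T + w.semantic_bias)))
        h_prev = 1.0 / (1.0 + np.exp(-(drive + h_prev @ w.hidden_to_hidden.T)))
    return s


def _train_on_batch_reference(
    w: NetworkWeights, X: np.ndarray, targets: np.ndarray, hp: Hyperparameters
) -> tuple[NetworkWeights, int]:
    """Scalar reference path: per-trial forward, BPTT, SGD via multicue.network."""
    n_correct = 0
    eye = np.eye(hp.n_semantic)
    for x, tgt in zip(X, targets):
        trace = forward(w, x, hp)
        if classify_output(trace, int(tgt)):
            n_correct += 1
        g = bptt_gradients(w, x, eye[int(tgt)], hp)
        w = sgd_update(w, g, hp.learning_rate)
    return w, n_correct


def _train_on_batch_fast(
    w: NetworkWeights, X: np.ndarray, targets: np.ndarray, hp: Hyperparameters
) -> tuple[NetworkWeights, int]:
    from multicue import _fast

    args = (
        w.input_to_hidden,
        w.hidden_to_hidden,
        w.hidden_to_semantic,
        w.hidden_bias,
        w.semantic_bias,
        np.ascontiguousarray(X),
        np.asarray(targets, dtype=np.int64),
        hp.learning_rate,
    )
    if hp.timesteps == 6 and hp.error_window == (3, 6):
        n_correct = _fast.train_epoch_kernel_t6w4(*args)
    else:
        n_correct = _fast.train_epoch_kernel(
            *args, hp.timesteps, hp.error_window[0], hp.error_window[1]
        )
    return w, int(n_correct)


_BACKENDS = {"reference": _train_on_batch_reference, "fast": _train_on_batch_fast}


def run_epoch(
    w: NetworkWeights,
    lexicon: Lexicon,
    condition: ConditionConfig,
    hp: Hyperparameters,
    rng: np.random.Generator,
    backend: str = "fast",
) -> tuple[NetworkWeights, float]:
    """Train one epoch (each word once as target, random order); return accuracy.

    Accuracy is scored on each trial's pre-update forward pass.
    """
    batch = sample_epoch(lexicon, condition, rng)
    X = assemble_batch(batch, lexicon)
    w, n_correct = _BACKENDS[backend](w, X, batch.targets, hp)
    return w, n_correct / len(batch)


def detect_criterion(accuracy_by_epoch, criterion_run: int = 5) -> int | None:
    """1-based index of the first epoch starting ``criterion_run`` consecutive
    perfect epochs, or None (censored) if there is no such run."""
    if criterion_run < 1:
        raise ValueError("criterion_run must be >= 1")
    streak = 0
    for i, acc in enumerate(accuracy_by_epoch, start=1):
        streak = streak + 1 if acc == 1.0 else 0
        if streak == criterion_run:
            return i - criterion_run + 1
    return None


def robustness_test(
    w: NetworkWeights,
    lexicon: Lexicon,
    hp: Hyperparameters,
    rng: np.random.Generator,
    repeats_per_word: int = 10,
) -> float:
    """Cue-free test accuracy over ``repeats_per_word`` fresh foil/slot draws
    per word. No weight updates occur."""
    n = len(lexicon)
    targets = np.repeat(np.arange(n), repeats_per_word)
    no_cue = ConditionConfig(name="_eval_no_cue")
    batch = sample_epoch(lexicon, no_cue, rng, targets=targets)
    X = assemble_batch(batch, lexicon)
    outputs = _batched_final_output(w, X, hp)
    return float(np.mean(_strict_argmax_correct(outputs, targets)))


def _train_replicate(
    condition: ConditionConfig,
    hp: Hyperparameters,
    master_seed: int,
    replicate: int,
    *,
    fixed_epochs: int | None,
    backend: str,
    repeats_per_word: int,
    progress=None,
) -> RunRecord:
    ckey = condition.key
    lex_seed = int(
        np.random.SeedSequence(master_seed, spawn_key=(ckey, replicate, _STREAM_LEXICON))
        .generate_state(1)[0]
    )
    lexicon = build_lexicon(n_words=hp.n_semantic, seed=lex_seed)
    w = init_weights(hp, _rng(master_seed, ckey, replicate, _STREAM_WEIGHTS))
    train = _BACKENDS[backend]

    n_epochs = fixed_epochs if fixed_epochs is not None else condition.max_epochs
    accuracies = np.empty(n_epochs)
    streak = 0
    last_epoch = 0
    for epoch in range(1, n_epochs + 1):
        rng_e = _rng(master_seed, ckey, replicate, _STREAM_TRIALS, epoch)
        batch = sample_epoch(lexicon, condition, rng_e)
        X = assemble_batch(batch, lexicon)
        w, n_correct = train(w, X, batch.targets, hp)
        accuracies[epoch - 1] = n_correct / len(batch)
        last_epoch = epoch
        if progress is not None:
            progress(condition.name, replicate, epoch, accuracies[epoch - 1])
        if fixed_epochs is None:
            streak = streak + 1 if n_correct == len(batch) else 0
            if streak == condition.criterion_run:
                break
    accuracies = accuracies[:last_epoch]
    robustness = robustness_test(
        w, lexicon, hp, _rng(master_seed, ckey, replicate, _STREAM_EVAL), repeats_per_word
    )
    return RunRecord(
        replicate_id=replicate,
        condition=condition.name,
        accuracy_by_epoch=accuracies,
        epochs_to_criterion=detect_criterion(accuracies, condition.criterion_run),
        robustness_accuracy=robustness,
        seeds={
            "master_seed": master_seed,
            "condition_key": ckey,
            "replicate": replicate,
            "lexicon_seed": lex_seed,
        },
    )


def run_condition(
    condition: ConditionConfig,
    n_replicates: int,
    hp: Hyperparameters,
    master_seed: int,
    backend: str = "fast",
    repeats_per_word: int = 10,
    progress=None,
    replicate_ids=None,
) -> list[RunRecord]:
    """Train ``n_replicates`` fresh models (fresh lexicon, weights, trial order)
    until criterion is confirmed or ``condition.max_epochs``; then test robustness.

    ``replicate_ids`` overrides the default ``range(n_replicates)`` so single
    replicates can be computed incrementally with identical seeding.
    """
    if replicate_ids is None:
        if n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        replicate_ids = range(n_replicates)
    return [
        _train_replicate(
            condition,
            hp,
            master_seed,
            rep,
            fixed_epochs=None,
            backend=backend,
            repeats_per_word=repeats_per_word,
            progress=progress,
        )
        for rep in replicate_ids
    ]


def run_matched_training(
    conditions,
    total_epochs: int,
    n_replicates: int,
    hp: Hyperparameters,
    master_seed: int,
    backend: str = "fast",
    repeats_per_word: int = 10,
    progress=None,
    replicate_ids=None,
) -> dict[str, list[RunRecord]]:
    """Train every replicate of every condition for exactly ``total_epochs``
    epochs (no criterion stop), then measure robustness."""
    if total_epochs < 0:
        raise ValueError("total_epochs must be >= 0")
    if replicate_ids is None:
        replicate_ids = range(n_replicates)
    return {
        c.name: [
            _train_replicate(
                c,
                hp,
                master_seed,
                rep,
                fixed_epochs=total_epochs,
                backend=backend,
                repeats_per_word=repeats_per_word,
                progress=progress,
            )
            for rep in replicate_ids
        ]
        for c in conditions
    }


def times_to_criterion(records, cap: int) -> np.ndarray:
    """Epochs-to-criterion per record, with censored runs entered at ``cap``."""
    return np.array(
        [cap if r.epochs_to_criterion is None else r.epochs_to_criterion for r in records],
        dtype=float,
    )
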
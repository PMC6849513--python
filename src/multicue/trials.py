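"""Cross-situational trial construction and cue application.

A trial presents two word forms (one per phonological slot) and two object
referents (one per visual slot); only one word-object pairing is the true
target. Cues, when present, always mark the target:

* prosody doubles the activation of the target word form in its slot;
* gesture doubles the activation of the target referent in its slot;
* the distributional cue activates one of 2 extra input units according to
  the target's category.

Foil form and foil referent are drawn independently and uniformly from the
other words, and the two target slot positions are randomized independently.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from multicue.lexicon import Lexicon, Word

__all__ = [
    "CueFlags",
    "TrialSpec",
    "InputVector",
    "EpochBatch",
    "sample_cue_flags",
    "sample_trial",
    "assemble_input",
    "make_test_input",
    "sample_epoch",
    "assemble_batch",
]

SLOT_WIDTH = 20
N_INPUT = 2 * SLOT_WIDTH + 2 * SLOT_WIDTH + 2  # 82


@dataclass(frozen=True)
class CueFlags:
    prosody: bool = False
    gesture: bool = False
    distributional: bool = False


@dataclass(frozen=True)
class TrialSpec:
    """One cross-situational learning event."""

    target: Word
    foil_form: Word
    foil_referent: Word
    target_form_slot: int  # 0 or 1
    target_object_slot: int  # 0 or 1
    cues: CueFlags

    def __post_init__(self) -> None:
        if self.foil_form.index == self.target.index:
            raise ValueError("foil form must come from a non-target word")
        if self.foil_referent.index == self.target.index:
            raise ValueError("foil referent must come from a non-target word")
        if self.target_form_slot not in (0, 1) or self.target_object_slot not in (0, 1):
            raise ValueError("slots must be 0 or 1")


@dataclass(frozen=True)
class InputVector:
    """Clamped network input: two phonological slots, two visual slots, 2 distributional units."""

    phonology: np.ndarray  # (40,)
    visual: np.ndarray  # (40,)
    distributional: np.ndarray  # (2,)

    def as_array(self) -> np.ndarray:
        """Concatenated 82-unit input vector (phonology, visual, distributional)."""
        return np.concatenate([self.phonology, self.visual, self.distributional])


def sample_cue_flags(condition, rng: np.random.Generator) -> CueFlags:
    """Sample per-trial cue presence, each cue independently Bernoulli."""
    return CueFlags(
        prosody=bool(rng.random() < condition.p_prosody),
        gesture=bool(rng.random() < condition.p_gesture),
        distributional=bool(rng.random() < condition.p_distributional),
    )


def _sample_other(n: int, exclude: int, rng: np.random.Generator) -> int:
    i = int(rng.integers(0, n - 1))
    return i + 1 if i >= exclude else i


def sample_trial(
    lexicon: Lexicon, condition, target_index: int, rng: np.random.Generator
) -> TrialSpec:
    """Build one training trial for ``target_index`` under ``condition``."""
    n = len(lexicon)
    if not 0 <= target_index < n:
        raise IndexError(f"target_index {target_index} out of range")
    foil_form = _sample_other(n, target_index, rng)
    foil_referent = _sample_other(n, target_index, rng)
    return TrialSpec(
        target=lexicon[target_index],
        foil_form=lexicon[foil_form],
        foil_referent=lexicon[foil_referent],
        target_form_slot=int(rng.integers(0, 2)),
        target_object_slot=int(rng.integers(0, 2)),
        cues=sample_cue_flags(condition, rng),
    )


def _two_slots(target_vec, foil_vec, target_slot: int, gain: float) -> np.ndarray:
    out = np.zeros(2 * SLOT_WIDTH)
    t0 = target_slot * SLOT_WIDTH
    f0 = (1 - target_slot) * SLOT_WIDTH
    out[t0 : t0 + SLOT_WIDTH] = target_vec * gain
    out[f0 : f0 + SLOT_WIDTH] = foil_vec
    return out


def assemble_input(trial: TrialSpec, lexicon: Lexicon) -> InputVector:
    """Place forms/referents into their slots and apply the trial's cues.

    Cues only ever touch the target's own slot (prosody/gesture) or the
    distributional units; foil-slot activations are never modified.
    """
    phonology = _two_slots(
        trial.target.form.astype(np.float64),
        trial.foil_form.form.astype(np.float64),
        trial.target_form_slot,
        2.0 if trial.cues.prosody else 1.0,
    )
    visual = _two_slots(
        trial.target.referent.astype(np.float64),
        trial.foil_referent.referent.astype(np.float64),
        trial.target_object_slot,
        2.0 if trial.cues.gesture else 1.0,
    )
    distributional = np.zeros(2)
    if trial.cues.distributional:
        distributional[0 if trial.target.category == "A" else 1] = 1.0
    return InputVector(phonology=phonology, visual=visual, distributional=distributional)


def make_test_input(
    target_index: int,
    foil_form_index: int,
    foil_referent_index: int,
    slots: tuple[int, int],
    lexicon: Lexicon,
) -> InputVector:
    """Deterministic cue-free input for robustness testing."""
    trial = TrialSpec(
        target=lexicon[target_index],
        foil_form=lexicon[foil_form_index],
        foil_referent=lexicon[foil_referent_index],
        target_form_slot=slots[0],
        target_object_slot=slots[1],
        cues=CueFlags(),
    )
    return assemble_input(trial, lexicon)


@dataclass(frozen=True)
class EpochBatch:
    """Vectorized trial specs for one epoch (or one evaluation sweep)."""

    targets: np.ndarray  # (n,) int
    foil_forms: np.ndarray  # (n,) int, != targets elementwise
    foil_referents: np.ndarray  # (n,) int, != targets elementwise
    form_slots: np.ndarray  # (n,) 0/1
    object_slots: np.ndarray  # (n,) 0/1
    prosody: np.ndarray  # (n,) bool
    gesture: np.ndarray  # (n,) bool
    distributional: np.ndarray  # (n,) bool

    def __len__(self) -> int:
        return self.targets.shape[0]

    def trial_spec(self, i: int, lexicon: Lexicon) -> TrialSpec:
        """Materialize row ``i`` as a TrialSpec (for debugging/equivalence tests)."""
        return TrialSpec(
            target=lexicon[int(self.targets[i])],
            foil_form=lexicon[int(self.foil_forms[i])],
            foil_referent=lexicon[int(self.foil_referents[i])],
            target_form_slot=int(self.form_slots[i]),
            target_object_slot=int(self.object_slots[i]),
            cues=CueFlags(
                prosody=bool(self.prosody[i]),
                gesture=bool(self.gesture[i]),
                distributional=bool(self.distributional[i]),
            ),
        )


def sample_epoch(
    lexicon: Lexicon,
    condition,
    rng: np.random.Generator,
    targets: np.ndarray | None = None,
) -> EpochBatch:
    """Sample one epoch of trials: each word once as target, in random order.

    Pass explicit ``targets`` to override the permutation (used for cue-free
    evaluation sweeps, where targets may repeat).
    """
    n = len(lexicon)
    if targets is None:
        targets = rng.permutation(n)
    m = targets.shape[0]
    ff = rng.integers(0, n - 1, size=m)
    ff = np.where(ff >= targets, ff + 1, ff)
    fr = rng.integers(0, n - 1, size=m)
    fr = np.where(fr >= targets, fr + 1, fr)
    return EpochBatch(
        targets=targets,
        foil_forms=ff,
        foil_referents=fr,
        form_slots=rng.integers(0, 2, size=m),
        object_slots=rng.integers(0, 2, size=m),
        prosody=rng.random(m) < condition.p_prosody,
        gesture=rng.random(m) < condition.p_gesture,
        distributional=rng.random(m) < condition.p_distributional,
    )


def assemble_batch(batch: EpochBatch, lexicon: Lexicon) -> np.ndarray:
    """Assemble all trials of a batch into an (n, 82) input matrix.

    Row ``i`` equals ``assemble_input(batch.trial_spec(i), lexicon).as_array()``.
    """
    m = len(batch)
    X = np.zeros((m, N_INPUT))
    rows = np.arange(m)
    tgt_form = lexicon.forms[batch.targets] * np.where(batch.prosody, 2.0, 1.0)[:, None]
    tgt_ref = lexicon.referents[batch.targets] * np.where(batch.gesture, 2.0, 1.0)[:, None]
    foil_form = lexicon.forms[batch.foil_forms]
    foil_ref = lexicon.referents[batch.foil_referents]
    for slot in (0, 1):
        m_form = batch.form_slots == slot
        X[m_form, slot * 20 : slot * 20 + 20] = tgt_form[m_form]
        X[~m_form, slot * 20 : slot * 20 + 20] = foil_form[~m_form]
        m_obj = batch.object_slots == slot
        X[m_obj, 40 + slot * 20 : 40 + slot * 20 + 20] = tgt_ref[m_obj]
        X[~m_obj, 40 + slot * 20 : 40 + slot * 20 + 20] = foil_ref[~m_obj]
    cat = lexicon.categories[batch.targets]
    X[rows, 80 + cat] = np.where(batch.distributional, 1.0, 0.0)
    return X
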
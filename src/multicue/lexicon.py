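"""Pseudopattern lexicon: phoneme inventory, word forms, referents, categories.

Every representation is a sparse binary vector generated from a seeded RNG so
that a lexicon can be regenerated bit-exactly from its stored seed:

* word forms: 4 phonemes drawn (with replacement) from a 10-phoneme
  inventory; each phoneme is a 2-of-5 binary pattern, so a form is a 20-unit
  vector with 8 active units;
* visual referents: 8-of-20 binary vectors;
* semantics: localist — word ``i`` maps to output unit ``i``;
* categories: a random half of the words is category A, the rest category B
  (the distributional cue signals this split).
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

__all__ = [
    "PhonemeInventory",
    "Word",
    "Lexicon",
    "build_phoneme_inventory",
    "make_word_form",
    "make_visual_pattern",
    "build_lexicon",
    "validate_lexicon",
]

PHONEME_LENGTH = 5
PHONEME_ACTIVE = 2
PHONEMES_PER_WORD = 4
FORM_LENGTH = PHONEME_LENGTH * PHONEMES_PER_WORD  # 20
VISUAL_LENGTH = 20
VISUAL_ACTIVE = 8

_MAX_RESAMPLE = 10_000


@dataclass(frozen=True)
class PhonemeInventory:
    """The full set of 2-of-5 binary phoneme patterns, in randomized order.

    There are exactly C(5, 2) = 10 such patterns, so a 10-phoneme inventory
    of distinct patterns is necessarily all of them.
    """

    patterns: np.ndarray  # (10, 5) uint8

    def __post_init__(self) -> None:
        p = np.asarray(self.patterns, dtype=np.uint8)
        if p.shape != (10, PHONEME_LENGTH):
            raise ValueError(f"expected 10x{PHONEME_LENGTH} patterns, got {p.shape}")
        if not np.all(p.sum(axis=1) == PHONEME_ACTIVE):
            raise ValueError("each phoneme must have exactly 2 of 5 units active")
        if len({tuple(row) for row in p}) != 10:
            raise ValueError("phoneme patterns must be pairwise distinct")
        object.__setattr__(self, "patterns", p)

    def __len__(self) -> int:
        return self.patterns.shape[0]

    def __iter__(self) -> Iterator[np.ndarray]:
        return iter(self.patterns)


@dataclass(frozen=True)
class Word:
    index: int
    form: np.ndarray  # (20,) uint8, 8 active
    referent: np.ndarray  # (20,) uint8, 8 active
    semantic_index: int
    category: str  # "A" or "B"


@dataclass(frozen=True)
class Lexicon:
    words: tuple[Word, ...]
    seed: int
    # dense matrices mirrored from `words` for vectorized trial assembly
    forms: np.ndarray = field(repr=False, default=None)  # (n, 20) float64
    referents: np.ndarray = field(repr=False, default=None)  # (n, 20) float64
    categories: np.ndarray = field(repr=False, default=None)  # (n,) uint8; 0=A, 1=B

    def __post_init__(self) -> None:
        if self.forms is None:
            object.__setattr__(
                self, "forms", np.stack([w.form for w in self.words]).astype(np.float64)
            )
        if self.referents is None:
            object.__setattr__(
                self,
                "referents",
                np.stack([w.referent for w in self.words]).astype(np.float64),
            )
        if self.categories is None:
            object.__setattr__(
                self,
                "categories",
                np.array([0 if w.category == "A" else 1 for w in self.words], dtype=np.uint8),
            )

    def __len__(self) -> int:
        return len(self.words)

    def __getitem__(self, index: int) -> Word:
        return self.words[index]

    def to_json(self) -> str:
        """Serialize to a JSON document for auditing/replay."""
        doc = {
            "seed": self.seed,
            "n_words": len(self.words),
            "words": [
                {
                    "index": w.index,
                    "form": w.form.tolist(),
                    "referent": w.referent.tolist(),
                    "semantic_index": w.semantic_index,
                    "category": w.category,
                }
                for w in self.words
            ],
        }
        return json.dumps(doc)

    @classmethod
    def from_json(cls, text: str) -> "Lexicon":
        doc = json.loads(text)
        words = tuple(
            Word(
                index=w["index"],
                form=np.array(w["form"], dtype=np.uint8),
                referent=np.array(w["referent"], dtype=np.uint8),
                semantic_index=w["semantic_index"],
                category=w["category"],
            )
            for w in doc["words"]
        )
        return cls(words=words, seed=doc["seed"])


def build_phoneme_inventory(rng: np.random.Generator | None = None) -> PhonemeInventory:
    """Return all 10 distinct 2-of-5 phoneme patterns in randomized order."""
    patterns = np.zeros((10, PHONEME_LENGTH), dtype=np.uint8)
    for i, active in enumerate(itertools.combinations(range(PHONEME_LENGTH), PHONEME_ACTIVE)):
        patterns[i, list(active)] = 1
    if rng is not None:
        patterns = patterns[rng.permutation(10)]
    return PhonemeInventory(patterns=patterns)


def make_word_form(inventory: PhonemeInventory, rng: np.random.Generator) -> np.ndarray:
    """Concatenate 4 phonemes sampled uniformly with replacement; 8 of 20 active."""
    idx = rng.integers(0, len(inventory), size=PHONEMES_PER_WORD)
    return inventory.patterns[idx].reshape(FORM_LENGTH).copy()


def make_visual_pattern(rng: np.random.Generator) -> np.ndarray:
    """Uniformly sampled 8-of-20 binary referent pattern."""
    pattern = np.zeros(VISUAL_LENGTH, dtype=np.uint8)
    active = rng.choice(VISUAL_LENGTH, size=VISUAL_ACTIVE, replace=False)
    pattern[active] = 1
    return pattern


def _sample_unique(draw, n: int, what: str) -> list[np.ndarray]:
    """Draw n vectors, resampling on collision until all are unique."""
    seen: set[tuple] = set()
    out: list[np.ndarray] = []
    attempts = 0
    while len(out) < n:
        v = draw()
        key = tuple(v.tolist())
        if key not in seen:
            seen.add(key)
            out.append(v)
        attempts += 1
        if attempts > _MAX_RESAMPLE + n:
            raise RuntimeError(f"could not draw {n} unique {what} patterns")
    return out


def build_lexicon(n_words: int = 100, seed: int = 0) -> Lexicon:
    """Generate a lexicon of ``n_words`` pseudopattern words from ``seed``.

    Word forms and referents are deduplicated across the lexicon (resampled
    on collision). Categories are assigned by a random permutation: the first
    half of the permuted indices become category A, the rest category B.
    """
    if n_words % 2 != 0:
        raise ValueError("n_words must be even (50/50 category split)")
    if n_words > 10 ** PHONEMES_PER_WORD:
        raise ValueError(f"at most {10 ** PHONEMES_PER_WORD} distinct forms exist")
    rng = np.random.default_rng(seed)
    inventory = build_phoneme_inventory(rng)
    forms = _sample_unique(lambda: make_word_form(inventory, rng), n_words, "form")
    referents = _sample_unique(lambda: make_visual_pattern(rng), n_words, "referent")
    category = np.full(n_words, "B")
    category[rng.permutation(n_words)[: n_words // 2]] = "A"
    words = tuple(
        Word(
            index=i,
            form=forms[i],
            referent=referents[i],
            semantic_index=i,
            category=str(category[i]),
        )
        for i in range(n_words)
    )
    lex = Lexicon(words=words, seed=int(seed))
    validate_lexicon(lex)
    return lex


def validate_lexicon(lex: Lexicon) -> None:
    """Assert all structural invariants; raise ValueError on violation."""
    n = len(lex)
    if n % 2 != 0:
        raise ValueError("lexicon size must be even")
    forms = set()
    referents = set()
    n_a = 0
    for i, w in enumerate(lex.words):
        if w.index != i or w.semantic_index != i:
            raise ValueError(f"word {i}: index/semantic_index must equal position")
        if w.form.shape != (FORM_LENGTH,) or int(w.form.sum()) != 8:
            raise ValueError(f"word {i}: form must be 20 units with 8 active")
        for block in w.form.reshape(PHONEMES_PER_WORD, PHONEME_LENGTH):
            if int(block.sum()) != PHONEME_ACTIVE:
                raise ValueError(f"word {i}: each phoneme block must have 2 active units")
        if w.referent.shape != (VISUAL_LENGTH,) or int(w.referent.sum()) != VISUAL_ACTIVE:
            raise ValueError(f"word {i}: referent must be 20 units with 8 active")
        if w.category not in ("A", "B"):
            raise ValueError(f"word {i}: category must be 'A' or 'B'")
        n_a += w.category == "A"
        forms.add(tuple(w.form.tolist()))
        referents.add(tuple(w.referent.tolist()))
    if len(forms) != n:
        raise ValueError("word forms must be pairwise distinct")
    if len(referents) != n:
        raise ValueError("referents must be pairwise distinct")
    if n_a != n // 2:
        raise ValueError("exactly half the words must be category A")
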
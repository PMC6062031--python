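"""Seeded corpus and pattern generators.

Desk-scale stand-ins for the kinds of text an exact matcher is run on:
uniform random streams over alphabets of a few sizes (binary, DNA, protein,
a 64-symbol "large alphabet"), Zipf-distributed word streams emulating
natural language, and DNA/protein sequences.  Planted-pattern fixtures
carry oracle-derived ground truth: after planting, the brute-force matcher
defines the true occurrence set, so accidental or merged occurrences are
accounted for.  Every generator is a pure function of its parameters and
seed.
"""

from __future__ import annotations

import string
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .baselines import brute_force_find_all
from .corpus_io import Text

__all__ = [
    "ALPHABETS",
    "CorpusProfile",
    "gen_uniform_text",
    "gen_zipf_text",
    "gen_corpus",
    "plant_pattern",
    "sample_patterns",
    "PATTERN_CATEGORIES",
]

#: canonical alphabets by profile name
ALPHABETS = {
    "binary": "AB",
    "dna": "ACGT",
    "protein": "ACDEFGHIKLMNPQRSTVWY",
    "alpha64": string.ascii_uppercase + string.ascii_lowercase + string.digits + "+/",
}

#: pattern-length categories (inclusive ranges)
PATTERN_CATEGORIES = {"short": (1, 4), "medium": (5, 8), "long": (9, 16)}


@dataclass(frozen=True)
class CorpusProfile:
    """Declarative description of a synthetic corpus."""

    kind: str  # uniform | zipf-words | dna | protein
    n: int
    seed: int
    alphabet: Optional[str] = None
    vocab_size: int = 1000
    exponent: float = 1.0


def gen_uniform_text(alphabet: Sequence[str], n: int, seed: int) -> Text:
    """``n`` symbols drawn i.i.d. uniformly from ``alphabet``."""
    if len(alphabet) == 0:
        raise ValueError("empty alphabet")
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(alphabet), size=n)
    symbols = "".join(alphabet[i] for i in idx)
    return Text(symbols=symbols, source_id=f"uniform{len(alphabet)}-n{n}-s{seed}")


def _make_vocab(vocab_size: int, rng: np.random.Generator) -> list[str]:
    # short lowercase words, unique, rank order fixed by generation order
    vocab: list[str] = []
    seen = set()
    letters = string.ascii_lowercase
    while len(vocab) < vocab_size:
        length = int(rng.integers(2, 9))
        word = "".join(letters[i] for i in rng.integers(0, 26, size=length))
        if word not in seen:
            seen.add(word)
            vocab.append(word)
    return vocab


def gen_zipf_text(
    vocab_size: int, n_words: int, exponent: float = 1.0, seed: int = 0
) -> Text:
    """Space-separated word stream with Zipf(``exponent``) rank frequencies.

    Word *k* (rank ``k``, 1-based) is drawn with probability proportional
    to ``k**-exponent`` over a seeded synthetic vocabulary.
    """
    if vocab_size < 1:
        raise ValueError("vocab_size must be >= 1")
    if n_words < 0:
        raise ValueError("n_words must be >= 0")
    if exponent <= 0:
        raise ValueError("exponent must be > 0")
    rng = np.random.default_rng(seed)
    vocab = _make_vocab(vocab_size, rng)
    ranks = np.arange(1, vocab_size + 1, dtype=float)
    p = ranks ** -exponent
    p /= p.sum()
    draws = rng.choice(vocab_size, size=n_words, p=p)
    symbols = " ".join(vocab[i] for i in draws)
    return Text(symbols=symbols, source_id=f"zipf{vocab_size}-w{n_words}-s{seed}")


def gen_corpus(profile: CorpusProfile) -> Text:
    """Generate a corpus from a :class:`CorpusProfile`."""
    if profile.kind == "uniform":
        alphabet = profile.alphabet or ALPHABETS["alpha64"]
        return gen_uniform_text(alphabet, profile.n, profile.seed)
    if profile.kind == "dna":
        return gen_uniform_text(ALPHABETS["dna"], profile.n, profile.seed)
    if profile.kind == "protein":
        return gen_uniform_text(ALPHABETS["protein"], profile.n, profile.seed)
    if profile.kind == "zipf-words":
        return gen_zipf_text(profile.vocab_size, profile.n, profile.exponent, profile.seed)
    raise ValueError(f"unknown corpus kind: {profile.kind!r}")


def plant_pattern(
    text: Text, pattern: str, k: int, seed: int
) -> tuple[Text, list[int]]:
    """Overwrite ``k`` seeded non-overlapping windows of ``text`` with
    ``pattern`` and return the modified text with its ground truth.

    Ground truth is the brute-force oracle's occurrence-start list on the
    *modified* text — planting can create accidental extra occurrences or
    merge with pre-existing ones, and the oracle, not ``k``, defines truth.

    Raises
    ------
    ValueError
        If ``k`` non-overlapping windows cannot be placed.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    symbols = text.symbols
    m, n = len(pattern), len(symbols)
    if m > n:
        raise ValueError("pattern longer than text")
    rng = np.random.default_rng(seed)
    candidates = rng.permutation(n - m + 1)
    chosen: list[int] = []
    for s in candidates:
        s = int(s)
        if all(abs(s - c) >= m for c in chosen):
            chosen.append(s)
            if len(chosen) == k:
                break
    if len(chosen) < k:
        raise ValueError(f"cannot place {k} non-overlapping windows of length {m}")
    buf = list(symbols)
    for s in chosen:
        buf[s : s + m] = pattern
    planted = Text(
        symbols="".join(buf),
        source_id=text.source_id + f"+plant({pattern}x{k})",
        encoding=text.encoding,
        mode=text.mode,
    )
    occ, _ = brute_force_find_all(pattern, planted)
    return planted, [o.start for o in occ]


def sample_patterns(text: Text, category: str, count: int, seed: int) -> list[str]:
    """Sample ``count`` substrings of ``text`` with lengths drawn from the
    named category's range (short 1–4, medium 5–8, long 9–16)."""
    if category not in PATTERN_CATEGORIES:
        raise ValueError(f"unknown category: {category!r}")
    lo, hi = PATTERN_CATEGORIES[category]
    n = len(text.symbols)
    if n < hi:
        raise ValueError(f"text of length {n} too short for category {category!r}")
    rng = np.random.default_rng(seed)
    patterns = []
    for _ in range(count):
        m = int(rng.integers(lo, hi + 1))
        s = int(rng.integers(0, n - m + 1))
        patterns.append(text.symbols[s : s + m])
    return patterns
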
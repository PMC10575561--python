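"""Vocabulary representation: padded letter-vector encodings and the
frequency (non-contextual) prior.

Words are lowercase a-z strings. Each word is encoded as a concatenation of
one-hot 26-dimensional letter vectors, zero-padded to the length of the
longest word, so the vocabulary is a ``V x d`` matrix with ``d = 26 * l_max``.
Beliefs over the vocabulary are carried as log-odds relative to a designated
reference word (by convention the last word of the input order); results are
invariant to that choice.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field

import numpy as np

_ALPHABET = string.ascii_lowercase
_LETTER_INDEX = {c: i for i, c in enumerate(_ALPHABET)}


@dataclass(frozen=True)
class Lexicon:
    """Ordered vocabulary with frequencies and letter-vector encodings.

    Attributes
    ----------
    words:
        Unique lowercase alphabetic strings, input order preserved.
    frequencies:
        Positive real frequency per word (arbitrary scale).
    l_max:
        Length of the longest word, in characters.
    encoding:
        ``(V, d)`` float array of padded one-hot letter vectors,
        ``d = 26 * l_max``.
    reference_index:
        Index of the word used as the log-odds reference (``V - 1``).
    """

    words: tuple[str, ...]
    frequencies: np.ndarray
    l_max: int
    encoding: np.ndarray = field(repr=False)
    reference_index: int

    @property
    def V(self) -> int:
        return len(self.words)

    @property
    def d(self) -> int:
        return 26 * self.l_max

    @property
    def lengths(self) -> np.ndarray:
        return np.array([len(w) for w in self.words])

    def index(self, word: str) -> int:
        return self._word_index[word]

    def __contains__(self, word: str) -> bool:
        return word in self._word_index

    def __post_init__(self) -> None:
        object.__setattr__(self, "_word_index", {w: i for i, w in enumerate(self.words)})


def encode_word(word: str, l_max: int) -> np.ndarray:
    """Encode ``word`` as a padded one-hot letter vector of length ``26 * l_max``.

    Position ``j`` (0-based) of the word sets index ``26*j + rank(letter)``;
    letter slots at or beyond the word's length stay all-zero.
    """
    if len(word) > l_max:
        raise ValueError(f"word {word!r} longer than l_max={l_max}")
    vec = np.zeros(26 * l_max)
    for j, ch in enumerate(word):
        try:
            vec[26 * j + _LETTER_INDEX[ch]] = 1.0
        except KeyError:
            raise ValueError(f"non a-z character {ch!r} in word {word!r}") from None
    return vec


def decode_vector(vec: np.ndarray) -> str:
    """Inverse of :func:`encode_word`: argmax per 26-block, stop at an all-zero block."""
    if vec.size % 26 != 0:
        raise ValueError("vector length must be a multiple of 26")
    letters = []
    for block in vec.reshape(-1, 26):
        if not block.any():
            break
        letters.append(_ALPHABET[int(np.argmax(block))])
    return "".join(letters)


def build_lexicon(words: list[str], frequencies: list[float]) -> Lexicon:
    """Build a :class:`Lexicon`, validating words and frequencies.

    Raises ``ValueError`` on duplicate words, non-alphabetic characters,
    empty words, or non-positive frequencies. The reference word for
    log-odds representations is the last word of the input order.
    """
    if len(words) != len(frequencies):
        raise ValueError("words and frequencies must have equal length")
    if not words:
        raise ValueError("lexicon must contain at least one word")
    seen: set[str] = set()
    for w in words:
        if not w:
            raise ValueError("empty word in lexicon")
        if not w.isascii() or not w.isalpha() or w.lower() != w:
            raise ValueError(f"word {w!r} is not lowercase a-z")
        if w in seen:
            raise ValueError(f"duplicate word {w!r}")
        seen.add(w)
    freq = np.asarray(frequencies, dtype=float)
    if np.any(freq <= 0) or not np.all(np.isfinite(freq)):
        bad = words[int(np.argmin(freq))]
        raise ValueError(f"non-positive or non-finite frequency (e.g. for {bad!r})")
    l_max = max(len(w) for w in words)
    encoding = np.stack([encode_word(w, l_max) for w in words])
    return Lexicon(
        words=tuple(words),
        frequencies=freq,
        l_max=l_max,
        encoding=encoding,
        reference_index=len(words) - 1,
    )


def frequency_prior_logodds(lexicon: Lexicon) -> np.ndarray:
    """Prior log-odds (length ``V - 1``) from raw frequencies.

    Entry ``i`` is ``log f_i - log f_ref``; invariant under rescaling all
    frequencies by a common constant.
    """
    logf = np.log(lexicon.frequencies)
    out = logf - logf[lexicon.reference_index]
    return np.delete(out, lexicon.reference_index)


def read_lexicon_tsv(path, header: bool = False) -> Lexicon:
    """Read a two-column ``word<TAB>frequency`` TSV into a Lexicon."""
    words: list[str] = []
    freqs: list[float] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh):
            if header and lineno == 0:
                continue
            line = line.rstrip("\n")
            if not line:
                continue
            try:
                word, freq = line.split("\t")
            except ValueError:
                raise ValueError(f"{path}:{lineno + 1}: expected two tab-separated columns") from None
            words.append(word)
            freqs.append(float(freq))
    return build_lexicon(words, freqs)


def write_lexicon_tsv(lexicon: Lexicon, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for w, f in zip(lexicon.words, lexicon.frequencies):
            fh.write(f"{w}\t{f:g}\n")
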
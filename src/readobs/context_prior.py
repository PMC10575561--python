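"""Contextual prior for the observer, built from a next-word distribution.

The provider's distribution is truncated to its 'nucleus' — the smallest set
of top predictions whose cumulative probability reaches a mass threshold
(default 0.95) — and the remaining tail is assumed flat with an implied
pseudocount of 1 per word. Nucleus probabilities are converted to implied
pseudofrequencies

    freq_i = P_i * (V - k) / (1 - sum_j P_j),

so that the implied nucleus density equals the truncated nucleus mass while
the full observer vocabulary stays usable.
"""

from __future__ import annotations

import logging

import numpy as np

from readobs.lexicon import Lexicon

logger = logging.getLogger(__name__)


def nucleus_truncate(
    probabilities: dict[str, float], mass: float = 0.95
) -> tuple[list[str], np.ndarray, int]:
    """Smallest top-k prefix of the sorted distribution with cumulative
    probability >= ``mass``. Ties in probability break lexicographically."""
    if not 0 < mass < 1:
        raise ValueError("mass must be in (0, 1)")
    if not probabilities:
        raise ValueError("empty distribution")
    probs = np.array(list(probabilities.values()), dtype=float)
    if np.any(probs < 0):
        raise ValueError("negative probability")
    if probs.sum() > 1 + 1e-6:
        raise ValueError(f"probabilities sum to {probs.sum()} > 1")
    items = sorted(probabilities.items(), key=lambda kv: (-kv[1], kv[0]))
    cum = 0.0
    for k, (_, p) in enumerate(items, start=1):
        cum += p
        if cum >= mass - 1e-12:
            break
    else:
        k = len(items)
    words = [w for w, _ in items[:k]]
    return words, np.array([p for _, p in items[:k]]), k


def implied_frequencies(nucleus_probs: np.ndarray, V: int, k: int) -> np.ndarray:
    """Pseudofrequencies for nucleus words given a flat unit-count tail of V-k words."""
    nucleus_probs = np.asarray(nucleus_probs, dtype=float)
    if k >= V:
        raise ValueError(f"nucleus size k={k} must be smaller than vocabulary V={V}")
    total = nucleus_probs.sum()
    if total >= 1:
        raise ValueError(
            f"nucleus mass {total} >= 1 leaves no tail mass; lower the mass threshold"
        )
    return nucleus_probs * (V - k) / (1.0 - total)


def build_contextual_prior(
    lm_distribution: dict[str, float],
    lexicon: Lexicon,
    mass: float = 0.95,
) -> np.ndarray:
    """Prior log-odds (length V-1) over the observer vocabulary from an LM
    next-word distribution.

    Nucleus words absent from the lexicon are dropped; their mass implicitly
    joins the flat tail (the implied-frequency formula is applied with the
    retained nucleus probabilities, unrenormalized). If no nucleus word is in
    the lexicon, a flat prior is returned with a warning.
    """
    nucleus_words, nucleus_probs, _ = nucleus_truncate(lm_distribution, mass=mass)
    kept = [(w, p) for w, p in zip(nucleus_words, nucleus_probs) if w in lexicon]
    # the flat-tail construction needs a non-empty tail with positive mass:
    # demote the lowest-probability nucleus entries until it has one
    while kept and (len(kept) >= lexicon.V or sum(p for _, p in kept) >= 1 - 1e-12):
        kept.pop()
    if not kept:
        logger.warning(
            "no nucleus word present in the observer lexicon; falling back to a flat prior"
        )
        return np.zeros(lexicon.V - 1)
    kept_words = [w for w, _ in kept]
    kept_probs = np.array([p for _, p in kept])
    k = len(kept_words)
    freqs = np.ones(lexicon.V)
    nucleus_freqs = implied_frequencies(kept_probs, lexicon.V, k)
    for w, f in zip(kept_words, nucleus_freqs):
        freqs[lexicon.index(w)] = f
    logf = np.log(freqs)
    out = logf - logf[lexicon.reference_index]
    return np.delete(out, lexicon.reference_index)
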
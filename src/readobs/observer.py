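"""Bayesian ideal observer of parafoveal word identification.

The observer accumulates noisy visual samples of an upcoming word. Each
sample is a draw from a multivariate Gaussian centred on the word's padded
one-hot letter vector, with diagonal covariance whose per-letter variance
grows with eccentricity: sensory quality ``lambda(eps)`` is the Gaussian
integral over the letter's unit bounding box, and the variance of every
dimension of that letter slot is ``lambda(eps) ** noise_exponent``
(default exponent ``-1/2``).

Beliefs over the vocabulary are log-odds relative to a reference word and
are updated by adding the log-odds likelihood of each sample, which is a
linear function of the percept. Because the update is linear, a chain of
``T`` independent samples is equivalent (in distribution) to a single
update with their sum, drawn from ``Normal(T * y_true, T * Sigma)``; the
default ``method="aggregate"`` exploits this, while ``method="chain"``
performs the literal per-sample loop (used for oracle equivalence tests).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.special import ndtr

from readobs._rng import stable_seed
from readobs.lexicon import Lexicon

#: lambda is floored here before exponentiation so far-eccentric slots get a
#: finite (huge) variance instead of NaN/inf; at the floor the update
#: contribution is numerically negligible.
LAMBDA_FLOOR = 1e-12


class OutOfLexiconError(KeyError):
    """Raised when a corpus word has no entry in the observer vocabulary."""

    def __init__(self, word: str):
        super().__init__(word)
        self.word = word


@dataclass(frozen=True)
class PerceptualSpan:
    """Eccentricity-dependent sensory quality parameters."""

    sigma: float = 3.0
    Lambda: float = 1.0
    noise_exponent: float = -0.5

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.Lambda <= 0:
            raise ValueError("Lambda must be > 0")


@dataclass(frozen=True)
class ObserverConfig:
    """Sampling budget: T samples per run, `repeats` independent runs averaged."""

    T: int = 50
    repeats: int = 3
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.T < 0:
            raise ValueError("T must be >= 0")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")


@dataclass
class BeliefState:
    """Log-odds of each word versus the lexicon's reference word (length V-1)."""

    logodds: np.ndarray
    lexicon: Lexicon

    def __post_init__(self) -> None:
        self.logodds = np.asarray(self.logodds, dtype=float)
        if self.logodds.shape != (self.lexicon.V - 1,):
            raise ValueError(
                f"logodds must have length V-1={self.lexicon.V - 1}, got {self.logodds.shape}"
            )
        if not np.all(np.isfinite(self.logodds)):
            raise ValueError("non-finite log-odds")


@dataclass(frozen=True)
class ObserverOutput:
    prior_entropy: float
    posterior_entropy: float
    info_gain: float
    eccentricity: float
    word_token: object = None


def sensory_quality(eccentricity, span: PerceptualSpan):
    """Sensory quality lambda at a letter eccentricity (characters).

    ``Lambda * (Phi((eps+0.5)/sigma) - Phi((eps-0.5)/sigma))``; symmetric in
    eccentricity and strictly decreasing in its magnitude.
    """
    eps = np.asarray(eccentricity, dtype=float)
    lam = span.Lambda * (ndtr((eps + 0.5) / span.sigma) - ndtr((eps - 0.5) / span.sigma))
    return lam if lam.ndim else float(lam)


def slot_eccentricities(launch_distance: float, l_max: int) -> np.ndarray:
    """Eccentricity of each letter slot: slot j sits j characters right of the
    word's first character, which is `launch_distance` right of fixation."""
    return launch_distance + np.arange(l_max, dtype=float)


def _dim_variances(eccentricities: np.ndarray, span: PerceptualSpan) -> np.ndarray:
    """Per-dimension sampling variance: each slot's 26 dims share its lambda."""
    lam = np.maximum(np.asarray(sensory_quality(eccentricities, span), dtype=float), LAMBDA_FLOOR)
    return np.repeat(lam**span.noise_exponent, 26)


def sample_percept(
    true_vector: np.ndarray,
    eccentricities: np.ndarray,
    span: PerceptualSpan,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw one noisy visual sample centred on the true letter vector."""
    true_vector = np.asarray(true_vector, dtype=float)
    var = _dim_variances(eccentricities, span)
    if var.size != true_vector.size:
        raise ValueError("eccentricities must supply one entry per letter slot")
    return rng.normal(true_vector, np.sqrt(var))


def update_belief(
    belief: BeliefState,
    percept: np.ndarray,
    lexicon: Lexicon,
    span: PerceptualSpan,
    eccentricities: np.ndarray,
) -> BeliefState:
    """Add the log-odds likelihood of one percept to the belief.

    For word i: ``dx_i = (y_v' S^-1 y_v - y_i' S^-1 y_i)/2 + (y_i - y_v)' S^-1 I``
    with S the diagonal sampling covariance.
    """
    percept = np.asarray(percept, dtype=float)
    if percept.shape != (lexicon.d,):
        raise ValueError(f"percept must have length d={lexicon.d}")
    precision = 1.0 / _dim_variances(eccentricities, span)
    W = lexicon.encoding
    ref = lexicon.reference_index
    quad = W @ precision  # one-hot: y_i' S^-1 y_i = sum of precisions at active dims
    proj = W @ (precision * percept)
    delta = (quad[ref] - quad) / 2.0 + (proj - proj[ref])
    delta = np.delete(delta, ref)
    return replace(belief, logodds=belief.logodds + delta)


def posterior_distribution(belief: BeliefState | np.ndarray, reference_index: int | None = None) -> np.ndarray:
    """Probabilities over all V words implied by V-1 log-odds (overflow-safe)."""
    if isinstance(belief, BeliefState):
        logodds = belief.logodds
        reference_index = belief.lexicon.reference_index
    else:
        logodds = np.asarray(belief, dtype=float)
        if reference_index is None:
            reference_index = logodds.size  # reference last by default
    x = np.insert(logodds, reference_index, 0.0)
    x = x - x.max()
    ex = np.exp(x)
    return ex / ex.sum()


def entropy_bits(p: np.ndarray) -> float:
    """Shannon entropy in bits, with 0 * log 0 = 0."""
    p = np.asarray(p, dtype=float)
    if np.any(p < 0):
        raise ValueError("negative probabilities")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"probabilities sum to {p.sum()}, not 1")
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


def _aggregate_logodds(
    prior_logodds: np.ndarray,
    true_vector: np.ndarray,
    eccentricities: np.ndarray,
    lexicon: Lexicon,
    span: PerceptualSpan,
    T: int,
    repeats: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Posterior log-odds for `repeats` independent T-sample chains at once.

    Uses the sufficient statistic S = sum of T percepts ~ N(T*y, T*Sigma);
    the summed log-odds likelihood is linear in S. Returns (repeats, V-1).
    """
    var = _dim_variances(eccentricities, span)
    precision = 1.0 / var
    W = lexicon.encoding
    ref = lexicon.reference_index
    quad = W @ precision
    if T == 0:
        return np.tile(prior_logodds, (repeats, 1))
    S = rng.normal(T * true_vector, np.sqrt(T * var), size=(repeats, true_vector.size))
    proj = (precision * S) @ W.T  # (repeats, V)
    delta = T * (quad[ref] - quad) / 2.0 + (proj - proj[:, ref : ref + 1])
    delta = np.delete(delta, ref, axis=1)
    return prior_logodds + delta


def preview_entropy(
    word: str,
    launch_distance: float,
    prior_logodds: np.ndarray,
    lexicon: Lexicon,
    span: PerceptualSpan,
    config: ObserverConfig,
    rng: np.random.Generator | None = None,
    method: str = "aggregate",
    word_token=None,
) -> ObserverOutput:
    """Parafoveal identifiability of `word` previewed from `launch_distance`.

    Runs ``config.repeats`` independent chains of ``config.T`` samples from
    the given prior; letter slot j of the word sits at eccentricity
    ``launch_distance + j``. Posterior entropy is the mean over repeats of
    the Shannon entropy of each chain's posterior; info gain is prior minus
    posterior entropy.
    """
    if word not in lexicon:
        raise OutOfLexiconError(word)
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    true_vector = lexicon.encoding[lexicon.index(word)]
    eccs = slot_eccentricities(launch_distance, lexicon.l_max)
    prior_logodds = np.asarray(prior_logodds, dtype=float)
    prior_entropy = entropy_bits(posterior_distribution(prior_logodds, lexicon.reference_index))

    if method == "aggregate":
        post = _aggregate_logodds(
            prior_logodds, true_vector, eccs, lexicon, span, config.T, config.repeats, rng
        )
        entropies = [
            entropy_bits(posterior_distribution(post[r], lexicon.reference_index))
            for r in range(config.repeats)
        ]
    elif method == "chain":
        entropies = []
        for _ in range(config.repeats):
            belief = BeliefState(logodds=prior_logodds.copy(), lexicon=lexicon)
            for _ in range(config.T):
                percept = sample_percept(true_vector, eccs, span, rng)
                belief = update_belief(belief, percept, lexicon, span, eccs)
            entropies.append(entropy_bits(posterior_distribution(belief)))
    else:
        raise ValueError(f"unknown method {method!r}")

    posterior_entropy = float(np.mean(entropies))
    return ObserverOutput(
        prior_entropy=prior_entropy,
        posterior_entropy=posterior_entropy,
        info_gain=prior_entropy - posterior_entropy,
        eccentricity=launch_distance,
        word_token=word_token,
    )


def preview_entropy_for_token(
    word: str,
    launch_distance: float,
    prior_logodds: np.ndarray,
    lexicon: Lexicon,
    span: PerceptualSpan,
    config: ObserverConfig,
    key: tuple,
) -> ObserverOutput:
    """Like :func:`preview_entropy`, but seeded per token.

    ``key`` identifies the token (e.g. ``(participant, text_id, word_index)``);
    the generator is derived from ``config.rng_seed`` and the key by stable
    hashing, so outputs are reproducible and independent of evaluation order.
    """
    rng = np.random.default_rng(stable_seed(config.rng_seed, "observer", *key))
    return preview_entropy(
        word, launch_distance, prior_logodds, lexicon, span, config, rng=rng, word_token=key
    )
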
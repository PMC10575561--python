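"""Synthetic reading corpora with known ground truth.

Generates a Zipfian lexicon (longer words rarer), a bigram 'language model'
provider with nucleus/surprisal/entropy per token, and simulated readers:
left-to-right saccades whose skipping follows a logistic rule in word
length, launch distance and (optionally) predictive/parafoveal entropies;
landing positions left of word centre; gaze durations linear in surprisal,
preview entropy and log-frequency plus noise; and occasional regressions
back to poorly-previewed skipped words.

The generator uses the same observer machinery and per-token seed derivation
as the analysis pipeline, so an analysis run with the same master seed sees
exactly the features the generator used — implanted coefficients are then
recoverable without errors-in-variables attenuation.
"""

from __future__ import annotations

import json
import string
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from readobs._rng import derived_rng
from readobs.context_prior import build_contextual_prior
from readobs.lexicon import Lexicon, build_lexicon, frequency_prior_logodds, write_lexicon_tsv
from readobs.observer import (
    ObserverConfig,
    PerceptualSpan,
    preview_entropy_for_token,
)

WORD_CLASSES = ("function", "noun", "verb", "adjective")


@dataclass
class GeneratorParams:
    """Ground-truth parameters of the synthetic reading process.

    Skip and duration coefficients are on raw predictor units (characters,
    bits, log-counts); durations are in ms.
    """

    V: int = 300
    zipf_exponent: float = 1.1
    length_range: tuple[int, int] = (2, 9)
    bigram_concentration: float = 1.0
    lm_support_size: int | None = None  # per-context support; decorrelates context from frequency

    skip_intercept: float = 2.2
    skip_length: float = -0.45
    skip_launch: float = -0.3
    skip_pred_entropy: float = 0.0
    skip_para_entropy: float = 0.0

    landing_frac: float = 0.4  # preferred landing position, fraction of word length
    landing_sd_base: float = 0.6
    landing_sd_slope: float = 0.06  # per character of launch distance

    dur_intercept: float = 280.0  # keeps the noise window [70, 900] from binding
    dur_surprisal: tuple[float, float, float] = (6.0, 2.0, 1.0)
    dur_para_entropy: float = 8.0
    dur_log_freq: tuple[float, float, float] = (-4.0, -1.5, -0.5)
    word_class_offsets: dict = field(
        default_factory=lambda: {"function": 0.0, "noun": 10.0, "verb": 5.0, "adjective": 8.0}
    )
    dur_landing_abs: float = 3.0
    dur_residual_sd: float = 40.0

    comp_intercept: float = -2.5
    comp_para_entropy: float = 0.6  # refixation of skipped words vs pre-skip entropy

    n_participants: int = 20
    words_per_participant: int = 5000
    words_per_text: int = 12
    contextual_durations: bool = False  # drive durations by the contextual observer's entropy


def make_lexicon(V: int, zipf_exponent: float, length_range: tuple[int, int], seed: int) -> Lexicon:
    """Random unique letter-string lexicon with Zipfian frequencies and a
    negative length/log-frequency correlation."""
    if V < 10:
        raise ValueError("V must be >= 10")
    lo, hi = length_range
    rng = derived_rng(seed, "lexicon")
    ranks = np.arange(1, V + 1)
    freqs = 1e6 * ranks ** (-float(zipf_exponent))
    # length climbs with rank (rarer -> longer), with jitter
    base = lo + (hi - lo) * np.log(ranks) / np.log(V)
    lengths = np.clip(np.round(base + rng.normal(0, 0.8, size=V)), lo, hi).astype(int)
    capacity = sum(26**n for n in range(lo, hi + 1))
    if V > capacity:
        raise ValueError(f"cannot draw {V} unique words with lengths in {length_range}")
    words: list[str] = []
    seen: set[str] = set()
    letters = np.array(list(string.ascii_lowercase))
    for n in lengths:
        for attempt in range(1000):
            w = "".join(rng.choice(letters, size=int(n)))
            if w not in seen:
                break
        else:
            raise ValueError("could not draw a unique word; length range too tight")
        seen.add(w)
        words.append(w)
    return build_lexicon(words, freqs.tolist())


def word_classes(lexicon: Lexicon) -> dict[str, str]:
    """Deterministic 4-level class label per word: the most frequent decile is
    'function', the rest split by a stable hash of the word."""
    import hashlib

    order = np.argsort(-lexicon.frequencies)
    n_func = max(1, lexicon.V // 10)
    classes: dict[str, str] = {}
    func_set = {lexicon.words[i] for i in order[:n_func]}
    for w in lexicon.words:
        if w in func_set:
            classes[w] = "function"
        else:
            h = int.from_bytes(hashlib.blake2b(w.encode(), digest_size=4).digest(), "little")
            classes[w] = WORD_CLASSES[1 + h % 3]
    return classes


class SyntheticLM:
    """Bigram next-word provider over a lexicon.

    Row ``i`` of the bigram table is a Dirichlet draw centred on the unigram
    (frequency) distribution; larger ``concentration`` keeps rows closer to
    the unigram. Text-initial tokens use the unigram row (context index -1).
    """

    def __init__(
        self,
        lexicon: Lexicon,
        concentration: float,
        seed: int,
        nucleus_mass: float = 0.95,
        support_size: int | None = None,
    ):
        self.lexicon = lexicon
        self.nucleus_mass = nucleus_mass
        rng = derived_rng(seed, "lm")
        unigram = lexicon.frequencies / lexicon.frequencies.sum()
        self.unigram = unigram
        if support_size is None:
            alpha = concentration * lexicon.V * unigram
            rows = rng.gamma(np.tile(alpha, (lexicon.V, 1)))
        else:
            # each context predicts a random word subset: contextual
            # distributions decorrelate from the unigram while keeping
            # comparable entropy
            if not 1 < support_size <= lexicon.V:
                raise ValueError("support_size must be in (1, V]")
            rows = np.zeros((lexicon.V, lexicon.V))
            for i in range(lexicon.V):
                support = rng.choice(lexicon.V, size=support_size, replace=False)
                rows[i, support] = rng.gamma(concentration, size=support_size)
        self.bigram = rows / rows.sum(axis=1, keepdims=True)
        self._nucleus_cache: dict[int, tuple[np.ndarray, int]] = {}
        self._entropy_cache: dict[int, float] = {}
        self._prior_cache: dict[int, np.ndarray] = {}

    def next_dist(self, context: int) -> np.ndarray:
        return self.unigram if context < 0 else self.bigram[context]

    def _nucleus(self, context: int) -> tuple[np.ndarray, int]:
        """Sorted nucleus word indices and nucleus size k at the mass threshold."""
        if context not in self._nucleus_cache:
            p = self.next_dist(context)
            order = np.argsort(-p, kind="stable")
            cum = np.cumsum(p[order])
            k = int(np.searchsorted(cum, self.nucleus_mass - 1e-12) + 1)
            k = min(k, p.size)
            self._nucleus_cache[context] = (order[:k], k)
        return self._nucleus_cache[context]

    def nucleus_pairs(self, context: int) -> list[list]:
        idx, _ = self._nucleus(context)
        p = self.next_dist(context)
        return [[self.lexicon.words[i], float(p[i])] for i in idx]

    def surprisal_bits(self, context: int, word_index: int) -> float:
        return float(-np.log2(self.next_dist(context)[word_index]))

    def entropy_bits(self, context: int) -> float:
        """Predictive entropy of the nucleus + flat-tail representation."""
        if context not in self._entropy_cache:
            p = self.next_dist(context)
            idx, k = self._nucleus(context)
            nucleus = p[idx]
            n_tail = p.size - k
            parts = [nucleus]
            if n_tail > 0:
                tail_mass = max(1.0 - nucleus.sum(), 0.0)
                parts.append(np.full(n_tail, tail_mass / n_tail))
            q = np.concatenate(parts)
            q = q / q.sum()
            nz = q[q > 0]
            self._entropy_cache[context] = float(-(nz * np.log2(nz)).sum())
        return self._entropy_cache[context]

    def contextual_prior(self, context: int) -> np.ndarray:
        if context not in self._prior_cache:
            dist = {
                self.lexicon.words[i]: float(p)
                for i, p in enumerate(self.next_dist(context))
                if p > 0
            }
            self._prior_cache[context] = build_contextual_prior(
                dist, self.lexicon, mass=self.nucleus_mass
            )
        return self._prior_cache[context]

    def sample_texts(self, n_words: int, words_per_text: int, seed: int) -> list[list[int]]:
        """Sample word-index sequences; each text starts from the unigram."""
        rng = derived_rng(seed, "text")
        texts: list[list[int]] = []
        drawn = 0
        while drawn < n_words:
            n = min(words_per_text, n_words - drawn)
            text: list[int] = []
            context = -1
            for _ in range(n):
                w = int(rng.choice(self.lexicon.V, p=self.next_dist(context)))
                text.append(w)
                context = w
            texts.append(text)
            drawn += n
        return texts


def _sigmoid(x: float) -> float:
    return float(1.0 / (1.0 + np.exp(-x)))


def simulate_reader(
    texts: list[list[int]],
    lexicon: Lexicon,
    lm: SyntheticLM,
    params: GeneratorParams,
    span: PerceptualSpan,
    observer_config: ObserverConfig,
    participant: str,
    seed: int,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate one reader over the texts.

    Returns (words, fixations, ground_truth) frames in the canonical corpus
    schema. Observer entropies are computed with per-token seeds derived
    from ``observer_config.rng_seed``, identically to the analysis pipeline.
    """
    rng = derived_rng(seed, "reader", participant)
    classes = word_classes(lexicon)
    freq_prior = frequency_prior_logodds(lexicon)
    need_observer = (
        params.skip_para_entropy != 0.0
        or params.dur_para_entropy != 0.0
        or params.comp_para_entropy != 0.0
    )

    word_rows: list[dict] = []
    fix_rows: list[dict] = []
    truth_rows: list[dict] = []

    for ti, text in enumerate(texts):
        text_id = f"t{ti:04d}"
        # trailing non-alphabetic anchor: always fixated, so text-final real
        # words get genuine skip decisions; the analysis-side non-alphabetic
        # filter removes the anchor itself.
        n_real = len(text)
        words = [lexicon.words[w] for w in text] + ["#"]
        n = n_real + 1
        anchor = n_real
        lengths = np.array([len(w) for w in words])
        first = np.concatenate([[0], np.cumsum(lengths + 1)[:-1]]).astype(float)
        for k in range(n):
            word_rows.append(
                {
                    "participant": participant,
                    "text_id": text_id,
                    "line_id": 0,
                    "word_index": k,
                    "word": words[k],
                    "first_char": int(first[k]),
                    "word_class": classes[words[k]] if k < n_real else "function",
                }
            )

        surp = np.array(
            [lm.surprisal_bits(text[k - 1] if k > 0 else -1, text[k]) for k in range(n_real)]
            + [0.0]
        )
        pred_ent = np.array(
            [lm.entropy_bits(text[k - 1] if k > 0 else -1) for k in range(n_real)] + [0.0]
        )
        logf = np.array([np.log(lexicon.frequencies[w]) for w in text] + [0.0])

        pe_cache: dict[int, float] = {}

        def para_entropy(k: int, launch: float) -> float:
            if not need_observer:
                return float("nan")
            if k in pe_cache:
                return pe_cache[k]
            prior = (
                lm.contextual_prior(text[k - 1] if k > 0 else -1)
                if params.contextual_durations
                else freq_prior
            )
            out = preview_entropy_for_token(
                words[k], launch, prior, lexicon, span, observer_config,
                key=(participant, text_id, k),
            )
            pe_cache[k] = out.posterior_entropy
            return pe_cache[k]

        order = 0
        skipped_info: list[tuple[int, float]] = []  # (word index, pre-skip parafoveal entropy)
        truth: list[dict] = [
            {
                "participant": participant,
                "text_id": text_id,
                "word_index": k,
                "word": words[k],
                "length": int(lengths[k]),
                "word_class": classes[words[k]] if k < n_real else "function",
                "surprisal_0": surp[k],
                "surprisal_1": surp[k - 1] if k >= 1 else np.nan,
                "surprisal_2": surp[k - 2] if k >= 2 else np.nan,
                "pred_entropy": pred_ent[k],
                "log_freq_0": logf[k],
                "log_freq_1": logf[k - 1] if k >= 1 else np.nan,
                "log_freq_2": logf[k - 2] if k >= 2 else np.nan,
                "para_entropy": np.nan,
                "launch_distance": np.nan,
                "skip_prob": np.nan,
                "skipped": np.nan,
                "landing_offset": np.nan,
                "gaze_mean": np.nan,
                "gaze_duration": np.nan,
                "refix_prob": np.nan,
                "refixated": 0.0,
            }
            for k in range(n)
        ]

        def land_and_fixate(k: int, launch: float | None) -> float:
            """Draw landing and duration for word k; returns the landing x."""
            sd = params.landing_sd_base + params.landing_sd_slope * (abs(launch) if launch else 0.0)
            target = first[k] + params.landing_frac * lengths[k]
            x = rng.normal(target, sd)
            # round to the written file precision so analysis-side launch
            # distances (and hence re-derived observer see/entropy values)
            # match the generator's exactly
            x = round(float(np.clip(x, first[k], first[k] + lengths[k] - 1)), 4)
            offset = x - (first[k] + (lengths[k] - 1) / 2.0)
            nonlocal order
            if k == anchor:
                fix_rows.append(
                    {
                        "participant": participant,
                        "text_id": text_id,
                        "line_id": 0,
                        "order": order,
                        "x_char": round(x, 4),
                        "duration_ms": round(float(rng.uniform(150, 250)), 3),
                        "blink_adjacent": 0,
                    }
                )
                order += 1
                return x
            pe = para_entropy(k, launch) if launch is not None else np.nan
            mean = (
                params.dur_intercept
                + params.dur_surprisal[0] * surp[k]
                + (params.dur_surprisal[1] * surp[k - 1] if k >= 1 else 0.0)
                + (params.dur_surprisal[2] * surp[k - 2] if k >= 2 else 0.0)
                + (params.dur_para_entropy * pe if np.isfinite(pe) else 0.0)
                + params.dur_log_freq[0] * logf[k]
                + (params.dur_log_freq[1] * logf[k - 1] if k >= 1 else 0.0)
                + (params.dur_log_freq[2] * logf[k - 2] if k >= 2 else 0.0)
                + params.word_class_offsets[classes[words[k]]]
                + params.dur_landing_abs * abs(offset)
            )
            if params.dur_residual_sd > 0:
                dur = rng.normal(mean, params.dur_residual_sd)
                for _ in range(100):  # resample (not clip) into the plausible window
                    if 70.0 <= dur <= 900.0:
                        break
                    dur = rng.normal(mean, params.dur_residual_sd)
                else:
                    dur = float(np.clip(dur, 70.0, 900.0))
            else:
                dur = mean
            fix_rows.append(
                {
                    "participant": participant,
                    "text_id": text_id,
                    "line_id": 0,
                    "order": order,
                    "x_char": round(x, 4),
                    "duration_ms": round(float(dur), 3),
                    "blink_adjacent": 0,
                }
            )
            order += 1
            truth[k].update(
                launch_distance=launch if launch is not None else np.nan,
                para_entropy=pe,
                skipped=0.0 if launch is not None else np.nan,
                landing_offset=offset,
                gaze_mean=mean,
                gaze_duration=float(dur),
            )
            return x

        x = land_and_fixate(0, None)
        i = 0
        while i < anchor:
            j = i + 1
            while j < anchor:
                launch = first[j] - x
                pe = para_entropy(j, launch)
                logit = (
                    params.skip_intercept
                    + params.skip_length * lengths[j]
                    + params.skip_launch * launch
                    + (params.skip_pred_entropy * pred_ent[j] if params.skip_pred_entropy else 0.0)
                    + (params.skip_para_entropy * pe if params.skip_para_entropy and np.isfinite(pe) else 0.0)
                )
                p_skip = _sigmoid(logit)
                do_skip = rng.random() < p_skip
                truth[j].update(
                    launch_distance=launch,
                    para_entropy=pe,
                    skip_prob=p_skip,
                    skipped=1.0 if do_skip else 0.0,
                )
                if not do_skip:
                    break
                skipped_info.append((j, pe))
                j += 1
            x = land_and_fixate(j, first[j] - x)
            i = j

        # compensation: regressive refixations of poorly-previewed skipped words
        for k, pe in skipped_info:
            logit = params.comp_intercept + (
                params.comp_para_entropy * pe if np.isfinite(pe) else 0.0
            )
            p_refix = _sigmoid(logit)
            refix = rng.random() < p_refix
            truth[k].update(refix_prob=p_refix, refixated=1.0 if refix else 0.0)
            if refix:
                fix_rows.append(
                    {
                        "participant": participant,
                        "text_id": text_id,
                        "line_id": 0,
                        "order": order,
                        "x_char": round(float(first[k] + (lengths[k] - 1) / 2.0), 3),
                        "duration_ms": 180.0,
                        "blink_adjacent": 0,
                    }
                )
                order += 1
        truth_rows.extend(truth)

    words_df = pd.DataFrame(word_rows)
    fix_df = pd.DataFrame(fix_rows)
    truth_df = pd.DataFrame(truth_rows)
    return words_df, fix_df, truth_df


def write_nucleus_jsonl(texts: list[list[int]], lm: SyntheticLM, path) -> None:
    """Per-token language-model artifact: nucleus, surprisal and entropy."""
    with open(path, "w", encoding="utf-8") as fh:
        token_index = 0
        for ti, text in enumerate(texts):
            text_id = f"t{ti:04d}"
            for k, w in enumerate(text):
                context = text[k - 1] if k > 0 else -1
                rec = {
                    "token_index": token_index,
                    "text_id": text_id,
                    "word_index": k,
                    "word": lm.lexicon.words[w],
                    "nucleus": lm.nucleus_pairs(context),
                    "surprisal_bits": lm.surprisal_bits(context, w),
                    "entropy_bits": lm.entropy_bits(context),
                }
                fh.write(json.dumps(rec) + "\n")
                token_index += 1


def generate_study(
    params: GeneratorParams,
    span: PerceptualSpan,
    observer_config: ObserverConfig,
    outdir,
    master_seed: int = 0,
) -> dict:
    """Generate a full study: shared texts, per-participant readings, nucleus
    file, ground truth and a manifest of all seeds. Returns the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    lexicon = make_lexicon(params.V, params.zipf_exponent, params.length_range, master_seed)
    lm = SyntheticLM(
        lexicon, params.bigram_concentration, master_seed, support_size=params.lm_support_size
    )
    texts = lm.sample_texts(params.words_per_participant, params.words_per_text, master_seed)

    all_words, all_fix, all_truth = [], [], []
    for p in range(params.n_participants):
        participant = f"p{p:02d}"
        w, f, t = simulate_reader(
            texts, lexicon, lm, params, span, observer_config, participant, master_seed
        )
        all_words.append(w)
        all_fix.append(f)
        all_truth.append(t)
    pd.concat(all_words, ignore_index=True).to_csv(outdir / "words.tsv", sep="\t", index=False)
    pd.concat(all_fix, ignore_index=True).to_csv(outdir / "fixations.tsv", sep="\t", index=False)
    pd.concat(all_truth, ignore_index=True).to_csv(outdir / "ground_truth.tsv", sep="\t", index=False)
    write_nucleus_jsonl(texts, lm, outdir / "nucleus.jsonl")
    write_lexicon_tsv(lexicon, outdir / "lexicon.tsv")
    manifest = {
        "master_seed": master_seed,
        "observer_seed": observer_config.rng_seed,
        "params": {k: v for k, v in asdict(params).items()},
        "span": {"sigma": span.sigma, "Lambda": span.Lambda, "noise_exponent": span.noise_exponent},
        "observer": {"T": observer_config.T, "repeats": observer_config.repeats},
        "n_texts": len(texts),
    }
    with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, default=list)
    return manifest
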
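"""Linguistic prediction features and per-token predictor tables.

Builds the two analysis tables from filtered first-pass measures, observer
outputs, and language-model features:

* skipping rows: outcome ``skip`` with predictive entropy, parafoveal
  entropy, word length and launch distance;
* duration rows: outcome ``gaze_duration_ms`` with surprisal (current word
  and two preceding text words), parafoveal entropy, word class, length,
  log-frequency (current plus the same two lags), and landing offsets.

Continuous predictors are standardized to participant-specific z-scores; the
moments are retained so effect sizes can be reported back in natural units.
"""

from __future__ import annotations

from collections.abc import Iterable

import numpy as np
import pandas as pd

SKIP_PREDICTORS = ["predictive_entropy_bits", "parafoveal_entropy_bits", "length", "launch_distance"]
DURATION_PREDICTORS = [
    "surprisal_0",
    "surprisal_1",
    "surprisal_2",
    "parafoveal_entropy_bits",
    "length",
    "log_freq_0",
    "log_freq_1",
    "log_freq_2",
    "landing_offset_chars",
    "landing_offset_frac",
]


def word_surprisal(word_probability) -> float:
    """Surprisal in bits, ``-log2 p``. A sequence of constituent-token
    probabilities is combined into the joint probability first."""
    if isinstance(word_probability, Iterable) and not isinstance(word_probability, (str, bytes)):
        p = float(np.prod(list(word_probability)))
    else:
        p = float(word_probability)
    if not 0 < p <= 1:
        raise ValueError(f"probability must be in (0, 1], got {p}")
    return float(-np.log2(p))


def predictive_entropy(nucleus_probs, n_tail: int = 0) -> float:
    """Shannon entropy (bits) of a next-word distribution represented as
    nucleus probabilities plus ``n_tail`` equal-probability tail words."""
    nucleus = np.asarray(nucleus_probs, dtype=float)
    if nucleus.size == 0:
        raise ValueError("empty distribution")
    if np.any(nucleus < 0):
        raise ValueError("negative probability")
    tail_mass = 1.0 - nucleus.sum()
    if n_tail > 0:
        p = np.concatenate([nucleus, np.full(n_tail, max(tail_mass, 0.0) / n_tail)])
    else:
        p = nucleus
    total = p.sum()
    if abs(total - 1.0) > 1e-6:
        raise ValueError(f"distribution sums to {total}, not 1")
    p = p / total
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


def assemble_predictors(
    measures: pd.DataFrame,
    observer_outputs: pd.DataFrame,
    lm_features: pd.DataFrame,
    lexicon,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Join measures, observer outputs and LM features into the two tables.

    ``measures`` must carry ``include_skip`` / ``include_duration`` flags
    (see :func:`readobs.corpus.apply_exclusions`). ``observer_outputs`` is
    keyed by (participant, text_id, word_index) with a
    ``posterior_entropy_bits`` column; ``lm_features`` by (text_id,
    word_index) with ``surprisal_bits`` and ``entropy_bits``.
    """
    keys = ["participant", "text_id", "word_index"]
    obs = observer_outputs[keys + ["posterior_entropy_bits"]].rename(
        columns={"posterior_entropy_bits": "parafoveal_entropy_bits"}
    )
    df = measures.merge(obs, on=keys, how="left")
    retained = df["include_skip"]
    if df.loc[retained, "parafoveal_entropy_bits"].isna().any():
        missing = df.loc[retained & df["parafoveal_entropy_bits"].isna(), keys].iloc[0]
        raise ValueError(
            f"missing observer output for retained token {tuple(missing)}; "
            "observer stage must run before assembly"
        )
    lm = lm_features.set_index(["text_id", "word_index"])
    lm_key = pd.MultiIndex.from_frame(df[["text_id", "word_index"]])
    df["surprisal_0"] = lm["surprisal_bits"].reindex(lm_key).to_numpy()
    df["predictive_entropy_bits"] = lm["entropy_bits"].reindex(lm_key).to_numpy()

    logf = {w: np.log(f) for w, f in zip(lexicon.words, lexicon.frequencies)}
    df["log_freq_0"] = df["word"].str.lower().map(logf)

    # spillover lags from the two preceding text words, fixated or not
    for lag in (1, 2):
        lag_key = pd.MultiIndex.from_arrays([df["text_id"], df["word_index"] - lag])
        df[f"surprisal_{lag}"] = lm["surprisal_bits"].reindex(lag_key).to_numpy()
        lagged_word = (
            df.set_index(["participant", "text_id", "word_index"])["word"]
            .reindex(
                pd.MultiIndex.from_arrays([df["participant"], df["text_id"], df["word_index"] - lag])
            )
            .to_numpy()
        )
        df[f"log_freq_{lag}"] = pd.Series(lagged_word).str.lower().map(logf).to_numpy()

    skip_table = df.loc[
        df["include_skip"] & df["predictive_entropy_bits"].notna(),
        keys + ["skipped_first_pass"] + SKIP_PREDICTORS,
    ].rename(columns={"skipped_first_pass": "skip"})
    skip_table["skip"] = skip_table["skip"].astype(int)

    dur_cols = keys + ["gaze_duration_ms", "word_class"] + DURATION_PREDICTORS
    dur_mask = df["include_duration"]
    for col in DURATION_PREDICTORS:
        dur_mask &= df[col].notna()
    duration_table = df.loc[dur_mask, dur_cols]
    return skip_table.reset_index(drop=True), duration_table.reset_index(drop=True)


def standardize_within_participant(
    table: pd.DataFrame,
    predictors: list[str],
    categorical: list[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Z-score continuous predictors per participant; expand categoricals to
    0/1 indicator contrasts (first level dropped). Outcomes are untouched.

    Returns the transformed table and a moments table (participant,
    predictor, mean, sd) for back-transformation.
    """
    out = table.copy()
    for col in predictors:
        out[col] = out[col].astype(float)
    records = []
    for participant, grp in table.groupby("participant", sort=False):
        for col in predictors:
            x = grp[col].to_numpy(dtype=float)
            if np.unique(x).size < 2:
                raise ValueError(f"zero-variance predictor {col!r} for participant {participant!r}")
            mean, sd = float(x.mean()), float(x.std())
            out.loc[grp.index, col] = (x - mean) / sd
            records.append({"participant": participant, "predictor": col, "mean": mean, "sd": sd})
    if categorical:
        for col in categorical:
            dummies = pd.get_dummies(out[col], prefix=col, drop_first=True, dtype=float)
            out = pd.concat([out.drop(columns=[col]), dummies], axis=1)
    return out, pd.DataFrame.from_records(records)


def back_transform(z: np.ndarray, participant, predictor: str, moments: pd.DataFrame) -> np.ndarray:
    """Invert the participant-specific z-transform."""
    row = moments[(moments["participant"] == participant) & (moments["predictor"] == predictor)]
    if row.empty:
        raise ValueError(f"no stored moments for ({participant!r}, {predictor!r})")
    return np.asarray(z, dtype=float) * row["sd"].iloc[0] + row["mean"].iloc[0]
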
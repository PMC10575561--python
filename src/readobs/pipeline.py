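"""End-to-end orchestration: ingest -> first-pass measures and filters ->
observer entropies -> LM features -> predictor tables -> cross-validated
fits for all model combinations -> variation partitions -> bootstrap stats,
effect sizes and the contextual-vs-non-contextual observer comparison.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from readobs import corpus as corpus_mod
from readobs import predictors as pred_mod
from readobs.context_prior import build_contextual_prior
from readobs.lexicon import frequency_prior_logodds, read_lexicon_tsv
from readobs.observer import (
    ObserverConfig,
    PerceptualSpan,
    preview_entropy_for_token,
)
from readobs.partitioning import partition_three, partition_two
from readobs.regression import cv_score, fit_coefficients, fit_skipped_refixation_model
from readobs.stats import bootstrap_t_test, compare_observers, preview_benefit, predictability_benefit

logger = logging.getLogger(__name__)

#: predictor-set presets; word_class expands to its indicator contrasts
GROUPING_PRESETS: dict[str, dict[str, tuple[str, ...]]] = {
    "fig2_skipping": {
        "prediction": ("predictive_entropy_bits",),
        "preview": ("parafoveal_entropy_bits",),
        "oculomotor": ("length", "launch_distance"),
    },
    "fig3_durations": {
        "prediction": ("surprisal_0", "surprisal_1", "surprisal_2"),
        "preview": ("parafoveal_entropy_bits",),
        "noncontextual": (
            "word_class",
            "length",
            "log_freq_0",
            "log_freq_1",
            "log_freq_2",
            "landing_offset_chars",
            "landing_offset_frac",
        ),
    },
    "fig4_skipping": {
        "oculomotor": ("length", "launch_distance"),
        "lexical": ("predictive_entropy_bits", "parafoveal_entropy_bits"),
    },
    "fig4_durations": {
        "oculomotor": ("landing_offset_chars", "landing_offset_frac"),
        "lexical": (
            "surprisal_0",
            "surprisal_1",
            "surprisal_2",
            "parafoveal_entropy_bits",
            "log_freq_0",
            "log_freq_1",
            "log_freq_2",
            "word_class",
        ),
    },
    "fig4_durations_with_length": {
        "oculomotor": ("landing_offset_chars", "landing_offset_frac", "length"),
        "lexical": (
            "surprisal_0",
            "surprisal_1",
            "surprisal_2",
            "parafoveal_entropy_bits",
            "log_freq_0",
            "log_freq_1",
            "log_freq_2",
            "word_class",
        ),
    },
}


@dataclass
class PipelineConfig:
    words_path: str = "words.tsv"
    fixations_path: str = "fixations.tsv"
    lexicon_path: str = "lexicon.tsv"
    nucleus_path: str = "nucleus.jsonl"
    output_dir: str = "out"
    lexicon_header: bool = False

    sigma: float = 3.0
    Lambda: float = 1.0
    noise_exponent: float = -0.5
    T: int = 50
    repeats: int = 3
    nucleus_mass: float = 0.95
    cv_folds: int = 10
    n_boot: int = 10_000
    max_launch: float = 24.0
    min_gaze_ms: float = 70.0
    max_gaze_ms: float = 900.0
    seed: int = 0
    compare_priors: bool = True

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    @property
    def span(self) -> PerceptualSpan:
        return PerceptualSpan(self.sigma, self.Lambda, self.noise_exponent)

    @property
    def observer(self) -> ObserverConfig:
        return ObserverConfig(T=self.T, repeats=self.repeats, rng_seed=self.seed)


def load_nucleus_jsonl(path) -> tuple[pd.DataFrame, dict]:
    """LM feature table and per-token nucleus map from a JSONL artifact.

    Records must carry text_id, word_index, word, nucleus (word/prob pairs),
    surprisal_bits and entropy_bits.
    """
    rows, nucleus_map = [], {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            rec = json.loads(line)
            key = (rec["text_id"], rec["word_index"])
            rows.append(
                {
                    "text_id": rec["text_id"],
                    "word_index": rec["word_index"],
                    "word": rec["word"],
                    "surprisal_bits": rec["surprisal_bits"],
                    "entropy_bits": rec["entropy_bits"],
                }
            )
            nucleus_map[key] = rec["nucleus"]
    return pd.DataFrame(rows), nucleus_map


def compute_observer_outputs(
    tokens: pd.DataFrame,
    lexicon,
    span: PerceptualSpan,
    config: ObserverConfig,
    prior: str = "frequency",
    nucleus_map: dict | None = None,
    nucleus_mass: float = 0.95,
) -> pd.DataFrame:
    """Observer entropies for every row of ``tokens`` (columns: participant,
    text_id, word_index, word, launch_distance).

    ``prior`` is "frequency" or "contextual" (requires ``nucleus_map``).
    Per-token RNG seeds derive from ``config.rng_seed``, so results are
    reproducible and order-independent.
    """
    freq_prior = frequency_prior_logodds(lexicon)
    prior_cache: dict = {}

    def prior_for(text_id, word_index) -> np.ndarray:
        if prior == "frequency":
            return freq_prior
        if nucleus_map is None:
            raise ValueError("contextual prior requires a nucleus map")
        key = (text_id, word_index)
        if key not in prior_cache:
            pairs = nucleus_map.get(key)
            if pairs is None:
                raise KeyError(f"no nucleus record for token {key}")
            prior_cache[key] = build_contextual_prior(dict(pairs), lexicon, mass=nucleus_mass)
        return prior_cache[key]

    records = []
    for row in tokens.itertuples(index=False):
        p = prior_for(row.text_id, row.word_index)
        out = preview_entropy_for_token(
            row.word.lower(),
            float(row.launch_distance),
            p,
            lexicon,
            span,
            config,
            key=(row.participant, row.text_id, row.word_index),
        )
        records.append(
            {
                "participant": row.participant,
                "text_id": row.text_id,
                "word_index": row.word_index,
                "launch_distance": row.launch_distance,
                "prior_entropy_bits": out.prior_entropy,
                "posterior_entropy_bits": out.posterior_entropy,
                "info_gain_bits": out.info_gain,
                "n_repeats": config.repeats,
                "seed": config.rng_seed,
            }
        )
    return pd.DataFrame.from_records(records)


def _expand_groups(groups: dict[str, tuple[str, ...]], columns) -> dict[str, list[str]]:
    """Replace 'word_class' with its indicator-contrast column names."""
    out = {}
    for label, cols in groups.items():
        expanded: list[str] = []
        for c in cols:
            if c == "word_class":
                expanded.extend(sorted(col for col in columns if col.startswith("word_class_")))
            else:
                expanded.append(c)
        out[label] = expanded
    return out


def participant_partition(
    table: pd.DataFrame,
    groups: dict[str, list[str]],
    outcome: str,
    link: str,
    k_folds: int,
    seed: int,
):
    """Scores for every combination of explanation sets (shared folds) and
    the resulting partition. Returns (scores dict, PartitionResult)."""
    labels = list(groups)
    scores: dict[frozenset, float] = {}
    for r in range(1, len(labels) + 1):
        for combo in itertools.combinations(labels, r):
            cols = [c for lbl in combo for c in groups[lbl]]
            scores[frozenset(combo)] = cv_score(
                table, cols, outcome, link, k_folds=k_folds, seed=seed
            )
    if len(labels) == 2:
        a, b = labels
        result = partition_two(
            scores[frozenset([a])],
            scores[frozenset([b])],
            scores[frozenset([a, b])],
            labels=(a, b),
        )
    elif len(labels) == 3:
        a, b, c = labels
        result = partition_three(
            scores[frozenset([a])],
            scores[frozenset([b])],
            scores[frozenset([c])],
            scores[frozenset([a, b])],
            scores[frozenset([a, c])],
            scores[frozenset([b, c])],
            scores[frozenset([a, b, c])],
            labels=(a, b, c),
        )
    else:
        raise ValueError("partitioning supports 2 or 3 explanation sets")
    return scores, result


def run_analysis(
    table_z: pd.DataFrame,
    groups_preset: dict[str, tuple[str, ...]],
    outcome: str,
    link: str,
    k_folds: int,
    seed: int,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-participant partitioning for one analysis. Returns (scores frame,
    partitions frame)."""
    groups = _expand_groups(groups_preset, table_z.columns)
    score_rows, part_rows = [], []
    for participant, grp in table_z.groupby("participant", sort=False):
        scores, result = participant_partition(grp, groups, outcome, link, k_folds, seed)
        metric = "mcfadden_r2" if link == "logistic" else "r2"
        for combo, s in scores.items():
            score_rows.append(
                {
                    "participant": participant,
                    "model_label": "+".join(sorted(combo)),
                    "metric": metric,
                    "score": s,
                    "n_rows": len(grp),
                }
            )
        for label, value in result.partitions.items():
            part_rows.append({"participant": participant, "partition_label": label, "value": value})
    return pd.DataFrame(score_rows), pd.DataFrame(part_rows)


def summarize_partitions(partitions: pd.DataFrame, n_boot: int, seed: int) -> pd.DataFrame:
    """Bootstrap t-test of each partition across participants."""
    rows = []
    for label, grp in partitions.groupby("partition_label", sort=False):
        values = grp["value"].to_numpy(dtype=float)
        if values.size >= 2 and values.std(ddof=1) > 0:
            res = bootstrap_t_test(values, n_boot=n_boot, seed=seed)
            rows.append(
                {
                    "partition_label": label,
                    "mean": res.observed_mean,
                    "ci_low": res.ci_low,
                    "ci_high": res.ci_high,
                    "p": res.p,
                    "n": values.size,
                }
            )
        else:
            rows.append(
                {
                    "partition_label": label,
                    "mean": float(values.mean()) if values.size else np.nan,
                    "ci_low": np.nan,
                    "ci_high": np.nan,
                    "p": np.nan,
                    "n": values.size,
                }
            )
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage; returns (and writes) the report bundle."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    span, obs_cfg = config.span, config.observer

    logger.info("ingest")
    words, fixations = corpus_mod.parse_fixation_report(config.words_path, config.fixations_path)
    lexicon = read_lexicon_tsv(config.lexicon_path, header=config.lexicon_header)
    lm_features, nucleus_map = load_nucleus_jsonl(config.nucleus_path)

    logger.info("first-pass measures and filters")
    measures = corpus_mod.first_pass_measures(fixations, words)
    measures, exclusion_log = corpus_mod.apply_exclusions(
        measures,
        lexicon=lexicon,
        max_launch=config.max_launch,
        min_gaze_ms=config.min_gaze_ms,
        max_gaze_ms=config.max_gaze_ms,
    )
    measures.to_csv(outdir / "measures.tsv", sep="\t", index=False)

    retained = measures.loc[
        measures["include_skip"],
        ["participant", "text_id", "word_index", "word", "launch_distance"],
    ]
    logger.info("observer entropies (frequency prior) for %d tokens", len(retained))
    obs_freq = compute_observer_outputs(retained, lexicon, span, obs_cfg, prior="frequency")
    obs_freq.to_csv(outdir / "observer_frequency.tsv", sep="\t", index=False)
    obs_ctx = None
    if config.compare_priors:
        logger.info("observer entropies (contextual prior)")
        obs_ctx = compute_observer_outputs(
            retained, lexicon, span, obs_cfg,
            prior="contextual", nucleus_map=nucleus_map, nucleus_mass=config.nucleus_mass,
        )
        obs_ctx.to_csv(outdir / "observer_contextual.tsv", sep="\t", index=False)

    logger.info("assemble and standardize predictor tables")
    skip_table, dur_table = pred_mod.assemble_predictors(measures, obs_freq, lm_features, lexicon)
    skip_z, skip_moments = pred_mod.standardize_within_participant(
        skip_table, pred_mod.SKIP_PREDICTORS
    )
    dur_z, dur_moments = pred_mod.standardize_within_participant(
        dur_table, pred_mod.DURATION_PREDICTORS, categorical=["word_class"]
    )
    skip_z.to_csv(outdir / "table_skipping.tsv", sep="\t", index=False)
    dur_z.to_csv(outdir / "table_durations.tsv", sep="\t", index=False)

    logger.info("cross-validated fits and partitions")
    skip_scores, skip_parts = run_analysis(
        skip_z, GROUPING_PRESETS["fig2_skipping"], "skip", "logistic", config.cv_folds, config.seed
    )
    dur_scores, dur_parts = run_analysis(
        dur_z, GROUPING_PRESETS["fig3_durations"], "gaze_duration_ms", "identity",
        config.cv_folds, config.seed,
    )
    pd.concat([skip_scores.assign(analysis="skipping"), dur_scores.assign(analysis="durations")]).to_csv(
        outdir / "scores.tsv", sep="\t", index=False
    )
    pd.concat([skip_parts.assign(analysis="skipping"), dur_parts.assign(analysis="durations")]).to_csv(
        outdir / "partitions.tsv", sep="\t", index=False
    )

    report: dict = {
        "seed": config.seed,
        "exclusions": exclusion_log,
        "skipping": {
            "partitions": summarize_partitions(skip_parts, config.n_boot, config.seed).to_dict("records")
        },
        "durations": {
            "partitions": summarize_partitions(dur_parts, config.n_boot, config.seed).to_dict("records")
        },
    }

    logger.info("effect sizes")
    dur_groups = _expand_groups(GROUPING_PRESETS["fig3_durations"], dur_z.columns)
    all_dur_cols = [c for cols in dur_groups.values() for c in cols]
    effect_rows = []
    prior_entropy = float(obs_freq["prior_entropy_bits"].iloc[0])
    for participant, grp in dur_z.groupby("participant", sort=False):
        coefs = fit_coefficients(grp, all_dur_cols, "gaze_duration_ms", "identity")
        m = dur_moments[dur_moments["participant"] == participant].set_index("predictor")
        pb = preview_benefit(
            coefs["parafoveal_entropy_bits"],
            m.loc["parafoveal_entropy_bits", "mean"],
            m.loc["parafoveal_entropy_bits", "sd"],
            prior_entropy,
        )
        raw_surp = (
            grp["surprisal_0"].to_numpy() * m.loc["surprisal_0", "sd"] + m.loc["surprisal_0", "mean"]
        )
        try:
            db = predictability_benefit(
                coefs["surprisal_0"], raw_surp, m.loc["surprisal_0", "mean"], m.loc["surprisal_0", "sd"]
            )
        except ValueError:
            db = np.nan
        effect_rows.append(
            {"participant": participant, "preview_benefit_ms": pb, "predictability_benefit_ms": db}
        )
    effects = pd.DataFrame(effect_rows)
    effects.to_csv(outdir / "effect_sizes.tsv", sep="\t", index=False)
    report["effect_sizes"] = {
        "preview_benefit_ms_mean": float(effects["preview_benefit_ms"].mean()),
        "predictability_benefit_ms_mean": float(np.nanmean(effects["predictability_benefit_ms"])),
        "per_participant": effect_rows,
    }

    logger.info("compensation model for skipped words")
    skipped = measures[(measures["include_skip"]) & (measures["skipped_first_pass"] == 1.0)]
    skipped = skipped.merge(
        obs_freq[["participant", "text_id", "word_index", "posterior_entropy_bits"]],
        on=["participant", "text_id", "word_index"],
    ).rename(columns={"posterior_entropy_bits": "parafoveal_entropy_bits"})
    comp_rows = []
    for participant, grp in skipped.groupby("participant", sort=False):
        try:
            beta = fit_skipped_refixation_model(grp)
        except (ValueError, RuntimeError) as err:
            logger.warning("compensation model failed for %s: %s", participant, err)
            continue
        comp_rows.append({"participant": participant, "beta_parafoveal_entropy": beta})
    report["compensation"] = comp_rows

    if config.compare_priors and obs_ctx is not None:
        logger.info("contextual vs non-contextual observer comparison")
        report["observer_comparison"] = _compare_observer_fits(
            measures, obs_freq, obs_ctx, lm_features, lexicon, config
        )
        report["observer_info_gain"] = {
            "frequency_prior_bits": float(obs_freq["info_gain_bits"].mean()),
            "contextual_prior_bits": float(obs_ctx["info_gain_bits"].mean()),
        }

    with open(outdir / "report.json", "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, default=float)
    return report


def _compare_observer_fits(measures, obs_freq, obs_ctx, lm_features, lexicon, config) -> dict:
    """Full-model CV scores with parafoveal entropy from each observer."""
    out = {}
    for analysis, outcome, link, preset in (
        ("skipping", "skip", "logistic", "fig2_skipping"),
        ("durations", "gaze_duration_ms", "identity", "fig3_durations"),
    ):
        scores = {}
        for name, obs in (("noncontextual", obs_freq), ("contextual", obs_ctx)):
            table, dur_table = pred_mod.assemble_predictors(measures, obs, lm_features, lexicon)
            tbl = table if analysis == "skipping" else dur_table
            preds = (
                pred_mod.SKIP_PREDICTORS if analysis == "skipping" else pred_mod.DURATION_PREDICTORS
            )
            cat = None if analysis == "skipping" else ["word_class"]
            tbl_z, _ = pred_mod.standardize_within_participant(tbl, preds, categorical=cat)
            groups = _expand_groups(GROUPING_PRESETS[preset], tbl_z.columns)
            cols = [c for cc in groups.values() for c in cc]
            per_part = {}
            for participant, grp in tbl_z.groupby("participant", sort=False):
                per_part[participant] = cv_score(
                    grp, cols, outcome, link, k_folds=config.cv_folds, seed=config.seed
                )
            scores[name] = pd.Series(per_part)
        res = compare_observers(
            scores["noncontextual"], scores["contextual"], n_boot=config.n_boot, seed=config.seed
        )
        out[analysis] = {
            "mean_diff_noncontextual_minus_contextual": res.observed_mean,
            "t": res.t,
            "p": res.p,
            "ci": [res.ci_low, res.ci_high],
            "per_participant_noncontextual": scores["noncontextual"].to_dict(),
            "per_participant_contextual": scores["contextual"].to_dict(),
        }
    return out
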
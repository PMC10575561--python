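# readobs

Model-based analysis of eye movements in natural reading. The package
quantifies, for every word token a reader encounters, how much information
about the word's identity is available *before* fixation — from linguistic
prediction (a next-word probability provider) and from parafoveal preview (a
Bayesian ideal observer with an eccentricity-dependent perceptual span) —
then regresses word skipping and first-pass gaze durations on competing
explanation sets, partitions the cross-validated explained variation into
unique and shared components, and runs equal-tail bootstrap inference and
model-derived effect sizes on top.

A first-class synthetic-data module generates reading corpora with known
ground truth (Zipfian lexicons, a bigram next-word provider, simulated
readers with length/distance-driven skipping, preferred landing positions,
surprisal/preview/frequency-driven gaze durations, and compensatory
regressions to poorly-previewed skipped words), so the entire pipeline is
verifiable offline.

## Layout

| module | what it does |
| --- | --- |
| `readobs.lexicon` | vocabulary, padded one-hot letter encodings, frequency prior |
| `readobs.observer` | ideal observer: noisy letter sampling, log-odds belief updates, preview entropy |
| `readobs.context_prior` | contextual prior via nucleus truncation + implied pseudofrequencies |
| `readobs.predictors` | surprisal/entropy features, predictor tables, per-participant z-scoring |
| `readobs.corpus` | canonical fixation-report ingestion, first-pass measures, exclusion filters |
| `readobs.regression` | per-participant logistic / OLS fits, 10-fold CV, R² and McFadden R² |
| `readobs.partitioning` | 2- and 3-set unique/shared variation partitions |
| `readobs.stats` | equal-tail bootstrap t-tests, preview/predictability benefits, observer comparison |
| `readobs.synthetic` | ground-truth corpus generator + synthetic language model |
| `readobs.pipeline` / `readobs.cli` | end-to-end orchestration, YAML config, CLI |

## CLI

Generate a synthetic study and analyse it end to end:

```bash
readobs simulate --params params.yaml --out study/ --seed 11
readobs all --config config.yaml
```

`config.yaml` points at the four canonical inputs and sets the analysis
parameters (all defaults shown):

```yaml
words_path: study/words.tsv        # participant, text_id, line_id, word_index, word, first_char, word_class
fixations_path: study/fixations.tsv  # participant, text_id, line_id, order, x_char, duration_ms, blink_adjacent
lexicon_path: study/lexicon.tsv    # word <TAB> frequency
nucleus_path: study/nucleus.jsonl  # per-token LM output: nucleus, surprisal_bits, entropy_bits
output_dir: out
sigma: 3.0          # perceptual span width (characters)
Lambda: 1.0         # sensory-quality scale
T: 50               # observer samples per run
repeats: 3          # independent runs averaged
nucleus_mass: 0.95
cv_folds: 10
n_boot: 10000
max_launch: 24.0    # |launch distance| filter
min_gaze_ms: 70.0
max_gaze_ms: 900.0
seed: 11
```

The output directory receives cached intermediates (`measures.tsv`,
`observer_*.tsv`, `table_*.tsv`, `scores.tsv`, `partitions.tsv`) and a
`report.json` with partition summaries, bootstrap statistics, effect sizes,
the skipped-word compensation coefficients, and the contextual vs
non-contextual observer comparison. Stage subcommands (`observe`,
`features`, `fit`, `partition`, `report`) re-run the pipeline through the
corresponding stage; `partition` recomputes partitions from cached scores.

Any external language model can drive the analysis by writing its per-token
output in the `nucleus.jsonl` format; no model download is required for the
tests, which use the synthetic provider.

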
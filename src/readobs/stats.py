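"""Group-level inference and model-derived effect sizes.

Inference across participants uses equal-tail bootstrap t-tests: the null is
built by mean-centering the observed per-participant statistics, resampling
with replacement, and counting how often a t-value at least as extreme as
the observed one occurs in either tail (no symmetry assumed). Confidence
intervals are percentile bootstrap intervals on the mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class BootstrapResult:
    observed_mean: float
    t: float
    p: float
    ci_low: float
    ci_high: float
    n_boot: int


@dataclass(frozen=True)
class EffectSizeConfig:
    """Cloze-probability cutoffs defining 'low' and 'high' predictability."""

    cloze_low_cutoff: float = 0.02
    cloze_high_cutoff: float = 0.25

    def __post_init__(self) -> None:
        if not 0 < self.cloze_low_cutoff < self.cloze_high_cutoff < 1:
            raise ValueError("need 0 < low < high < 1")

    @property
    def low_surprisal_bits(self) -> float:
        """Surprisal above this marks a low-probability word."""
        return float(-np.log2(self.cloze_low_cutoff))

    @property
    def high_surprisal_bits(self) -> float:
        """Surprisal below this marks a high-probability word."""
        return float(-np.log2(self.cloze_high_cutoff))


def _t_stat(values: np.ndarray) -> float:
    n = values.shape[-1]
    mean = values.mean(axis=-1)
    sd = values.std(axis=-1, ddof=1)
    return mean / (sd / np.sqrt(n))


def bootstrap_t_test(
    values, n_boot: int = 10_000, seed: int = 0, ci_level: float = 0.95
) -> BootstrapResult:
    """Equal-tail bootstrap t-test of the mean against zero."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 values")
    if v.std(ddof=1) == 0:
        raise ValueError("zero variance across participants")
    rng = np.random.default_rng(seed)
    t_obs = float(_t_stat(v))
    centred = v - v.mean()
    idx = rng.integers(0, v.size, size=(n_boot, v.size))
    null_samples = centred[idx]
    # drop degenerate resamples (all-identical draws give undefined t)
    sd = null_samples.std(axis=1, ddof=1)
    ok = sd > 0
    t_null = _t_stat(null_samples[ok])
    p_low = float(np.mean(t_null <= t_obs))
    p_high = float(np.mean(t_null >= t_obs))
    p = min(1.0, 2.0 * min(p_low, p_high))
    boot_means = v[idx].mean(axis=1)
    alpha = 1.0 - ci_level
    ci_low, ci_high = np.quantile(boot_means, [alpha / 2, 1 - alpha / 2])
    return BootstrapResult(
        observed_mean=float(v.mean()),
        t=t_obs,
        p=p,
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        n_boot=n_boot,
    )


def bootstrap_t_ci(
    values, n_boot: int = 10_000, seed: int = 0, ci_level: float = 0.95
) -> tuple[float, float]:
    """Bootstrap-t (studentized) confidence interval for the mean.

    Pivots on the resampled t statistic, which gives closer-to-nominal
    coverage than the percentile interval at small n.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2 or v.std(ddof=1) == 0:
        raise ValueError("need >= 2 values with nonzero variance")
    rng = np.random.default_rng(seed)
    n = v.size
    mean = v.mean()
    se = v.std(ddof=1) / np.sqrt(n)
    boots = v[rng.integers(0, n, size=(n_boot, n))]
    boot_se = boots.std(axis=1, ddof=1) / np.sqrt(n)
    ok = boot_se > 0
    t_star = (boots.mean(axis=1)[ok] - mean) / boot_se[ok]
    alpha = 1.0 - ci_level
    q_lo, q_hi = np.quantile(t_star, [alpha / 2, 1 - alpha / 2])
    return float(mean - q_hi * se), float(mean - q_lo * se)


def preview_benefit(
    beta_parafoveal_z: float,
    parafoveal_mean: float,
    parafoveal_sd: float,
    prior_entropy_bits: float,
) -> float:
    """Expected gaze-duration difference (ms) between a preview of average
    informativeness and no preview at all.

    ``beta_parafoveal_z`` is the fitted duration weight in ms per SD of
    parafoveal entropy; ``parafoveal_mean``/``parafoveal_sd`` are the
    participant's standardization moments for that predictor, and
    ``prior_entropy_bits`` is the entropy with no preview (the prior).
    Positive output means informative previews shorten gaze durations.
    """
    if parafoveal_sd <= 0:
        raise ValueError("parafoveal entropy SD must be positive")
    delta_z = (parafoveal_mean - prior_entropy_bits) / parafoveal_sd
    return float(-(delta_z * beta_parafoveal_z))


def predictability_benefit(
    beta_surprisal_z: float,
    surprisal_bits: np.ndarray,
    surprisal_mean: float,
    surprisal_sd: float,
    config: EffectSizeConfig = EffectSizeConfig(),
) -> float:
    """Expected gaze-duration difference (ms) between low- and
    high-probability words.

    Bins are defined by cloze cutoffs mapped to surprisal: low-probability
    words have surprisal above ``-log2(low_cutoff)``, high-probability words
    below ``-log2(high_cutoff)``. The difference of mean z-surprisal between
    bins is multiplied by the current-word surprisal weight (ms per SD).
    """
    s = np.asarray(surprisal_bits, dtype=float)
    low_bin = s > config.low_surprisal_bits
    high_bin = s < config.high_surprisal_bits
    if not low_bin.any():
        raise ValueError("no low-probability (high-surprisal) words in this participant's data")
    if not high_bin.any():
        raise ValueError("no high-probability (low-surprisal) words in this participant's data")
    z = (s - surprisal_mean) / surprisal_sd
    return float((z[low_bin].mean() - z[high_bin].mean()) * beta_surprisal_z)


def compare_observers(
    scores_noncontextual: pd.Series,
    scores_contextual: pd.Series,
    n_boot: int = 10_000,
    seed: int = 0,
) -> BootstrapResult:
    """Paired bootstrap test of full-model CV scores with non-contextual vs
    contextual parafoveal entropy. Positive mean = non-contextual fits better."""
    nc = pd.Series(scores_noncontextual)
    ct = pd.Series(scores_contextual)
    if set(nc.index) != set(ct.index):
        raise ValueError("participant sets differ between the two observers")
    diffs = (nc - ct.reindex(nc.index)).to_numpy(dtype=float)
    return bootstrap_t_test(diffs, n_boot=n_boot, seed=seed)
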
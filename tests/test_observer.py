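import numpy as np
import pytest
from scipy.stats import norm

from readobs.lexicon import build_lexicon, frequency_prior_logodds
from readobs.observer import (
    BeliefState,
    ObserverConfig,
    OutOfLexiconError,
    PerceptualSpan,
    entropy_bits,
    posterior_distribution,
    preview_entropy,
    preview_entropy_for_token,
    sample_percept,
    sensory_quality,
    slot_eccentricities,
    update_belief,
    _dim_variances,
)
from readobs.synthetic import make_lexicon


class TestSensoryQuality:
    def test_closed_form_at_zero(self, span):
        # independent oracle: lambda(0) = Phi(1/6) - Phi(-1/6)
        expected = norm.cdf(1 / 6) - norm.cdf(-1 / 6)
        assert sensory_quality(0.0, span) == pytest.approx(expected, abs=1e-12)
        assert sensory_quality(0.0, span) == pytest.approx(0.1324, abs=5e-4)

    def test_symmetry(self, span):
        for eps in [0.5, 1.0, 2.5, 5.0, 8.0]:
            assert sensory_quality(eps, span) == pytest.approx(
                sensory_quality(-eps, span), abs=1e-14
            )

    def test_monotone_decay(self, span):
        grid = np.arange(0.0, 15.0, 0.5)
        vals = sensory_quality(grid, span)
        assert np.all(np.diff(vals) < 0)
        assert sensory_quality(8.0, span) < sensory_quality(2.0, span)

    def test_lambda_scaling(self):
        big = PerceptualSpan(sigma=3.0, Lambda=2.0)
        small = PerceptualSpan(sigma=3.0, Lambda=1.0)
        assert sensory_quality(1.0, big) == pytest.approx(2 * sensory_quality(1.0, small))


class TestSamplePercept:
    def test_moments(self):
        # Lambda chosen so lambda(0) = 1 exactly: variance = 1^(-1/2) = 1
        lam0 = norm.cdf(1 / 6) - norm.cdf(-1 / 6)
        span = PerceptualSpan(sigma=3.0, Lambda=1.0 / lam0)
        true = np.zeros(26)
        true[3] = 1.0
        rng = np.random.default_rng(1)
        draws = np.stack(
            [sample_percept(true, np.array([0.0]), span, rng) for _ in range(20_000)]
        )
        assert draws.var(axis=0).mean() == pytest.approx(1.0, rel=0.02)
        assert np.abs(draws.mean(axis=0) - true).max() < 0.05

    def test_deterministic_with_seed(self, span):
        true = np.zeros(52)
        a = sample_percept(true, np.array([1.0, 2.0]), span, np.random.default_rng(5))
        b = sample_percept(true, np.array([1.0, 2.0]), span, np.random.default_rng(5))
        assert np.array_equal(a, b)

    def test_far_eccentricity_finite(self, span):
        true = np.zeros(26)
        out = sample_percept(true, np.array([500.0]), span, np.random.default_rng(0))
        assert np.all(np.isfinite(out))

    def test_slot_count_mismatch(self, span):
        with pytest.raises(ValueError):
            sample_percept(np.zeros(52), np.array([1.0]), span, np.random.default_rng(0))


class TestUpdateBelief:
    def test_zero_samples_equals_prior(self, lex5, span):
        prior = frequency_prior_logodds(lex5)
        cfg = ObserverConfig(T=0, repeats=2, rng_seed=1)
        out = preview_entropy("cat", 2.0, prior, lex5, span, cfg)
        assert out.posterior_entropy == pytest.approx(out.prior_entropy, abs=1e-12)
        assert out.info_gain == pytest.approx(0.0, abs=1e-12)

    def test_two_word_single_letter_bayes(self, span):
        # brute-force Bayes with explicit Gaussian densities
        lex = build_lexicon(["a", "b"], [3.0, 1.0])
        prior = frequency_prior_logodds(lex)
        eccs = slot_eccentricities(1.0, lex.l_max)
        var = _dim_variances(eccs, span)
        rng = np.random.default_rng(9)
        percept = sample_percept(lex.encoding[0], eccs, span, rng)
        belief = update_belief(BeliefState(prior, lex), percept, lex, span, eccs)
        p_chain = posterior_distribution(belief)
        logp = np.log(lex.frequencies / lex.frequencies.sum())
        for i in range(2):
            logp[i] += norm.logpdf(percept, lex.encoding[i], np.sqrt(var)).sum()
        p_brute = np.exp(logp - logp.max())
        p_brute /= p_brute.sum()
        assert np.abs(p_chain - p_brute).max() < 1e-9

    def test_chained_oracle_equivalence(self, span):
        # V<=5, l_max<=2: chained log-odds updating matches explicit
        # multivariate-normal Bayes on the same percept sequence
        lex = build_lexicon(["ab", "ba", "a", "b", "aa"], [5.0, 4.0, 3.0, 2.0, 1.0])
        prior = frequency_prior_logodds(lex)
        eccs = slot_eccentricities(1.5, lex.l_max)
        var = _dim_variances(eccs, span)
        rng = np.random.default_rng(21)
        belief = BeliefState(prior.copy(), lex)
        logp = np.log(lex.frequencies / lex.frequencies.sum())
        for _ in range(10):
            percept = sample_percept(lex.encoding[0], eccs, span, rng)
            belief = update_belief(belief, percept, lex, span, eccs)
            for i in range(lex.V):
                logp[i] += norm.logpdf(percept, lex.encoding[i], np.sqrt(var)).sum()
        p_brute = np.exp(logp - logp.max())
        p_brute /= p_brute.sum()
        assert np.abs(posterior_distribution(belief) - p_brute).max() < 1e-8

    def test_dimension_mismatch(self, lex5, span):
        eccs = slot_eccentricities(1.0, lex5.l_max)
        belief = BeliefState(frequency_prior_logodds(lex5), lex5)
        with pytest.raises(ValueError):
            update_belief(belief, np.zeros(10), lex5, span, eccs)


class TestPosteriorDistribution:
    def test_two_way_even(self):
        assert np.allclose(posterior_distribution(np.array([0.0]), 1), [0.5, 0.5])

    def test_two_way_log3(self):
        p = posterior_distribution(np.array([np.log(3.0)]), 1)
        assert np.allclose(p, [0.75, 0.25])

    def test_normalization_large(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0, 50, size=999)
        p = posterior_distribution(x, 999)
        assert p.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(p >= 0)


class TestEntropyBits:
    def test_uniform_four(self):
        assert entropy_bits(np.full(4, 0.25)) == pytest.approx(2.0)

    def test_degenerate(self):
        assert entropy_bits(np.array([1.0, 0.0, 0.0])) == 0.0

    def test_half_quarter_quarter(self):
        assert entropy_bits(np.array([0.5, 0.25, 0.25])) == pytest.approx(1.5)

    def test_negative_raises(self):
        with pytest.raises(ValueError):
            entropy_bits(np.array([1.1, -0.1]))

    def test_unnormalized_raises(self):
        with pytest.raises(ValueError):
            entropy_bits(np.array([0.5, 0.4]))


class TestPreviewEntropy:
    def test_far_launch_no_information(self, span, obs_config):
        lex = make_lexicon(100, 1.0, (2, 7), seed=4)
        prior = frequency_prior_logodds(lex)
        out = preview_entropy(lex.words[0], 24.0, prior, lex, span, obs_config)
        assert out.info_gain == pytest.approx(0.0, abs=0.05)

    def test_close_launch_high_precision(self, span, obs_config):
        lex = make_lexicon(100, 1.0, (3, 3), seed=4)
        prior = frequency_prior_logodds(lex)
        out = preview_entropy(lex.words[10], 1.0, prior, lex, span, obs_config)
        assert out.posterior_entropy < 0.1

    def test_repeats_average(self, lex5, span):
        # posterior entropy is the arithmetic mean of per-run entropies
        prior = frequency_prior_logodds(lex5)
        cfg3 = ObserverConfig(T=20, repeats=3, rng_seed=13)
        out = preview_entropy("cat", 3.0, prior, lex5, span, cfg3)
        rng = np.random.default_rng(13)
        singles = []
        for _ in range(3):
            one = preview_entropy(
                "cat", 3.0, prior, lex5, span, ObserverConfig(T=20, repeats=1), rng=rng
            )
            singles.append(one.posterior_entropy)
        assert out.posterior_entropy == pytest.approx(np.mean(singles), abs=1e-12)

    def test_out_of_lexicon(self, lex5, span, obs_config):
        prior = frequency_prior_logodds(lex5)
        with pytest.raises(OutOfLexiconError):
            preview_entropy("zebra", 2.0, prior, lex5, span, obs_config)

    def test_deterministic_per_token_seed(self, lex5, span, obs_config):
        prior = frequency_prior_logodds(lex5)
        a = preview_entropy_for_token("dog", 2.0, prior, lex5, span, obs_config, key=("p", "t", 3))
        b = preview_entropy_for_token("dog", 2.0, prior, lex5, span, obs_config, key=("p", "t", 3))
        c = preview_entropy_for_token("dog", 2.0, prior, lex5, span, obs_config, key=("p", "t", 4))
        assert a.posterior_entropy == b.posterior_entropy
        assert a.posterior_entropy != c.posterior_entropy

    def test_chain_and_aggregate_agree_in_distribution(self, span):
        lex = build_lexicon(["ab", "cd", "ef", "gh"], [4.0, 3.0, 2.0, 1.0])
        prior = frequency_prior_logodds(lex)
        cfg = ObserverConfig(T=10, repeats=1)
        means = {}
        for method in ("chain", "aggregate"):
            rng = np.random.default_rng(77)
            vals = [
                preview_entropy(
                    "ab", 4.0, prior, lex, span, cfg, rng=rng, method=method
                ).posterior_entropy
                for _ in range(400)
            ]
            means[method] = np.mean(vals)
        assert means["chain"] == pytest.approx(means["aggregate"], abs=0.08)


@pytest.fixture(scope="module")
def lex100():
    return make_lexicon(100, 1.0, (2, 7), seed=8)


class TestObserverProperties:
    def test_mean_info_gain_positive_inside_span(self, lex100, span):
        prior = frequency_prior_logodds(lex100)
        cfg = ObserverConfig(T=50, repeats=1, rng_seed=0)
        rng = np.random.default_rng(3)
        gains = []
        for i in range(200):
            word = lex100.words[rng.integers(0, 100)]
            launch = rng.uniform(0.5, 9.5)
            out = preview_entropy(word, launch, prior, lex100, span, cfg,
                                  rng=np.random.default_rng(1000 + i))
            gains.append(out.info_gain)
        assert np.mean(gains) > 0

    def test_posterior_entropy_monotone_in_launch(self, lex100, span):
        prior = frequency_prior_logodds(lex100)
        cfg = ObserverConfig(T=50, repeats=1, rng_seed=0)
        rng = np.random.default_rng(4)
        bin_means = []
        for launch in (1.0, 4.0, 7.0, 10.0, 13.0):
            vals = []
            for i in range(500):
                word = lex100.words[rng.integers(0, 100)]
                out = preview_entropy(word, launch, prior, lex100, span, cfg,
                                      rng=np.random.default_rng(i))
                vals.append(out.posterior_entropy)
            bin_means.append(np.mean(vals))
        assert np.all(np.diff(bin_means) >= -1e-9)

    def test_true_word_posterior_exceeds_prior(self, lex100, span):
        prior = frequency_prior_logodds(lex100)
        prior_p = posterior_distribution(prior, lex100.reference_index)
        cfg = ObserverConfig(T=50, repeats=1, rng_seed=0)
        from readobs.observer import _aggregate_logodds

        rng = np.random.default_rng(5)
        diffs = []
        for i in range(100):
            wi = int(rng.integers(0, 100))
            eccs = slot_eccentricities(rng.uniform(0.5, 5.0), lex100.l_max)
            post = _aggregate_logodds(
                prior, lex100.encoding[wi], eccs, lex100, span, 50, 1,
                np.random.default_rng(200 + i),
            )
            p = posterior_distribution(post[0], lex100.reference_index)
            diffs.append(p[wi] - prior_p[wi])
        assert np.mean(diffs) > 0

    def test_more_samples_never_increase_entropy(self, lex100, span):
        prior = frequency_prior_logodds(lex100)
        rng = np.random.default_rng(6)
        words = [lex100.words[rng.integers(0, 100)] for _ in range(200)]
        launches = rng.uniform(2, 8, size=200)
        means = []
        for T in (5, 20, 50):
            cfg = ObserverConfig(T=T, repeats=1, rng_seed=0)
            vals = [
                preview_entropy(w, la, prior, lex100, span, cfg,
                                rng=np.random.default_rng(i)).posterior_entropy
                for i, (w, la) in enumerate(zip(words, launches))
            ]
            means.append(np.mean(vals))
        assert means[0] >= means[1] >= means[2]
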
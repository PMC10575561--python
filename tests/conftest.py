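import numpy as np
import pytest

from readobs.lexicon import build_lexicon
from readobs.observer import ObserverConfig, PerceptualSpan
from readobs.synthetic import GeneratorParams, generate_study


@pytest.fixture
def span():
    return PerceptualSpan()


@pytest.fixture
def obs_config():
    return ObserverConfig(T=50, repeats=3, rng_seed=7)


@pytest.fixture
def lex5():
    return build_lexicon(["cat", "dog", "cow", "pig", "hen"], [5.0, 4.0, 3.0, 2.0, 1.0])


@pytest.fixture(scope="session")
def small_study(tmp_path_factory):
    """A small generated study shared by corpus/pipeline tests."""
    outdir = tmp_path_factory.mktemp("study")
    params = GeneratorParams(V=150, n_participants=3, words_per_participant=500)
    manifest = generate_study(
        params, PerceptualSpan(), ObserverConfig(rng_seed=11), outdir, master_seed=11
    )
    return outdir, params, manifest


@pytest.fixture
def rng():
    return np.random.default_rng(0)
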
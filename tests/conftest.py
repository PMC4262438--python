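import numpy as np
import pytest

from reportcheck import SyntheticSpec, generate

# The classic textbook example of an inconsistent p-value embedded in prose:
# the middle F statistic (0.54 on 1 and 20 df) implies p ~ .47, far above the
# reported bound of .03.
INTRO_SNIPPET = (
    "All two-way interactions were significant: A×B, F(1, 20) = 9.5, p<.006; "
    "A×C, F(1, 20) = 0.54, p<.03; and C×B, F(1, 20) = 6.8, p<.02"
)


@pytest.fixture(scope="session")
def intro_snippet():
    return INTRO_SNIPPET


@pytest.fixture(scope="session")
def small_corpus():
    """A deterministic 40-article corpus with planted errors."""
    return generate(SyntheticSpec(n_articles=40, seed=11))


@pytest.fixture(scope="session")
def homogeneous_corpus():
    """No between-article heterogeneity: truth recovery must be exact."""
    return generate(SyntheticSpec(n_articles=80, article_effect_sd=0.0, seed=5))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
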
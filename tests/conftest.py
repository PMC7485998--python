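import numpy as np
import pytest
from hypothesis import settings

from tweethood.lexicon import Lexicon
from tweethood.sentiment import train_sentiment
from tweethood.synthetic import gen_training_corpus

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def lexicon() -> Lexicon:
    return Lexicon.default()


@pytest.fixture(scope="session")
def sentiment_model():
    """Naive-Bayes model trained on the packaged synthetic corpus."""
    return train_sentiment(gen_training_corpus(3000, 0.5, 0))


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20250925)
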
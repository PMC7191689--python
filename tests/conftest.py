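import numpy as np
import pytest

from stsfuse.corpus_io import Corpus, SentencePair
from stsfuse.preprocess import TokenizedPair
from stsfuse.synthgen import GeneratorConfig, generate, worked_fixture


@pytest.fixture
def fixture_corpus() -> Corpus:
    return worked_fixture()


@pytest.fixture
def small_corpus() -> Corpus:
    """300 synthetic scored pairs, fixed seed."""
    return generate(GeneratorConfig(n_pairs=300, noise_sd=0.2, seed=7))


@pytest.fixture
def tiny_corpus() -> Corpus:
    """40 synthetic scored pairs for fast training smoke tests."""
    return generate(GeneratorConfig(n_pairs=40, noise_sd=0.1, seed=3))


@pytest.fixture
def uniform_scored_corpus() -> Corpus:
    """100 pairs, exactly 20 per unit score interval."""
    pairs = []
    k = 0
    for interval in range(5):
        for j in range(20):
            gold = interval + (j + 0.5) / 20.0
            pairs.append(
                SentencePair(
                    pair_id=f"u{k}", s1=f"alpha beta tok{k}", s2=f"gamma tok{k}",
                    gold=gold,
                )
            )
            k += 1
    return Corpus(pairs, provenance="uniform")


@pytest.fixture
def tokenized_pair() -> TokenizedPair:
    return TokenizedPair(
        pair_id="t0",
        tokens1=["nurse", "visit", "chest", "pain"],
        tokens2=["nurse", "visit", "fever"],
        gold=3.0,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
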
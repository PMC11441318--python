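import numpy as np
import pytest
from hypothesis import settings, HealthCheck

from protdistill.sequence_io import Vocabulary, tokenize
from protdistill.student import StudentConfig, StudentModel
from protdistill.synthetic import SyntheticSpec, generate_corpus

settings.register_profile(
    "suite", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def vocab():
    return Vocabulary()


@pytest.fixture(scope="session")
def tiny_config(vocab):
    return StudentConfig(num_layers=2, hidden_dim=32, num_heads=4,
                         feedforward_dim=64, vocab_size=vocab.size,
                         max_length=200)


@pytest.fixture(scope="session")
def tiny_model(tiny_config, vocab):
    return StudentModel(tiny_config, vocab=vocab, seed=7)


@pytest.fixture(scope="session")
def motif_corpus(vocab):
    """Small planted-motif corpus shared across downstream tests."""
    spec = SyntheticSpec(n_sequences=60, seed=11)
    records, dataset = generate_corpus(spec)
    tokens = [tokenize(r, vocab, 200) for r in records]
    return records, dataset, tokens


def random_token_sequences(n, vocab, rng, min_len=5, max_len=30):
    from protdistill.sequence_io import TokenSequence

    out = []
    for i in range(n):
        length = int(rng.integers(min_len, max_len + 1))
        toks = rng.integers(0, vocab.unknown_index, size=length)
        out.append(TokenSequence(id=f"r{i}", tokens=tuple(int(t) for t in toks),
                                 original_length=length))
    return out
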
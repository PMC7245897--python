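import numpy as np
import pytest

from kbrelex.corpus import segment
from kbrelex.representation import EmbeddingTable
from kbrelex.synth import SynthConfig, generate


@pytest.fixture(scope="session")
def small_synth():
    """A small deterministic synthetic corpus + KB + embeddings."""
    return generate(
        SynthConfig(
            n_documents=6,
            sentences_per_doc=4,
            embed_dim=16,
            kb_signal=1.0,
            p_trigger=0.5,
            seed=42,
        )
    )


@pytest.fixture
def zero_table():
    """A tiny embedding table mapping nothing (all lookups hit OOV)."""
    return EmbeddingTable(dim=8, oov_seed=0)


def make_sentence(text: str):
    """One-sentence helper: tokenize `text` as a full document."""
    sentences = segment(text)
    assert len(sentences) == 1
    return sentences[0]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
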
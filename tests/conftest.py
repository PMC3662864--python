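import pytest

from topicminer.lexicon import Lexicon, LexiconEntry
from topicminer.synthetic_corpus import SimConfig, generate


@pytest.fixture(scope="session")
def small_lexicon() -> Lexicon:
    return Lexicon(
        [
            LexiconEntry("T1", "neuropathic pain", ("neuropathic pain",),
                         "pain type", "specific"),
            LexiconEntry("T2", "pain", ("pain",), "disorder", "specific"),
            LexiconEntry("T3", "CFA", ("CFA",), "molecule", "relevant"),
            LexiconEntry("T4", "dorsal root ganglion", ("dorsal root ganglion", "DRG"),
                         "anatomy", "relevant"),
        ]
    )


@pytest.fixture(scope="session")
def bundle():
    """A medium synthetic bundle shared by read-only tests."""
    return generate(SimConfig(seed=11, n_docs=150))


@pytest.fixture(scope="session")
def large_bundle():
    """A bundle with well over 1000 event mentions for grouping properties."""
    return generate(SimConfig(seed=3, n_docs=400, events_per_doc_mean=3.5))
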
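import numpy as np
import pytest

from slrminer import load_schema
from slrminer.synthgen import SynthConfig, generate_corpus


@pytest.fixture(scope="session")
def slr1():
    return load_schema("slr1")


@pytest.fixture(scope="session")
def slr2():
    return load_schema("slr2")


@pytest.fixture(scope="session")
def small_corpus():
    """50 synthetic documents under the slr2 schema (shared, read-only)."""
    return generate_corpus(SynthConfig(schema_id="slr2", n_documents=50, seed=11)).corpus


@pytest.fixture(scope="session")
def tiny_corpus():
    """A handful of documents for fast overfitting checks."""
    return generate_corpus(SynthConfig(schema_id="slr2", n_documents=8, seed=5)).corpus
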
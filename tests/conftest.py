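import numpy as np
import pytest

import ecoevosim as es


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def trait_grammar():
    return es.load_packaged_grammar("trait")


@pytest.fixture
def fitness_grammar():
    return es.load_packaged_grammar("fitness")


def make_segment(bitstrings, kind="reproductive", roles=None, size_gene=8):
    bits = np.array([int(b) for s in bitstrings for b in s], dtype=np.uint8)
    return es.GenotypeSegment(kind, bits, size_gene, roles)


@pytest.fixture
def genotype(rng):
    return es.random_genotype(36, 2, 1, 8, rng)
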
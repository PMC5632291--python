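"""Shared fixtures: small hand-checkable tables and metadata."""

import numpy as np
import pytest

from ampliquery import FeatureTable, SampleMetadata, SequenceRecord

BASES = "ACGT"


def random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(BASES), length))


def mutate(seq: str, positions, offset: int = 0) -> str:
    """Substitute at the given positions (cyclic base shift: deterministic)."""
    out = list(seq)
    for p in positions:
        out[p] = BASES[(BASES.index(out[p]) + 1 + offset) % 4]
    return "".join(out)


@pytest.fixture
def toy_table():
    """6 samples x 2 features; feature A present in samples 1-3."""
    return FeatureTable(
        sample_ids=["s1", "s2", "s3", "s4", "s5", "s6"],
        feature_ids=["A", "B"],
        counts=[[5, 0], [3, 2], [1, 4], [0, 6], [0, 1], [0, 2]],
    )


@pytest.fixture
def toy_metadata():
    """host field: s1/s2 -> H1, s3/s4 -> H2, s5/s6 -> H3."""
    return SampleMetadata(
        ["s1", "s2", "s3", "s4", "s5", "s6"],
        {
            "host": {"s1": "H1", "s2": "H1", "s3": "H2", "s4": "H2",
                     "s5": "H3", "s6": "H3"},
        },
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)
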
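from collections import Counter

import pytest

from algocp.msa import Alignment, AlignmentColumn, SequenceRecord, extract_columns
from algocp.generator import ProfileSequenceGenerator
from algocp.properties import default_property_table
from algocp.synthetic import acpp_like_config, synthesize_msa


@pytest.fixture(scope="session")
def table():
    return default_property_table()


@pytest.fixture
def toy_alignment():
    return Alignment(
        (
            SequenceRecord("s1", "ACD-EF"),
            SequenceRecord("s2", "ACDGEF"),
            SequenceRecord("s3", "ACEGEF"),
        )
    )


def make_column(residues: str, index: int = 0) -> AlignmentColumn:
    return AlignmentColumn(index=index, residues=Counter(residues))


@pytest.fixture(scope="session")
def synthetic_alignment():
    """The default carrier-protein-like fixture: 200 x 78, invariant serine
    at 0-based position 36."""
    return synthesize_msa(acpp_like_config(n_sequences=200, seed=11))


@pytest.fixture(scope="session")
def synthetic_columns(synthetic_alignment):
    return extract_columns(synthetic_alignment, min_residues=50)


@pytest.fixture(scope="session")
def fitted_generator(synthetic_alignment):
    return ProfileSequenceGenerator(min_residues=50).fit(synthetic_alignment)
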
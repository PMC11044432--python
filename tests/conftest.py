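"""Shared fixtures: the standard synthetic fixture and its scores.

Session-scoped so the random-forest training and score computation run once
for the whole suite.
"""

import pytest

from telorank import SyntheticConfig
from telorank.reference_scores import ReferenceSet
from telorank.synthetic import compute_all_scores, generate_dataset


@pytest.fixture(scope="session")
def standard_config():
    return SyntheticConfig()  # 500 genes, 20 species, 10 planted at 3 Mb, seed 42


@pytest.fixture(scope="session")
def standard_data(standard_config):
    ds, truth = generate_dataset(standard_config)
    return ds, truth


@pytest.fixture(scope="session")
def standard_refs(standard_data):
    _, truth = standard_data
    return ReferenceSet(truth.planted_genes[:5])


@pytest.fixture(scope="session")
def standard_scores(standard_data, standard_refs):
    ds, _ = standard_data
    return compute_all_scores(ds, standard_refs)
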
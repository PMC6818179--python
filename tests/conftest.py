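import io

import pytest

from genecurate import simulate
from genecurate.parsers import parse_functional


@pytest.fixture(scope="session")
def bundle():
    """Seeded 200-model fixture with 5 plants of each of the 12 violation tags."""
    return simulate.generate(
        genome_params={"n_scaffolds": 4, "scaffold_length": 60_000},
        model_params={"n_models": 200, "violation_mix": simulate.default_violation_mix(5)},
        seed=20_240_101,
    )


@pytest.fixture(scope="session")
def genome(bundle):
    return bundle.genome()


@pytest.fixture(scope="session")
def fmap(bundle):
    return parse_functional(io.StringIO(bundle.entap_tsv))


@pytest.fixture(scope="session")
def clean_bundle():
    """Fixture with zero planted violations."""
    return simulate.generate(
        genome_params={"n_scaffolds": 2, "scaffold_length": 30_000},
        model_params={"n_models": 40, "violation_mix": {}},
        seed=7,
    )
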
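import warnings

import pytest

from genomescape import SyntheticSpec, generate_expression, generate_genome, generate_hits

warnings.filterwarnings("ignore", message=".*Precision loss.*")


@pytest.fixture(scope="session")
def spec():
    return SyntheticSpec(seed=101)


@pytest.fixture(scope="session")
def genome(spec):
    return generate_genome(spec)


@pytest.fixture(scope="session")
def hit_tables(spec, genome):
    return generate_hits(spec, genome)


@pytest.fixture(scope="session")
def expression(spec):
    return generate_expression(spec)
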
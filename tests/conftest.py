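import pytest

from cnvtriage.fixture import load_table1_fixture
from cnvtriage.sim import SimConfig, generate


@pytest.fixture(scope="session")
def table1():
    return load_table1_fixture()


@pytest.fixture(scope="session")
def default_bundle():
    """One default synthetic cohort, shared across read-only tests."""
    return generate(SimConfig(seed=1))


def base_set(iv):
    """Literal per-base representation of a genomic interval."""
    return {(iv.chrom, p) for p in range(iv.start, iv.end + 1)}
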
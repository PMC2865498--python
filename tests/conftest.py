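import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

from degradomics.seqforge import (
    CopyPlan,
    ForgeConfig,
    SeedProtein,
    forge_genome,
    forge_seed_set,
)


@pytest.fixture(scope="session")
def two_family_seeds():
    return forge_seed_set([("FAMA", "serine"), ("FAMB", "cysteine")], rng_seed=11)


@pytest.fixture(scope="session")
def small_forge(two_family_seeds):
    """One species, a tandem pair plus a single gene, zero divergence."""
    cfg = ForgeConfig(
        species=["sp1"],
        plan={"sp1": [CopyPlan("FAMA", 2, "tandem"), CopyPlan("FAMB", 1)]},
        divergence=0.0,
        rng_seed=11,
    )
    genomes, truth = forge_genome(two_family_seeds, cfg)
    return genomes, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_seed(sequence, positions=None, cls="cysteine", family="FAM", sid="FAM_seed"):
    """A SeedProtein with valid catalytic bookkeeping for tests."""
    if positions is None:
        n = {"serine": 3, "cysteine": 2, "aspartyl": 2, "metallo": 3}[cls]
        positions = list(range(5, 5 + n))
    return SeedProtein(
        id=sid,
        family=family,
        catalytic_class=cls,
        catalytic_positions=list(positions),
        sequence=sequence,
    )
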
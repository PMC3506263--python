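import numpy as np
import pytest

from pprd.simulate import LibraryParams, SimConfig, gen_parental_genomes, gen_te_library
from pprd.types import Strand, StrandedHit


def make_hit(read_id, target="TE001", strand=Strand.SENSE, five_prime=0,
             length=26, n_locations=1, copies=1):
    return StrandedHit(read_id=read_id, target=target, strand=strand,
                       five_prime=five_prime, length=length,
                       n_locations=n_locations, copies=copies)


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(
        seed=11,
        n_families=6,
        consensus_length_range=(1200, 2000),
        n_clusters=3,
        smallrna={
            "parentA": LibraryParams(n_reads=4000),
            "parentB": LibraryParams(n_reads=4000),
            "hybrid": LibraryParams(n_reads=4000),
        },
    )


@pytest.fixture(scope="session")
def small_families(small_config):
    families, truth = gen_te_library(small_config)
    return families, truth


@pytest.fixture(scope="session")
def small_genomes(small_config, small_families):
    families, _ = small_families
    return gen_parental_genomes(small_config, families)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
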
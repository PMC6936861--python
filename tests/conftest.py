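import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from apobecsig import simulate
from apobecsig.catalog_io import ReferenceSequence


@pytest.fixture(scope="session")
def sim_reference():
    """A 20 kb simulated reference with its exact TCW site list."""
    cfg = simulate.CatalogSimConfig(reference_length=20_000, seed=101)
    return simulate.simulate_reference(cfg)


@pytest.fixture(scope="session")
def paralog_pair():
    """A simulated transcript pair with planted unique regions (A3A/A3B-like)."""
    cfg = simulate.ReadSimConfig(seed=11)
    pair, truth = simulate.simulate_paralog_pair(cfg)
    return pair, truth, cfg


@pytest.fixture()
def tiny_reference():
    return ReferenceSequence(
        {
            "chr1": "ACGTACGTACGTACGTACGTCACGTACGTACGTACGTACGT",  # 41 bp, C at pos 21
            "chr2": "TTTTCATTTTGATTTTTTTTTTTTTTTTTTTTTTTTTTTT",
        }
    )
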
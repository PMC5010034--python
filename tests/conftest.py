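import pytest

from bipolarmeth.simulate import (
    SEQ_ADAPTER,
    SimConfig,
    SubsetModel,
    simulate_bulk_reads,
    simulate_hairpin_pairs,
)
from bipolarmeth.hairpin import process_pairs


@pytest.fixture(scope="session")
def hairpin_sim():
    """2,000 hairpin molecules, 5% dyad asymmetry, 10% unmethylated
    spike-in, 99.7% conversion — the default study conditions."""
    config = SimConfig(seed=2, dyad_asymmetry_rate=0.05)
    return simulate_hairpin_pairs(config, n_molecules=2000, spike_in_fraction=0.1)


@pytest.fixture(scope="session")
def recovered(hairpin_sim):
    molecules, rejected = process_pairs(hairpin_sim.pairs, adapter_seq=SEQ_ADAPTER)
    return molecules, rejected


@pytest.fixture(scope="session")
def small_bulk():
    """60 segments (30 CSM / 30 uniform) at 20x for unit tests."""
    config = SimConfig(seed=7, depth=20)
    return simulate_bulk_reads(
        SubsetModel(), config, n_csm_segments=30, n_uniform_segments=30
    )
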
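import pytest

from nucleolong import SimulationConfig, simulate
from nucleolong.nanopore_assign import MoleculeConsensus


@pytest.fixture(scope="session")
def noisy_ds():
    """2,000 reads across 100 nuclei at the default 5% error rate."""
    return simulate(SimulationConfig(seed=0, n_nuclei=100, reads_per_nucleus=20))


@pytest.fixture(scope="session")
def clean_ds():
    """Same layout with the error channel off."""
    return simulate(
        SimulationConfig(seed=0, n_nuclei=100, reads_per_nucleus=20, per_base_error_rate=0.0)
    )


def truth_molecules(ds):
    """Truth-labelled molecules as consensus objects (transcript strand +)."""
    return [
        MoleculeConsensus(m.barcode, m.umi, m.gene_id, "", 1, m.blocks, m.chrom, "+")
        for m in ds.molecules
    ]
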
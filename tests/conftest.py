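import numpy as np
import pytest

import uvtx


@pytest.fixture(scope="session")
def gene_set():
    """500 synthetic genes at generator defaults."""
    return uvtx.generate_gene_set(500, seed=1)


@pytest.fixture(scope="session")
def sim(gene_set):
    """Full condition grid: 10 and 20 J/m2, three timepoints, three genotypes."""
    cfg = uvtx.SimulationConfig(
        doses=(10.0, 20.0),
        timepoints=(0.0, 6.0, 24.0),
        genotypes=("WT", "XPC", "CSB"),
        reads_per_condition=500_000,
        seed=3,
    )
    return uvtx.simulate_experiment(gene_set, cfg)


@pytest.fixture(scope="session")
def ctrl_rpkm(sim):
    return sim.rpkm[sim.control("WT").label]


@pytest.fixture
def toy_gene():
    return uvtx.Gene("toy", "chr1", 1_000, 31_000, "+", basal_rate=1.0)
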
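from __future__ import annotations

import numpy as np
import pytest

from srnaevol import simulate as sim


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_simulation():
    """A small planted-cluster simulation shared across read-level tests:
    one cluster per class, 300 reads each, no sequencing errors."""
    genome = {"chr1": sim.simulate_genome(25000, 0.5, seed=7)}
    specs = list(sim.default_cluster_specs().values())
    for s in specs:
        s.n_reads = 300
    genome, truth = sim.plant_clusters(genome, specs, seed=8)
    reads, alignments, sam_rows = sim.simulate_reads(
        genome, truth, specs, error_rate=0.0, seed=9
    )
    return {
        "genome": genome,
        "truth": truth,
        "specs": specs,
        "reads": reads,
        "alignments": alignments,
        "sam_rows": sam_rows,
    }
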
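import numpy as np
import pytest

import pufclip as pc
from pufclip.genome import GenomeModel


@pytest.fixture(scope="session")
def random_2kb_genome():
    rng = np.random.default_rng(0)
    seq = "".join(rng.choice(list("ACGT"), size=2000))
    return GenomeModel(chrom_sequences={"c": seq})


@pytest.fixture(scope="session")
def default_sim():
    """Study-default simulation: 50 genes, one planted element each,
    deletion prob 0.3, duplication 0.3, two replicates."""
    genome = pc.make_genome(n_genes=50, seed=1)
    truth = pc.plant_elements(genome, seed=2)
    sim = pc.simulate_clip_reads(genome, truth, pc.ClipSimConfig())
    return genome, truth, sim


@pytest.fixture(scope="session")
def default_run(default_sim):
    """Full pipeline over the study-default simulation."""
    genome, truth, sim = default_sim
    result = pc.run_pipeline_from_sim(sim, genome, n_perm=500, seed=5)
    return genome, truth, sim, result
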
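import numpy as np
import pytest

import cinc


@pytest.fixture(scope="session")
def small_system():
    """10-residue apo/bound ensembles with one full and one partial shift."""
    apo, bound, site, spec = cinc.synth_protein_system(
        n_residues=10, signal_residues={5: 1.0, 7: 0.5}, frames=2000,
        n_replicates=3, seed=11)
    return apo, bound, site, spec


@pytest.fixture(scope="session")
def score_table(small_system):
    apo, bound, _, _ = small_system
    records = cinc.score_states(apo, bound, ligand_state="ligandX")
    return cinc.aggregate(records)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
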
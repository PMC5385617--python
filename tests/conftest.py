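import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

import treclineage as tl


@pytest.fixture(scope="session")
def reference():
    """Small germline reference shared across tests."""
    return tl.build_germline_reference(6, 3, seed=1)


@pytest.fixture(scope="session")
def small_cohort(reference):
    """Two patients, nine compartments, default planted sharing."""
    model = tl.SharingModel(
        patients=2, clone_pool_size=150, cells_per_compartment=1500, seed=3
    )
    return model, tl.simulate_cohort(model, reference)


@pytest.fixture()
def table_pair():
    """Two hand-built clonotype tables with a known shared key."""

    def make(sample_id, entries):
        clonotypes = []
        for v, j, junc, count in entries:
            aa, productive = tl.translate_junction(junc)
            clonotypes.append(tl.Clonotype(v, j, junc, aa, productive, count))
        return tl.ClonotypeTable.from_clonotypes(clonotypes, sample_id)

    a = make("A", [("TRBV12-4", "TRBJ1-2", "TGTGCCAAATTT", 3),
                   ("TRBV1-1", "TRBJ1-2", "TGTGCCCCCTTT", 1)])
    b = make("B", [("TRBV12-4", "TRBJ1-2", "TGTGCCAAATTT", 1),
                   ("TRBV2-1", "TRBJ2-1", "TGTGCCGGGTTT", 3)])
    return a, b
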
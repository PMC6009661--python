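import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from duplexfid import ErrorModel, generate_reference, simulate_molecule
from duplexfid.align import align_to_reference
from duplexfid.consensus import StrandRead


@pytest.fixture(scope="session")
def amplicon():
    """A 500-bp all-4-mer amplicon, the study's standard template shape."""
    return generate_reference(500, seed=11)


@pytest.fixture(scope="session")
def zero_model():
    return ErrorModel.zero()


def perfect_read(seq: str, strand: str, molecule_id: str = "m", n_passes: int = 15) -> StrandRead:
    """A consensus-grade read with saturated qualities."""
    return StrandRead(molecule_id, strand, seq, np.full(len(seq), 93), n_passes)


def aligned_pair(sim, amplicon, n_passes: int = 15):
    """Align both strands of a noiseless simulated molecule."""
    first = align_to_reference(perfect_read(sim.first_strand, "first", n_passes=n_passes), amplicon)
    second = align_to_reference(perfect_read(sim.second_strand, "second", n_passes=n_passes), amplicon)
    return first, second
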
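import numpy as np
import pytest

from seqscape import SimulationSpec, build_msl, simulate, write_simulation
from seqscape.kselect import AlignmentRecord, assign_k


def random_dna(rng: np.random.Generator, n: int, alphabet_size: int = 4) -> str:
    return "".join("ACGT"[c] for c in rng.integers(0, alphabet_size, size=n))


@pytest.fixture(scope="session")
def catcat_msl():
    """The small worked example with two CAT mountains and a TT mountain."""
    return build_msl("CATCATTTG")


@pytest.fixture(scope="session")
def sim_data():
    """Default study conditions: 2 kb genome, one 40 bp repeat x2, 100 bp reads, 30x."""
    return simulate(SimulationSpec(seed=0))


@pytest.fixture(scope="session")
def sim_files(sim_data, tmp_path_factory):
    out = tmp_path_factory.mktemp("sim")
    return write_simulation(sim_data, out)


def truth_assignments(data, msl=None):
    """k assignments straight from the simulator's ground-truth positions."""
    if msl is None:
        msl = {data.ref_name: build_msl(data.genome)}
    out = {}
    for r in data.reads:
        aln = AlignmentRecord(r.read_id, data.ref_name, r.start, len(r.seq), r.is_reverse)
        out[r.read_id] = assign_k(r.read_id, [aln], msl)
    return out
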
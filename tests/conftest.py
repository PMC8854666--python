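import io

import numpy as np
import pytest

from sharcexo import parse_sam
from sharcexo.alignment import GappedAlignment, Segment
from sharcexo.simulate import SimulationConfig, make_toy_structure, simulate_experiment


def ga(read_id, *segs, cls=None):
    """Build a GappedAlignment from (ref, start, end[, strand]) tuples."""
    segments = tuple(Segment(*s) if not isinstance(s, Segment) else s for s in segs)
    aln = GappedAlignment(read_id, segments)
    aln.alignment_class = cls
    return aln


@pytest.fixture(scope="session")
def sim():
    """Standard synthetic experiment: 200 crosslinks on the two-hairpin
    structure, 10 reads each, trim offsets uniform on 3-7, fixed seed."""
    cfg = SimulationConfig(seed=1, trim_weights=(0.2, 0.2, 0.2, 0.2, 0.2))
    return simulate_experiment(cfg)


@pytest.fixture(scope="session")
def sim_alns(sim):
    return parse_sam(io.StringIO(sim.sam_text))


@pytest.fixture(scope="session")
def toy():
    return make_toy_structure("two_helix_loop", seed=0)


@pytest.fixture(scope="session")
def toy_model(toy):
    return toy.to_structure_model()


@pytest.fixture(scope="session")
def toy_mask(toy):
    return {toy.name: toy.ss_mask()}


@pytest.fixture()
def rng():
    return np.random.default_rng(20260927)
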
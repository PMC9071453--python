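import os
import sys

import pytest

sys.path.insert(0, os.path.dirname(__file__))

from ripscape.annotation import sanitize
from ripscape.simulate import SimulationConfig, simulate_annotation, simulate_short_read_alignments


@pytest.fixture(scope="session")
def default_cfg():
    return SimulationConfig(seed=7)


@pytest.fixture(scope="session")
def default_sim(default_cfg):
    return simulate_annotation(default_cfg)


@pytest.fixture(scope="session")
def default_san(default_sim):
    return sanitize(default_sim.annotation)


@pytest.fixture(scope="session")
def default_short_reads(default_cfg, default_sim):
    reads, truth = simulate_short_read_alignments(default_cfg, default_sim)
    return reads, truth
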
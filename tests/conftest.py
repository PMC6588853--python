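import numpy as np
import pytest

import smrtsim as sm
from smrtsim import fixtures as fx
from smrtsim.simulate import SimulationConfig


@pytest.fixture(scope="session")
def small_genome():
    return fx.random_genome(fx.FixtureSpec(genome_length=20_000, seed=7))


@pytest.fixture(scope="session")
def baseline_profile():
    """Context-free profile with realistic rates, mixed pass numbers and
    nonzero presumed-unaligned ends."""
    return sm.uniform_profile(
        0.09, 0.04, 0.01, 3000, {1: 0.5, 2: 0.3, 3: 0.2},
        head_ratio=0.1, tail_ratio=0.05)


@pytest.fixture(scope="session")
def sim_corpus(small_genome, baseline_profile):
    """A small simulated corpus shared by consistency checks."""
    reads, truths, report = sm.simulate_run(
        small_genome, baseline_profile, SimulationConfig(n_reads=60, seed=3))
    return reads, truths, report


def rng(seed=0):
    return np.random.default_rng(seed)
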
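import numpy as np
import pytest

from boa.genome import ChromosomeMap, SnpMap
from boa.phasing import default_suite
from boa.pipeline import analyze_dataset, simulate_scenario


@pytest.fixture
def rng():
    return np.random.Generator(np.random.PCG64(1234))


@pytest.fixture
def small_map():
    return SnpMap(
        [
            ChromosomeMap("chr1", 1.0, np.linspace(0.01, 0.99, 8)),
            ChromosomeMap("chr2", 0.5, np.linspace(0.01, 0.49, 4)),
        ]
    )


@pytest.fixture(scope="session")
def tiny_dataset():
    """A miniature three-way crossbreeding dataset (seconds to simulate)."""
    return simulate_scenario("close", seed=11, scale=0.05)


@pytest.fixture(scope="session")
def tiny_analysis(tiny_dataset):
    """Phasing + libraries + assignments on the miniature dataset."""
    suite = default_suite(core_tails=[(20, 20), (30, 20)], min_surrogates=4)
    return analyze_dataset(
        tiny_dataset,
        suite=suite,
        fr_values=(0.0, 10.0, 20.0),
        post_rules=(False, True),
    )
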
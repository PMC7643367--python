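import numpy as np
import pytest

from introscan import synth, timeline

EURASIAN_LEAVES = [
    "Southern_Chinese_wild",
    "Southern_Chinese_domestic",
    "Tibetan_wild",
    "Northern_Chinese_wild",
    "Northern_Chinese_domestic",
    "European_domestic",
    "European_wild",
]

ASIAN_LEAVES = EURASIAN_LEAVES[:5]


@pytest.fixture(scope="session")
def pig_tree() -> timeline.DatedTree:
    return timeline.default_sus_tree()


@pytest.fixture(scope="session")
def small_config() -> synth.SimConfig:
    """A compact cohort: 11 genomes over a 60-kb window, 8 panel SVs."""
    return synth.SimConfig(
        seed=11,
        genome_length=60_000,
        depth=20.0,
        error_rate=0.0,
        pattern_window_SA=(5_000, 25_000),
        pattern_window_A=(30_000, 55_000),
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return synth.simulate_dataset(small_config, n_per_pattern=2, sv_length_range=(150, 800))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20_240_901)
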
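import pytest

from enhancerkit.intervals import GenomeLayout
from enhancerkit.simulate import SimulationConfig, simulate_experiment

SMALL_GENOME = {"chr1": 8_000_000, "chr2": 8_000_000}


def small_config(seed: int = 1, **overrides) -> SimulationConfig:
    """A seconds-scale simulated experiment shared across test modules."""
    base = dict(
        seed=seed,
        n_enhancers=60,
        n_genes=60,
        n_se_clusters=4,
        n_lncrnas=30,
        n_spurious_peaks=20,
        n_decoys=6,
        genome=GenomeLayout(SMALL_GENOME),
    )
    base.update(overrides)
    return SimulationConfig(**base)


@pytest.fixture(scope="session")
def small_experiment():
    return simulate_experiment(small_config())
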
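import numpy as np
import pytest
from hypothesis import settings

from modmotif.region_select import differential_track, top_windows, window_sequences
from modmotif.simulate import SimulationConfig, simulate_genome, simulate_tracks

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_run():
    """The standard synthetic dataset (200 kb, planted ATC, seed 1),
    pushed through control subtraction and top-100 window extraction."""
    config = SimulationConfig(seed=1)
    genome = simulate_genome(config.genome_length, config.gc, config.seed)
    test, control = simulate_tracks(genome, config)
    diff = differential_track(test, control)
    windows = top_windows(diff, genome, width=10, k=100)
    seqs = window_sequences(windows, genome)
    return {
        "config": config,
        "genome": genome,
        "test": test,
        "control": control,
        "diff": diff,
        "windows": windows,
        "seqs": seqs,
    }


@pytest.fixture(scope="session")
def planted_seqs():
    """50 length-10 sequences, each with ATC planted at a random offset."""
    rng = np.random.default_rng(0)
    seqs = []
    for _ in range(50):
        s = rng.choice(list("ACGT"), 10)
        j = int(rng.integers(8))
        s[j : j + 3] = list("ATC")
        seqs.append("".join(s))
    return seqs
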
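import numpy as np
import pandas as pd
import pytest

from medipdmr import (
    GenomeIndex,
    SimulationConfig,
    filter_windows,
    generate_genome,
    simulate_counts,
)


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(
        n_chromosomes=1,
        chromosome_length=50_000,
        n_case_samples=4,
        n_control_samples=4,
        n_spiked_regions=5,
        rng_seed=101,
    )


@pytest.fixture(scope="session")
def small_sim(small_config):
    """A 50-window simulated experiment with 5 spiked regions."""
    genome = generate_genome(small_config)
    matrix, truth = simulate_counts(genome, small_config)
    return genome, matrix, truth


@pytest.fixture(scope="session")
def filtered_small(small_sim):
    _, matrix, _ = small_sim
    return filter_windows(matrix)


@pytest.fixture
def toy_genome():
    rng = np.random.default_rng(0)
    seq = "".join(rng.choice(list("ACGT"), size=10_000))
    return GenomeIndex({"chrA": seq})


def make_results(p_values, chrom="chr1", window=1000, log2fc=None, start0=0):
    """Build a per-window results frame from a p-value track.

    ``None`` entries stand for depth-filtered (untested) windows and are
    omitted from the frame, leaving a coordinate gap.
    """
    rows = []
    for i, p in enumerate(p_values):
        if p is None:
            continue
        rows.append(
            {
                "chromosome": chrom,
                "start": start0 + i * window,
                "end": start0 + (i + 1) * window,
                "index": i,
                "log2fc": 1.0 if log2fc is None else log2fc[i],
                "p_value": p,
                "fdr": min(1.0, p * 2),
            }
        )
    return pd.DataFrame(rows)
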
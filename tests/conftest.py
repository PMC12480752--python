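import numpy as np
import pytest

import mcrigor as mr


@pytest.fixture
def tiny_counts() -> mr.CountMatrix:
    """5 cells x 4 features, hand-written."""
    values = np.array(
        [
            [3, 0, 1, 2],
            [0, 2, 2, 0],
            [1, 1, 0, 3],
            [2, 0, 1, 1],
            [0, 3, 2, 1],
        ]
    )
    return mr.CountMatrix(values, [f"c{i}" for i in range(5)], [f"g{j}" for j in range(4)])


@pytest.fixture(scope="session")
def sim_bundle():
    """Small simulated dataset with a partially mixed partition, shared by tests.

    600 cells, 12 true metacells at gamma* = 50, 300 features; two pairs of
    true metacells replaced by 50/50 mixtures.
    """
    config = mr.GeneratorConfig(p=300, gamma_star=50, seed=7)
    counts, truth = mr.simulate_dataset(config, 600)
    rng = np.random.default_rng(7)
    partition, flags = mr.make_mixed_partition(truth, 0.3, rng)
    norm = mr.normalize_and_select(counts, 300)
    return {
        "config": config,
        "counts": counts,
        "truth": truth,
        "partition": partition,
        "flags": flags,
        "norm": norm,
    }
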
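import numpy as np
import pytest

from mirmeta.datasets import InteractionRecord
from mirmeta.simulate import GeneratorConfig, simulate_study


@pytest.fixture(scope="session")
def small_table():
    """4 miRNAs x 5 candidates with deterministic, distinct energies."""
    rng = np.random.default_rng(11)
    records = []
    for i in range(4):
        energies = rng.uniform(-30, -5, size=5)
        for j, e in enumerate(energies):
            records.append(
                InteractionRecord(f"m{i}", f"g{i}_{j}", "positive", float(e))
            )
    return records


@pytest.fixture(scope="session")
def default_study():
    """One seeded default-sized synthetic study, shared across tests."""
    return simulate_study(GeneratorConfig(seed=7))
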
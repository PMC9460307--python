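import sys
from pathlib import Path

import numpy as np
import pytest
from hypothesis import settings

sys.path.insert(0, str(Path(__file__).parent))  # expose tests/_oracles.py

from tdpatterns import CohortConfig, generate_cohort, generate_separability_variants

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


def random_events(rng: np.random.Generator, n_events: int) -> list[tuple[int, float]]:
    """Random merged event list: distinct sorted times, positive energies."""
    times = np.sort(rng.choice(1440, size=n_events, replace=False))
    energies = rng.uniform(50.0, 2500.0, size=n_events)
    return [(int(t), float(e)) for t, e in zip(times, energies)]


@pytest.fixture(scope="session")
def small_cohort():
    """Well-separated cohort of 120 participants for cross-module tests."""
    cfg = generate_separability_variants(
        CohortConfig(n_participants=120, seed=42), "well_separated"
    )
    recalls, participants, true_labels = generate_cohort(cfg)
    return recalls, participants, true_labels
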
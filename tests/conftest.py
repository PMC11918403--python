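import numpy as np
import pytest

from ordrisk import (
    apply_exclusions,
    build_design,
    draw_agents,
    simulate_choices,
)


@pytest.fixture(scope="session")
def in_person_monetary():
    return build_design("in_person", "monetary")


@pytest.fixture(scope="session")
def small_dataset(in_person_monetary):
    """5 noisy classic-utility agents on the full in-person design."""
    rng = np.random.default_rng(42)
    agents = draw_agents(5, rng, noise_sd=0.4)
    return simulate_choices(agents, in_person_monetary, rng)


@pytest.fixture(scope="session")
def small_filtered(small_dataset):
    filtered, _ = apply_exclusions(small_dataset)
    return filtered
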
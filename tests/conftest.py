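import numpy as np
import pytest

from mrgap import glycation as gl
from mrgap import simulate as sim
from mrgap.summary_stats import HarmonizedSet


def spawn_seeds(root: int, n: int) -> list[int]:
    """Independent child seeds (< 2**31) from one root seed."""
    return [int(c.generate_state(1)[0] >> 1) for c in np.random.SeedSequence(root).spawn(n)]


@pytest.fixture
def hand_set() -> HarmonizedSet:
    """Three SNPs with unit exposure effects: IVW is the plain weighted
    mean of (0.5, 0.7, 0.6) -> 0.6, fixed SE sqrt(1/300), Q = 2."""
    return HarmonizedSet.from_arrays(
        beta_exp=[1.0, 1.0, 1.0],
        se_exp=[0.05, 0.05, 0.05],
        beta_out=[0.5, 0.7, 0.6],
        se_out=[0.1, 0.1, 0.1],
    )


@pytest.fixture(scope="session")
def strong_set() -> HarmonizedSet:
    """One simulated study in the strong-instrument (NOME) regime."""
    return sim.simulate_harmonized(sim.scenario_presets("strong_instrument", seed=20_240_101))


@pytest.fixture(scope="session")
def cohort():
    """One default synthetic cohort with derived columns attached."""
    df = sim.simulate_cohort(sim.CohortSimConfig(seed=20_240_102))
    return gl.add_derived_columns(df)
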
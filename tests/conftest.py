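import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20140905)


@pytest.fixture
def default_design():
    from stovewedge import StepWedgeDesign, randomize_wedge_order

    order = randomize_wedge_order(12, seed=42)
    return StepWedgeDesign.from_wedge_order(order)


@pytest.fixture
def small_panel():
    """A small but estimable panel: 12 groups x 1 sector, ~8 children each."""
    from stovewedge import (
        SimulationParams,
        StepWedgeDesign,
        generate_cohort,
        randomize_wedge_order,
        simulate_panel,
    )

    order = randomize_wedge_order(12, seed=7)
    design = StepWedgeDesign.from_wedge_order(order, sectors_per_group=1)
    params = SimulationParams(theta=-0.3, mean_children_per_sector=8, seed=99)
    cohort = generate_cohort(design, params)
    panel = simulate_panel(design, cohort, params)
    return design, params, cohort, panel
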
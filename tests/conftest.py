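import pytest

from beemarkers import (
    build_design,
    make_ground_truth,
    normalize,
    detection_filter,
    simulate_colonies,
    simulate_quant,
)

POPS = ["ON", "CA1", "CA2", "Ch", "SK"]


@pytest.fixture(scope="session")
def colonies():
    """Sixty founder colonies over five populations, wide HB range."""
    return simulate_colonies(12, POPS, seed=11)


@pytest.fixture(scope="session")
def design(colonies):
    return build_design(colonies, n_restarts=3, seed=12)


@pytest.fixture(scope="session")
def marker_sim(colonies, design):
    """Quant simulation with five planted markers among 200 proteins."""
    truth = make_ground_truth(
        200, POPS, n_markers=5, marker_beta=0.8, seed=13
    )
    return simulate_quant(colonies, design, truth, seed=14)


@pytest.fixture(scope="session")
def standardized(marker_sim):
    return normalize(detection_filter(marker_sim.matrix))
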
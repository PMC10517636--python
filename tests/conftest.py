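import pytest

from statemotif.motifs import motif_types
from statemotif.network_io import StateNetwork
from statemotif.synthetic import FixtureSpec, plant_motifs, random_state_network


def net_from(edges, states):
    return StateNetwork.from_edges(edges, states)


@pytest.fixture
def triangle_net():
    return net_from(
        [("A", "B"), ("B", "C"), ("A", "C")],
        {"A": "active", "B": "active", "C": "active"},
    )


@pytest.fixture
def path4_net():
    return net_from(
        [("a", "b"), ("b", "c"), ("c", "d")],
        {n: "active" for n in "abcd"},
    )


@pytest.fixture
def triangle_type():
    return next(t for t in motif_types(3) if t.label == "I")


@pytest.fixture
def path3_type():
    return next(t for t in motif_types(3) if t.label == "II")


@pytest.fixture
def small_random_net():
    return random_state_network(
        FixtureSpec(n_nodes=12, n_edges=24, state_alphabet=("a", "b", "c"), seed=5)
    )


@pytest.fixture
def planted_net(triangle_type):
    """Background G(60, 90) with uniform 4-state labels plus 40 disjoint
    all-active triangles: the planted-motif study fixture."""
    bg = random_state_network(FixtureSpec(n_nodes=60, n_edges=90, seed=42))
    return plant_motifs(bg, triangle_type, ["active"] * 3, copies=40)


ALL_ACTIVE_TRIANGLE_ID = "3:111:active;active;active"
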
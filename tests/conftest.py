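import pytest

from amtsim.amt_model import ModelParams, initial_states
from amtsim.cpn_core import Arc, ColorSet, Marking, Net, Place, Transition, UNIT
from amtsim.explorer import load_fixture_protocols

UNIT_CS = ColorSet("UNIT", "UNIT")
REAL_CS = ColorSet("REAL", "REAL")


@pytest.fixture
def params():
    return ModelParams()


@pytest.fixture
def meniere_initial():
    """Liver excess with spleen and kidney deficiency; other organs balanced."""
    return initial_states(liver=5.0, spleen=1.0, kidney=1.0)


@pytest.fixture
def reference_protocol():
    return load_fixture_protocols()["Ref"]


@pytest.fixture
def unit_chain_net():
    """p1 -> t1 -> p2 -> t2 -> p3 with unit tokens (no branching)."""
    net = Net(
        places=[Place(p, UNIT_CS) for p in ("p1", "p2", "p3")],
        transitions=[Transition("t1"), Transition("t2")],
        arcs=[
            Arc("p1", "t1", ("unit",)), Arc("t1", "p2", ("unit",)),
            Arc("p2", "t2", ("unit",)), Arc("t2", "p3", ("unit",)),
        ],
    )
    return net, Marking({"p1": [UNIT]})


@pytest.fixture
def conflict_net():
    """Two transitions competing for the single token in a shared place."""
    net = Net(
        places=[Place(p, UNIT_CS) for p in ("p", "qa", "qb")],
        transitions=[Transition("ta"), Transition("tb")],
        arcs=[
            Arc("p", "ta", ("unit",)), Arc("ta", "qa", ("unit",)),
            Arc("p", "tb", ("unit",)), Arc("tb", "qb", ("unit",)),
        ],
    )
    return net, Marking({"p": [UNIT]})
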
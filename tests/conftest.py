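import numpy as np
import pytest

from medeff import Panel, Role, UnitProfile, Variable, VariableSchema


@pytest.fixture
def xy_schema():
    return VariableSchema(
        [Variable("x", Role.INPUT), Variable("y", Role.DESIRABLE)]
    )


@pytest.fixture
def three_unit_panel(xy_schema):
    """Hand-solved fixture: C is benchmarked against the A-B facet at θ*=0.5."""
    return Panel(
        xy_schema,
        [
            UnitProfile("A", {"x": 1.0, "y": 2.0}),
            UnitProfile("B", {"x": 2.0, "y": 4.0}),
            UnitProfile("C", {"x": 2.0, "y": 2.0}),
        ],
    )


@pytest.fixture
def xyz_schema():
    return VariableSchema(
        [
            Variable("x", Role.INPUT),
            Variable("y", Role.DESIRABLE),
            Variable("z", Role.UNDESIRABLE),
        ]
    )


def make_panel(schema, rows):
    """rows: mapping id -> value mapping (metadata-free helper)."""
    return Panel(schema, [UnitProfile(uid, vals) for uid, vals in rows.items()])


@pytest.fixture
def rng():
    return np.random.default_rng(20240)
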
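"""Shared model builders for the test suite."""

import pytest

from hexlogic import (
    Atom,
    Component,
    LogicalFunction,
    LogicalModel,
    Not,
    Or,
    PriorityScheme,
)


@pytest.fixture
def dn_model():
    """The two-marker lateral-inhibition cell (Green input, Red internal)."""
    from hexlogic.fixtures import delta_notch_model

    return delta_notch_model()


def make_chain_model():
    """Input I drives P which drives Q: exposes the one-step-per-update lag."""
    return LogicalModel(
        components=[
            Component("I", is_input=True),
            Component("P"),
            Component("Q"),
        ],
        functions=[
            LogicalFunction.boolean("P", Atom("I", ">=", 1)),
            LogicalFunction.boolean("Q", Atom("P", ">=", 1)),
        ],
    )


def make_multivalued_model(priorities=None):
    """Ternary X pushed by input A or by Y; Boolean Y reads high X."""
    return LogicalModel(
        components=[
            Component("A", max_level=2, is_input=True),
            Component("X", max_level=2),
            Component("Y"),
        ],
        functions=[
            LogicalFunction(
                "X",
                [
                    (2, Atom("A", ">=", 2)),
                    (1, Or(Atom("A", ">=", 1), Atom("Y", ">=", 1))),
                ],
            ),
            LogicalFunction.boolean("Y", Atom("X", ">=", 2)),
        ],
        priorities=priorities,
    )


def make_priority_model():
    """Two Boolean components with R in a strictly higher class than G."""
    scheme = PriorityScheme([[("R", "both")], [("G", "both")]])
    return LogicalModel(
        components=[Component("G"), Component("R")],
        functions=[
            LogicalFunction.boolean("G", Atom("R", ">=", 1)),
            LogicalFunction.boolean("R", Not(Atom("G", ">=", 1))),
        ],
        priorities=scheme,
    )


@pytest.fixture
def chain_model():
    return make_chain_model()


@pytest.fixture
def mv_model():
    return make_multivalued_model()
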
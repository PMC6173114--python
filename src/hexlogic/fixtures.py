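"""Built-in epithelium models.

The Delta–Notch lateral-inhibition cell is an idealised two-marker Boolean
model: the Green marker (the Notch-activity readout) is induced by Red
secreted by neighbouring cells, while Red (the Delta signal) is induced by
low levels of Green in the same cell. Green carries no regulatory rule of
its own — it is the cell's *integration input*, set each step by a
juxtacrine integration rule over the neighbourhood; Red is the single
internal component with function ``Red = NOT Green``.

Wired over a grid with the contact rule ("Green induced when at least one
contacting cell is Red"), the stable patterns are exactly the salt-and-pepper
configurations whose Red set is a maximal independent set of the contact
graph.
"""

from __future__ import annotations

from .epithelium import EpitheliumModel, parse_integration_rule
from .errors import ConfigError
from .hexgrid import GridTopology
from .logic_core import Atom, Component, LogicalFunction, LogicalModel, Not
from .simulation import ALPHA_ASYNC, SimulationConfig

__all__ = ["delta_notch_model", "fixture_delta_notch", "RULE_VARIANTS", "WRAP_MODES"]

#: rule variant name -> integration-rule text for the Green input
RULE_VARIANTS = {
    "contact_atleast1": "Red>=1 [1:1] atleast 1",
    "contact_all": "Red>=1 [1:1] all",
    "dist3_atleast12": "Red>=1 [1:3] atleast 12",
}

WRAP_MODES = {
    "none": (False, False),
    "h": (True, False),
    "v": (False, True),
    "torus": (True, True),
}


def delta_notch_model() -> LogicalModel:
    """The two-marker lateral-inhibition cell.

    Green is the integration input (induced by neighbouring Red, via the
    epithelium's integration rule); Red is internal, induced by low Green in
    the same cell.
    """
    return LogicalModel(
        components=[
            Component("Green", is_input=True),
            Component("Red"),
        ],
        functions=[
            LogicalFunction.boolean("Red", Not(Atom("Green", ">=", 1))),
        ],
    )


def fixture_delta_notch(
    width: int,
    height: int,
    wrap: str = "none",
    rule_variant: str = "contact_atleast1",
    alpha: float = 0.25,
    seed: int = 0,
    max_steps: int = 1000,
) -> tuple[EpitheliumModel, SimulationConfig]:
    """The lateral-inhibition epithelium on a ``width x height`` grid.

    ``wrap`` is one of ``none``/``h``/``v``/``torus``; ``rule_variant`` picks
    the integration rule for Green (see :data:`RULE_VARIANTS`). The initial
    state is all-zero; the default simulation settings are α-asynchronous
    with α = 0.25.
    """
    if wrap not in WRAP_MODES:
        raise ConfigError(f"unknown wrap mode {wrap!r} (expected one of {sorted(WRAP_MODES)})")
    if rule_variant not in RULE_VARIANTS:
        raise ConfigError(
            f"unknown rule variant {rule_variant!r} (expected one of {sorted(RULE_VARIANTS)})"
        )
    wh, wv = WRAP_MODES[wrap]
    topo = GridTopology(width, height, wrap_horizontal=wh, wrap_vertical=wv)
    epi = EpitheliumModel(
        topology=topo,
        models={"delta_notch": delta_notch_model()},
        integration={
            "Green": [parse_integration_rule(RULE_VARIANTS[rule_variant], "Green", 1)]
        },
    )
    config = SimulationConfig(
        scheme=ALPHA_ASYNC, alpha=alpha, seed=seed, max_steps=max_steps
    )
    return epi, config
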
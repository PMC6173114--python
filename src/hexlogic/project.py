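"""Project files: a YAML dialect describing a full epithelium simulation.

A project declares the grid, the cellular models (inline SBML-qual text or a
path relative to the project file), the per-region model assignment, the
input semantics (positional maps, integration rules), perturbations, the
initial state and the simulation settings. ``save_project`` always embeds
models inline and emits keys in sorted order, so two saves of the same model
are byte-identical.

Regions anywhere in the file are either ``all``, an explicit ``cells`` list
of ``[col, row]`` pairs, or an inclusive ``rect: [col0, row0, col1, row1]``.
"""

from __future__ import annotations

import os
from typing import Any

import numpy as np
import yaml

from .epithelium import (
    EpitheliumModel,
    GridState,
    Perturbation,
    PositionalInput,
    parse_integration_rule,
    rule_to_text,
)
from .errors import ParseError, ValidationError
from .hexgrid import CellCoord, GridTopology
from .logic_core import PriorityScheme
from .sbml_qual import read_sbml_qual, write_sbml_qual
from .simulation import SimulationConfig

__all__ = ["load_project", "save_project"]

_WRAP_NAMES = {
    (False, False): "none",
    (True, False): "horizontal",
    (False, True): "vertical",
    (True, True): "torus",
}
_WRAP_MODES = {v: k for k, v in _WRAP_NAMES.items()}


def _fail(msg: str) -> None:
    raise ParseError(msg)


def _require(doc: dict, key: str, where: str) -> Any:
    if not isinstance(doc, dict) or key not in doc:
        _fail(f"missing {key!r} in {where}")
    return doc[key]


def _parse_cells(spec, where: str) -> list[CellCoord]:
    out = []
    for item in spec:
        if not (isinstance(item, (list, tuple)) and len(item) == 2):
            _fail(f"{where}: cells entries must be [col, row] pairs")
        out.append(CellCoord(int(item[0]), int(item[1])))
    return out


def _parse_region(spec, topo: GridTopology, where: str) -> frozenset[CellCoord] | None:
    """None means all cells."""
    if spec == "all" or spec is None:
        return None
    if isinstance(spec, dict) and "cells" in spec:
        return frozenset(_parse_cells(spec["cells"], where))
    if isinstance(spec, dict) and "rect" in spec:
        r = spec["rect"]
        if not (isinstance(r, (list, tuple)) and len(r) == 4):
            _fail(f"{where}: rect must be [col0, row0, col1, row1]")
        c0, r0, c1, r1 = (int(v) for v in r)
        return frozenset(
            CellCoord(c, w)
            for w in range(r0, r1 + 1)
            for c in range(c0, c1 + 1)
        )
    _fail(f"{where}: region must be 'all', {{cells: ...}} or {{rect: ...}}")


def load_project(path: str) -> tuple[EpitheliumModel, SimulationConfig]:
    """Load and fully validate a project file."""
    if not os.path.exists(path):
        raise ParseError(f"project file not found: {path}")
    with open(path, "r", encoding="utf-8") as fh:
        try:
            doc = yaml.safe_load(fh)
        except yaml.YAMLError as e:
            line = None
            mark = getattr(e, "problem_mark", None)
            if mark is not None:
                line = mark.line + 1
            raise ParseError(f"cannot parse project file: {e}", line=line) from None
    if not isinstance(doc, dict):
        _fail("project file must contain a mapping at top level")

    grid = _require(doc, "grid", "project")
    width = int(_require(grid, "width", "grid"))
    height = int(_require(grid, "height", "grid"))
    if width < 1:
        _fail(f"grid width must be >= 1, got {width}")
    if height < 1:
        _fail(f"grid height must be >= 1, got {height}")
    wrap = grid.get("wrap", "none")
    if wrap not in _WRAP_MODES:
        _fail(f"grid wrap must be one of {sorted(_WRAP_MODES)}, got {wrap!r}")
    wh, wv = _WRAP_MODES[wrap]
    try:
        topo = GridTopology(width, height, wrap_horizontal=wh, wrap_vertical=wv)
    except ValidationError as e:
        raise ParseError(f"grid: {e}") from None

    models_doc = _require(doc, "models", "project")
    models = {}
    for name, spec in models_doc.items():
        if isinstance(spec, dict) and "sbml" in spec:
            models[name] = read_sbml_qual(spec["sbml"])
        elif isinstance(spec, dict) and "file" in spec:
            mpath = spec["file"]
            if not os.path.isabs(mpath):
                mpath = os.path.join(os.path.dirname(os.path.abspath(path)), mpath)
            models[name] = read_sbml_qual(mpath)
        else:
            _fail(f"model {name!r}: need either 'sbml' (inline) or 'file' (path)")

    priorities_doc = doc.get("priorities", {})
    for mname, classes in priorities_doc.items():
        if mname not in models:
            _fail(f"priorities for undeclared model {mname!r}")
        scheme = PriorityScheme(
            [[(str(n), str(d)) for n, d in members] for members in classes]
        )
        m = models[mname]
        models[mname] = type(m)(m.components, m.functions, scheme)

    assign_doc = doc.get("assignment", {})
    default_model = assign_doc.get("default")
    if default_model is None:
        if len(models) != 1:
            _fail("assignment.default is required with several models")
        default_model = next(iter(models))
    assignment: dict[CellCoord, str] = {}
    for entry in assign_doc.get("regions", []):
        mname = _require(entry, "model", "assignment region")
        region = _parse_region(entry, topo, "assignment region")
        if region is None:
            _fail("assignment regions must be explicit (use 'default' for all cells)")
        for c in region:
            assignment[c] = mname

    inputs_doc = doc.get("inputs", {})
    positional = {}
    for name, spec in (inputs_doc.get("positional") or {}).items():
        overrides: dict[CellCoord, int] = {}
        for entry in (spec or {}).get("regions", []):
            level = int(_require(entry, "level", f"positional {name!r}"))
            region = _parse_region(entry, topo, f"positional {name!r}")
            if region is None:
                _fail(f"positional {name!r}: use 'default' for the whole grid")
            for c in region:
                overrides[c] = level
        positional[name] = PositionalInput(
            default_level=int((spec or {}).get("default", 0)), overrides=overrides
        )
    integration = {}
    for name, rules in (inputs_doc.get("integration") or {}).items():
        parsed = []
        for entry in rules:
            level = int(entry.get("level", 1))
            text = _require(entry, "rule", f"integration {name!r}")
            parsed.append(parse_integration_rule(text, name, level))
        integration[name] = parsed

    perturbations = []
    for entry in doc.get("perturbations", []) or []:
        comp = _require(entry, "component", "perturbation")
        level = int(_require(entry, "level", "perturbation"))
        region = _parse_region(entry.get("region", "all"), topo, "perturbation")
        perturbations.append(Perturbation(comp, level, region))

    all_names: dict[str, None] = {}
    for m in models.values():
        for c in m.components:
            all_names.setdefault(c.name, None)
    init_doc = doc.get("initial_state", {}) or {}
    fill = {
        str(k): int(v) for k, v in (init_doc.get("components") or {}).items()
    }
    default_fill = int(init_doc.get("default", 0))
    initial = GridState.filled(
        width,
        height,
        all_names,
        {n: fill.get(n, default_fill) for n in all_names},
    )
    for entry in init_doc.get("regions", []) or []:
        comp = _require(entry, "component", "initial_state region")
        level = int(_require(entry, "level", "initial_state region"))
        region = _parse_region(entry, topo, "initial_state region")
        cells = topo.cells() if region is None else region
        for c in cells:
            initial.set_level(comp, c, level)

    sim_doc = doc.get("simulation", {}) or {}
    scheme = sim_doc.get("scheme", "synchronous")
    if scheme != "synchronous" and "seed" not in sim_doc:
        _fail("simulation.seed is required for stochastic schemes")
    try:
        config = SimulationConfig(
            scheme=scheme,
            alpha=float(sim_doc.get("alpha", 1.0)),
            seed=int(sim_doc.get("seed", 0)),
            max_steps=int(sim_doc.get("max_steps", 1000)),
            bernoulli=bool(sim_doc.get("bernoulli", False)),
        )
    except Exception as e:
        raise ParseError(f"simulation settings: {e}") from None

    epi = EpitheliumModel(
        topology=topo,
        models=models,
        default_model=default_model,
        assignment=assignment,
        positional=positional,
        integration=integration,
        perturbations=perturbations,
        initial=initial,
    )
    findings = epi.validate()
    if findings:
        raise ValidationError(
            "invalid project:\n  - " + "\n  - ".join(findings)
        )
    return epi, config


def save_project(epi: EpitheliumModel, config: SimulationConfig, path: str) -> None:
    """Write a project readable by :func:`load_project`.

    Deterministic: sorted keys, models embedded inline, explicit cell lists.
    """
    findings = epi.validate()
    if findings:
        raise ValidationError(
            "refusing to save invalid project:\n  - " + "\n  - ".join(findings)
        )
    topo = epi.topology
    doc: dict[str, Any] = {
        "grid": {
            "width": topo.width,
            "height": topo.height,
            "wrap": _WRAP_NAMES[(topo.wrap_horizontal, topo.wrap_vertical)],
        },
        "models": {
            name: {"sbml": write_sbml_qual(m, model_id=name)}
            for name, m in epi.models.items()
        },
    }
    priorities = {
        name: [sorted(list(members)) for members in m.priorities.classes]
        for name, m in epi.models.items()
        if m.priorities is not None
    }
    if priorities:
        doc["priorities"] = {
            name: [[[n, d] for n, d in members] for members in classes]
            for name, classes in priorities.items()
        }
    assignment: dict[str, Any] = {"default": epi.default_model}
    by_model: dict[str, list] = {}
    for cell, mname in sorted(epi.assignment.items()):
        by_model.setdefault(mname, []).append([cell.col, cell.row])
    if by_model:
        assignment["regions"] = [
            {"model": mname, "cells": cells} for mname, cells in sorted(by_model.items())
        ]
    doc["assignment"] = assignment

    inputs: dict[str, Any] = {}
    if epi.positional:
        inputs["positional"] = {
            name: {
                "default": pmap.default_level,
                **(
                    {
                        "regions": [
                            {"cells": [[c.col, c.row]], "level": v}
                            for c, v in pmap.overrides
                        ]
                    }
                    if pmap.overrides
                    else {}
                ),
            }
            for name, pmap in sorted(epi.positional.items())
        }
    if epi.integration:
        inputs["integration"] = {
            name: [
                {"level": level, "rule": rule_to_text(by_level[level].expression)}
                for level in sorted(by_level)
            ]
            for name, by_level in sorted(epi.integration.items())
        }
    if inputs:
        doc["inputs"] = inputs

    if epi.perturbations:
        doc["perturbations"] = [
            {
                "component": p.component,
                "level": p.fixed_level,
                "region": (
                    "all"
                    if p.region is None
                    else {"cells": [[c.col, c.row] for c in sorted(p.region)]}
                ),
            }
            for p in epi.perturbations
        ]

    init: dict[str, Any] = {"default": 0}
    regions = []
    components = {}
    for name in sorted(epi.initial.levels):
        arr = epi.initial.levels[name]
        values, counts = np.unique(arr, return_counts=True)
        common = int(values[np.argmax(counts)])
        components[name] = common
        rows, cols = np.nonzero(arr != common)
        for r, c in zip(rows.tolist(), cols.tolist()):
            regions.append(
                {
                    "component": name,
                    "level": int(arr[r, c]),
                    "cells": [[c, r]],
                }
            )
    init["components"] = components
    if regions:
        init["regions"] = regions
    doc["initial_state"] = init

    doc["simulation"] = {
        "scheme": config.scheme,
        "alpha": config.alpha,
        "seed": config.seed,
        "max_steps": config.max_steps,
        "bernoulli": config.bernoulli,
    }

    text = yaml.safe_dump(doc, sort_keys=True, default_flow_style=None, width=100)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(text)
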
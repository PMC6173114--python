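"""Epithelium models: a hexagonal grid of communicating logical cells.

An :class:`EpitheliumModel` composes a :class:`~hexlogic.hexgrid.GridTopology`
with one or more cellular logical models assigned to grid regions, and gives
semantics to every *input* component of those models:

* **positional inputs** are held at a fixed per-cell level (e.g. a morphogen
  gradient painted over the grid);
* **integration inputs** are recomputed at every step from the *internal*
  components of neighbouring cells, through logical *integration rules* —
  expressions over neighbourhood-count atoms such as "at least 12 cells at
  distance up to 3 have Red >= 1".

The integration-rule concrete syntax is::

    expr   := term ('|' term)*
    term   := factor ('&' factor)*
    factor := '!' factor | '(' expr ')' | atom
    atom   := NAME '>=' INT '[' INT ':' INT ']' ('atleast' INT | 'all')

so the lateral-inhibition contact rule reads ``Red>=1 [1:1] atleast 1``.

Input resolution is two-phase: all inputs for a tissue step are computed from
the full grid state *before* any internal update, which makes the synchronous
tissue update independent of cell iteration order.

Perturbations clamp a component to a fixed level over a region (or the whole
grid); the clamp is re-applied after every update, so perturbed components
never move — the logical-modelling idiom for knock-outs and ectopic
expression.
"""

from __future__ import annotations

import copy as _copy
import re
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np

from .errors import ParseError, ValidationError
from .hexgrid import CellCoord, GridTopology
from .logic_core import And, Atom, BoolConst, CellState, Expr, LogicalModel, Not, Or

__all__ = [
    "CardAtom",
    "IntegrationRule",
    "PositionalInput",
    "Perturbation",
    "GridState",
    "EpitheliumModel",
    "parse_integration_expression",
    "parse_integration_rule",
    "eval_integration_input",
    "resolve_inputs",
    "apply_perturbations",
    "validate",
]

LEVEL_DTYPE = np.int8


# ---------------------------------------------------------------------------
# Rule atoms and rules
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CardAtom(Expr):
    """Neighbourhood-count test: cells in a distance band with component >= value.

    ``quantifier`` is ``"atleast"`` (with threshold ``k``) or ``"all"``.
    ``all`` over an empty band is false — a border cell without neighbours
    receives no signal.
    """

    component: str
    value: int
    dmin: int
    dmax: int
    quantifier: str
    k: int | None = None

    def __post_init__(self):
        if not 1 <= self.dmin <= self.dmax:
            raise ValidationError(
                f"invalid distance band [{self.dmin}:{self.dmax}] (need 1 <= dmin <= dmax)"
            )
        if self.quantifier == "atleast":
            if self.k is None or self.k < 1:
                raise ValidationError("atleast quantifier needs a threshold k >= 1")
        elif self.quantifier == "all":
            if self.k is not None:
                raise ValidationError("all quantifier takes no threshold")
        else:
            raise ValidationError(f"unknown quantifier {self.quantifier!r}")
        if self.value < 1:
            raise ValidationError("tested level must be >= 1")

    def eval(self, assignment):
        raise TypeError("CardAtom is evaluated over a neighbourhood, not a cell state")

    def atoms(self):
        yield self


@dataclass(frozen=True)
class IntegrationRule:
    """One level of an integration input: the input reaches ``level`` when
    ``expression`` holds over the cell's neighbourhood."""

    target: str
    level: int
    expression: Expr

    def __post_init__(self):
        if self.level < 1:
            raise ValidationError("integration rule level must be >= 1")


# ---------------------------------------------------------------------------
# Rule grammar (recursive descent)
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(
    r"\s*(?:(?P<name>[A-Za-z_][A-Za-z0-9_]*)|(?P<int>\d+)|(?P<sym>>=|[|&!():\[\]]))"
)


def _tokenize(text: str) -> list[tuple[str, str, int]]:
    tokens = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            rest = text[pos:].lstrip()
            if not rest:
                break
            raise ParseError(f"unexpected character {rest[0]!r}", position=pos)
        if m.group("name"):
            tokens.append(("name", m.group("name"), m.start("name")))
        elif m.group("int"):
            tokens.append(("int", m.group("int"), m.start("int")))
        else:
            tokens.append(("sym", m.group("sym"), m.start("sym")))
        pos = m.end()
    tokens.append(("eof", "", len(text)))
    return tokens


class _RuleParser:
    def __init__(self, text: str):
        self.text = text
        self.tokens = _tokenize(text)
        self.i = 0

    def peek(self):
        return self.tokens[self.i]

    def next(self):
        tok = self.tokens[self.i]
        self.i += 1
        return tok

    def expect(self, kind, value=None):
        tok = self.next()
        if tok[0] != kind or (value is not None and tok[1] != value):
            want = value if value is not None else kind
            raise ParseError(
                f"expected {want!r}, found {tok[1] or 'end of input'!r}",
                position=tok[2],
            )
        return tok

    def parse(self) -> Expr:
        e = self.expr()
        tok = self.peek()
        if tok[0] != "eof":
            raise ParseError(f"trailing input {tok[1]!r}", position=tok[2])
        return e

    def expr(self) -> Expr:
        terms = [self.term()]
        while self.peek()[:2] == ("sym", "|"):
            self.next()
            terms.append(self.term())
        return terms[0] if len(terms) == 1 else Or(*terms)

    def term(self) -> Expr:
        factors = [self.factor()]
        while self.peek()[:2] == ("sym", "&"):
            self.next()
            factors.append(self.factor())
        return factors[0] if len(factors) == 1 else And(*factors)

    def factor(self) -> Expr:
        tok = self.peek()
        if tok[:2] == ("sym", "!"):
            self.next()
            return Not(self.factor())
        if tok[:2] == ("sym", "("):
            self.next()
            e = self.expr()
            self.expect("sym", ")")
            return e
        return self.atom()

    def atom(self) -> CardAtom:
        kind, name, pos = self.next()
        if kind != "name" or name in ("atleast", "all"):
            raise ParseError(
                f"expected component name, found {name or 'end of input'!r}",
                position=pos,
            )
        self.expect("sym", ">=")
        value = int(self.expect("int")[1])
        self.expect("sym", "[")
        dmin = int(self.expect("int")[1])
        self.expect("sym", ":")
        dmax = int(self.expect("int")[1])
        self.expect("sym", "]")
        qtok = self.next()
        if qtok[:2] == ("name", "atleast"):
            k = int(self.expect("int")[1])
            quant, kk = "atleast", k
        elif qtok[:2] == ("name", "all"):
            quant, kk = "all", None
        else:
            raise ParseError(
                f"expected 'atleast' or 'all', found {qtok[1] or 'end of input'!r}",
                position=qtok[2],
            )
        if dmin > dmax:
            raise ParseError(f"distance band inverted [{dmin}:{dmax}]", position=pos)
        try:
            return CardAtom(name, value, dmin, dmax, quant, kk)
        except ValidationError as e:
            raise ParseError(str(e), position=pos) from None


def parse_integration_expression(text: str) -> Expr:
    """Parse a rule expression such as ``"Red>=1 [1:3] atleast 12"``."""
    return _RuleParser(text).parse()


def parse_integration_rule(text: str, target: str, level: int = 1) -> IntegrationRule:
    """Parse ``text`` as the rule giving ``target`` its value ``level``."""
    return IntegrationRule(target, level, parse_integration_expression(text))


def rule_to_text(expr: Expr) -> str:
    """Serialise a rule expression back to the grammar (inverse of parsing)."""
    if isinstance(expr, CardAtom):
        quant = "all" if expr.quantifier == "all" else f"atleast {expr.k}"
        return f"{expr.component}>={expr.value} [{expr.dmin}:{expr.dmax}] {quant}"
    if isinstance(expr, Not):
        return f"!({rule_to_text(expr.child)})"
    if isinstance(expr, And):
        return " & ".join(f"({rule_to_text(c)})" for c in expr.children)
    if isinstance(expr, Or):
        return " | ".join(f"({rule_to_text(c)})" for c in expr.children)
    raise ValidationError(f"cannot serialise node {type(expr).__name__}")


# ---------------------------------------------------------------------------
# Positional inputs, perturbations, grid state
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PositionalInput:
    """Per-cell fixed level for one input component: a default level plus
    explicit overrides (e.g. the graded levels of a morphogen)."""

    default_level: int = 0
    overrides: tuple[tuple[CellCoord, int], ...] = ()

    def __init__(self, default_level=0, overrides=()):
        if isinstance(overrides, Mapping):
            overrides = overrides.items()
        norm = tuple(sorted((CellCoord(*c), int(v)) for c, v in overrides))
        object.__setattr__(self, "default_level", int(default_level))
        object.__setattr__(self, "overrides", norm)

    def value(self, cell: CellCoord) -> int:
        for c, v in self.overrides:
            if c == CellCoord(*cell):
                return v
        return self.default_level

    def as_array(self, topology: GridTopology) -> np.ndarray:
        arr = np.full((topology.height, topology.width), self.default_level, LEVEL_DTYPE)
        for (col, row), v in self.overrides:
            arr[row, col] = v
        return arr


@dataclass(frozen=True)
class Perturbation:
    """Clamp ``component`` to ``fixed_level`` over ``region`` (None = all cells)."""

    component: str
    fixed_level: int
    region: frozenset[CellCoord] | None = None

    def __init__(self, component, fixed_level, region=None):
        object.__setattr__(self, "component", str(component))
        object.__setattr__(self, "fixed_level", int(fixed_level))
        if region is not None:
            region = frozenset(CellCoord(*c) for c in region)
        object.__setattr__(self, "region", region)

    def mask(self, topology: GridTopology) -> np.ndarray:
        m = np.zeros((topology.height, topology.width), dtype=bool)
        if self.region is None:
            m[:] = True
        else:
            for col, row in self.region:
                m[row, col] = True
        return m


class GridState:
    """Levels of every component in every cell; canonical order is row-major.

    Internally one small-integer array of shape ``(height, width)`` per
    component name (the union over all assigned models; a cell simply ignores
    components its model does not declare).
    """

    def __init__(self, width: int, height: int, levels: Mapping[str, np.ndarray]):
        self.width = int(width)
        self.height = int(height)
        self.levels: dict[str, np.ndarray] = {}
        for name, arr in levels.items():
            a = np.asarray(arr, dtype=LEVEL_DTYPE)
            if a.shape != (self.height, self.width):
                raise ValidationError(
                    f"level array for {name!r} has shape {a.shape}, "
                    f"expected {(self.height, self.width)}"
                )
            self.levels[name] = a.copy()

    @classmethod
    def filled(
        cls,
        width: int,
        height: int,
        components: Iterable[str],
        fill: int | Mapping[str, int] = 0,
    ) -> "GridState":
        levels = {}
        for name in components:
            v = fill.get(name, 0) if isinstance(fill, Mapping) else fill
            levels[name] = np.full((height, width), v, LEVEL_DTYPE)
        return cls(width, height, levels)

    @property
    def component_names(self) -> list[str]:
        return list(self.levels)

    def level(self, component: str, cell: CellCoord) -> int:
        col, row = cell
        return int(self.levels[component][row, col])

    def set_level(self, component: str, cell: CellCoord, value: int) -> None:
        col, row = cell
        self.levels[component][row, col] = value

    def copy(self) -> "GridState":
        return GridState(self.width, self.height, self.levels)

    def digest(self, names: Iterable[str] | None = None) -> bytes:
        names = sorted(self.levels) if names is None else sorted(names)
        return b"|".join(n.encode() + b":" + self.levels[n].tobytes() for n in names)

    def __eq__(self, other):
        if not isinstance(other, GridState):
            return NotImplemented
        return (
            self.width == other.width
            and self.height == other.height
            and set(self.levels) == set(other.levels)
            and all(np.array_equal(self.levels[n], other.levels[n]) for n in self.levels)
        )

    def __repr__(self):
        return f"GridState({self.width}x{self.height}, {len(self.levels)} components)"


# ---------------------------------------------------------------------------
# The epithelium model
# ---------------------------------------------------------------------------


class EpitheliumModel:
    """Grid topology + cellular models + input semantics + perturbations + initial state.

    ``models`` maps model names to :class:`LogicalModel`; ``assignment`` maps
    cells to model names (``default_model`` covers the rest). ``positional``
    and ``integration`` must together cover every input component of every
    assigned model, each input through exactly one of the two mechanisms.
    """

    def __init__(
        self,
        topology: GridTopology,
        models: Mapping[str, LogicalModel] | LogicalModel,
        default_model: str | None = None,
        assignment: Mapping[CellCoord, str] | None = None,
        positional: Mapping[str, PositionalInput] | None = None,
        integration: Mapping[str, Iterable[IntegrationRule]] | None = None,
        perturbations: Iterable[Perturbation] = (),
        initial: GridState | None = None,
    ):
        self.topology = topology
        if isinstance(models, LogicalModel):
            models = {"model": models}
        self.models: dict[str, LogicalModel] = dict(models)
        if default_model is None:
            if len(self.models) != 1:
                raise ValidationError(
                    "default_model is required when several models are declared"
                )
            default_model = next(iter(self.models))
        self.default_model = default_model
        self.assignment: dict[CellCoord, str] = {
            CellCoord(*c): str(m) for c, m in (assignment or {}).items()
        }
        self.positional: dict[str, PositionalInput] = dict(positional or {})
        self.integration: dict[str, dict[int, IntegrationRule]] = {}
        for name, rules in (integration or {}).items():
            if isinstance(rules, IntegrationRule):
                rules = [rules]
            by_level: dict[int, IntegrationRule] = {}
            for r in rules:
                if r.target != name:
                    raise ValidationError(
                        f"rule for {r.target!r} filed under input {name!r}"
                    )
                if r.level in by_level:
                    raise ValidationError(
                        f"duplicate integration rule for {name!r} level {r.level}"
                    )
                by_level[r.level] = r
            self.integration[name] = by_level
        self.perturbations: list[Perturbation] = list(perturbations)
        if initial is None:
            initial = self.zero_state()
        self.initial = initial

    # -- structure ---------------------------------------------------------

    def model_name_of(self, cell: CellCoord) -> str:
        return self.assignment.get(CellCoord(*cell), self.default_model)

    def model_of(self, cell: CellCoord) -> LogicalModel:
        return self.models[self.model_name_of(cell)]

    @property
    def all_component_names(self) -> list[str]:
        """Union of component names over all models, stable order."""
        seen: dict[str, None] = {}
        for m in self.models.values():
            for c in m.components:
                seen.setdefault(c.name, None)
        return list(seen)

    def component_any(self, name: str):
        for m in self.models.values():
            for c in m.components:
                if c.name == name:
                    return c
        return None

    def zero_state(self) -> GridState:
        return GridState.filled(
            self.topology.width, self.topology.height, self.all_component_names, 0
        )

    def cell_state(self, state: GridState, cell: CellCoord) -> CellState:
        model = self.model_of(cell)
        return CellState([state.level(n, cell) for n in model.names])

    def set_cell_state(self, state: GridState, cell: CellCoord, cs: CellState) -> None:
        model = self.model_of(cell)
        for name, v in zip(model.names, cs.levels):
            state.set_level(name, cell, v)

    def copy(self) -> "EpitheliumModel":
        return _copy.deepcopy(self)

    def __eq__(self, other):
        if not isinstance(other, EpitheliumModel):
            return NotImplemented
        return (
            self.topology == other.topology
            and self.models == other.models
            and self.default_model == other.default_model
            and self.assignment == other.assignment
            and self.positional == other.positional
            and self.integration == other.integration
            and self.perturbations == other.perturbations
            and self.initial == other.initial
        )

    # -- validation ---------------------------------------------------------

    def validate(self) -> list[str]:
        return validate(self)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def _eval_rule_expr(expr: Expr, atom_fn) -> bool:
    if isinstance(expr, CardAtom):
        return atom_fn(expr)
    if isinstance(expr, BoolConst):
        return expr.value
    if isinstance(expr, Not):
        return not _eval_rule_expr(expr.child, atom_fn)
    if isinstance(expr, And):
        return all(_eval_rule_expr(c, atom_fn) for c in expr.children)
    if isinstance(expr, Or):
        return any(_eval_rule_expr(c, atom_fn) for c in expr.children)
    raise ValidationError(f"unexpected node {type(expr).__name__} in integration rule")


def eval_integration_input(
    epi: EpitheliumModel, state: GridState, cell: CellCoord, input_name: str
) -> int:
    """Value of an integration input at one cell: the highest rule level whose
    expression holds over the neighbourhood, else 0.

    Reference (per-cell) semantics; the simulation engine computes the same
    quantity vectorised over the whole grid.
    """
    if input_name not in epi.integration:
        raise ValidationError(f"{input_name!r} is not declared as an integration input")
    cell = CellCoord(*cell)

    def atom_holds(atom: CardAtom) -> bool:
        band = epi.topology.cells_at_distance(cell, atom.dmin, atom.dmax)
        band.discard(cell)
        n_sat = 0
        for nb in band:
            nb_model = epi.model_of(nb)
            if atom.component not in nb_model.names:
                continue  # absent component: neighbour cannot satisfy the test
            if state.level(atom.component, nb) >= atom.value:
                n_sat += 1
        if atom.quantifier == "atleast":
            return n_sat >= atom.k
        return len(band) > 0 and n_sat == len(band)

    best = 0
    for level in sorted(epi.integration[input_name]):
        rule = epi.integration[input_name][level]
        if _eval_rule_expr(rule.expression, atom_holds):
            best = level
    return best


def resolve_inputs(epi: EpitheliumModel, state: GridState) -> GridState:
    """Return ``state`` with every input component set for every cell.

    Positional inputs take their per-cell map value; integration inputs are
    evaluated entirely from the *argument* state's internal components
    (two-phase semantics). Internal components are untouched. Perturbations
    clamping input components are honoured.
    """
    from ._engine import Engine

    return Engine(epi).resolve(state)


def apply_perturbations(epi: EpitheliumModel, state: GridState) -> GridState:
    """Clamp every perturbed component to its fixed level over its region."""
    out = state.copy()
    for p in epi.perturbations:
        if p.component not in out.levels:
            continue
        m = p.mask(epi.topology)
        arr = out.levels[p.component]
        arr[m] = p.fixed_level
    return out


def validate(epi: EpitheliumModel) -> list[str]:
    """Structural findings (empty list = valid). Human-readable, not exceptions."""
    findings: list[str] = []
    topo = epi.topology

    if epi.default_model not in epi.models:
        findings.append(f"default model {epi.default_model!r} is not declared")
    for cell, mname in epi.assignment.items():
        if not topo.contains(cell):
            findings.append(f"assignment names cell {tuple(cell)} outside the grid")
        if mname not in epi.models:
            findings.append(f"assignment references undeclared model {mname!r}")

    # global role map: name -> (is_input, max_level); conflicting roles are findings
    roles: dict[str, tuple[bool, int]] = {}
    for mname, model in epi.models.items():
        for c in model.components:
            prev = roles.get(c.name)
            if prev is None:
                roles[c.name] = (c.is_input, c.max_level)
            else:
                if prev[0] != c.is_input:
                    findings.append(
                        f"component {c.name!r} is an input in one model and internal "
                        "in another"
                    )
                if prev[1] != c.max_level:
                    findings.append(
                        f"component {c.name!r} has conflicting max_level across models"
                    )

    input_names = {n for n, (is_in, _) in roles.items() if is_in}
    for name in input_names:
        pos = name in epi.positional
        integ = name in epi.integration
        if pos and integ:
            findings.append(
                f"input {name!r} is declared both positional and integration"
            )
        elif not pos and not integ:
            findings.append(
                f"input {name!r} has neither a positional map nor integration rules"
            )

    for name in epi.positional:
        if name not in input_names:
            findings.append(f"positional map for non-input component {name!r}")
    for name, by_level in epi.integration.items():
        if name not in input_names:
            findings.append(f"integration rules for non-input component {name!r}")
            continue
        comp = epi.component_any(name)
        for level, rule in by_level.items():
            if level > comp.max_level:
                findings.append(
                    f"integration rule level {level} exceeds max_level "
                    f"{comp.max_level} of input {name!r}"
                )
            for atom in rule.expression.atoms():
                if not isinstance(atom, CardAtom):
                    findings.append(
                        f"integration rule for {name!r} contains a non-neighbourhood atom"
                    )
                    continue
                role = roles.get(atom.component)
                if role is None:
                    findings.append(
                        f"integration rule for {name!r} references unknown "
                        f"component {atom.component!r}"
                    )
                elif role[0]:
                    findings.append(
                        f"integration rule for {name!r} references input component "
                        f"{atom.component!r}; signals must come from internal components"
                    )
                elif atom.value > role[1]:
                    findings.append(
                        f"integration rule for {name!r} tests {atom.component!r} >= "
                        f"{atom.value}, above its max_level {role[1]}"
                    )

    for name, pmap in epi.positional.items():
        comp = epi.component_any(name)
        if comp is None:
            continue
        values = [pmap.default_level] + [v for _, v in pmap.overrides]
        for v in values:
            if not 0 <= v <= comp.max_level:
                findings.append(
                    f"positional level {v} out of range [0,{comp.max_level}] "
                    f"for {name!r}"
                )
        for c, _ in pmap.overrides:
            if not topo.contains(c):
                findings.append(
                    f"positional override for {name!r} at {tuple(c)} outside the grid"
                )

    clamped: dict[str, np.ndarray] = {}
    for p in epi.perturbations:
        role = roles.get(p.component)
        if role is None:
            findings.append(f"perturbation of unknown component {p.component!r}")
            continue
        if not 0 <= p.fixed_level <= role[1]:
            findings.append(
                f"perturbation clamps {p.component!r} to {p.fixed_level}, out of "
                f"range [0,{role[1]}]"
            )
        if p.region is not None:
            for c in p.region:
                if not topo.contains(c):
                    findings.append(
                        f"perturbation region for {p.component!r} includes "
                        f"{tuple(c)} outside the grid"
                    )
                    break
        m = p.mask(topo)
        prev = clamped.get(p.component)
        if prev is not None and bool((prev & m).any()):
            findings.append(
                f"overlapping perturbation regions for component {p.component!r}"
            )
        clamped[p.component] = m if prev is None else (prev | m)

    st = epi.initial
    if (st.width, st.height) != (topo.width, topo.height):
        findings.append(
            f"initial state is {st.width}x{st.height}, grid is "
            f"{topo.width}x{topo.height}"
        )
    else:
        for name, (is_in, max_level) in roles.items():
            if name not in st.levels:
                findings.append(f"initial state lacks component {name!r}")
            else:
                arr = st.levels[name]
                if arr.min() < 0 or arr.max() > max_level:
                    findings.append(
                        f"initial levels of {name!r} outside [0,{max_level}]"
                    )

    return findings
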
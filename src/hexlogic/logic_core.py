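"""Single-cell logical regulatory models.

A logical model assigns a discrete variable in ``{0..max_level}`` to each
regulatory component. *Internal* components evolve under logical regulatory
functions of the other components; *input* components carry no function — their
values are imposed from outside the cell (by a positional map or by signals
integrated from neighbouring cells, see :mod:`hexlogic.epithelium`).

Expressions are trees of :class:`Atom` tests (``component >= level``,
``component == level``, ``component < level``) combined with AND/OR/NOT. The
evaluator is polymorphic over the assignment values: plain integers give the
classical single-cell semantics, numpy arrays give the vectorised whole-grid
semantics used by the simulation engine. Both paths run the exact same code.

Multi-valued components update *stepwise*: a variable moves by at most one
level per update, toward the target level prescribed by its function.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from functools import reduce
from typing import Iterator, Mapping, Sequence

import numpy as np

from .errors import ValidationError

__all__ = [
    "Expr",
    "Atom",
    "Not",
    "And",
    "Or",
    "BoolConst",
    "TRUE",
    "FALSE",
    "Component",
    "LogicalFunction",
    "PriorityScheme",
    "LogicalModel",
    "CellState",
    "eval_expression",
    "target_level",
    "step_component",
    "update_cell",
    "is_cell_stable",
]


# ---------------------------------------------------------------------------
# Expressions
# ---------------------------------------------------------------------------

_OPS = (">=", "==", "<")


@dataclass(frozen=True)
class Expr:
    """Abstract logical expression node."""

    def eval(self, assignment: Mapping[str, object]):
        raise NotImplementedError

    def atoms(self) -> Iterator["Atom"]:
        raise NotImplementedError


@dataclass(frozen=True)
class BoolConst(Expr):
    value: bool

    def eval(self, assignment):
        return self.value

    def atoms(self):
        return iter(())


TRUE = BoolConst(True)
FALSE = BoolConst(False)


@dataclass(frozen=True)
class Atom(Expr):
    """Threshold test on one component: ``component <op> level``."""

    component: str
    op: str
    level: int

    def __post_init__(self):
        if self.op not in _OPS:
            raise ValidationError(f"unknown atom operator {self.op!r}")

    def eval(self, assignment):
        try:
            v = assignment[self.component]
        except KeyError:
            raise ValidationError(
                f"atom references unknown component {self.component!r}"
            ) from None
        if self.op == ">=":
            return v >= self.level
        if self.op == "==":
            return v == self.level
        return v < self.level

    def atoms(self):
        yield self


@dataclass(frozen=True)
class Not(Expr):
    child: Expr

    def eval(self, assignment):
        return np.logical_not(self.child.eval(assignment))

    def atoms(self):
        return self.child.atoms()


@dataclass(frozen=True)
class And(Expr):
    children: tuple[Expr, ...]

    def __init__(self, *children: Expr):
        if len(children) == 1 and isinstance(children[0], (tuple, list)):
            children = tuple(children[0])
        object.__setattr__(self, "children", tuple(children))

    def eval(self, assignment):
        if not self.children:
            return True
        return reduce(np.logical_and, (c.eval(assignment) for c in self.children))

    def atoms(self):
        return itertools.chain.from_iterable(c.atoms() for c in self.children)


@dataclass(frozen=True)
class Or(Expr):
    children: tuple[Expr, ...]

    def __init__(self, *children: Expr):
        if len(children) == 1 and isinstance(children[0], (tuple, list)):
            children = tuple(children[0])
        object.__setattr__(self, "children", tuple(children))

    def eval(self, assignment):
        if not self.children:
            return False
        return reduce(np.logical_or, (c.eval(assignment) for c in self.children))

    def atoms(self):
        return itertools.chain.from_iterable(c.atoms() for c in self.children)


def eval_expression(expr: Expr, assignment: Mapping[str, object]):
    """Evaluate ``expr`` under ``assignment`` (component name -> level).

    Values may be plain ints (returns a bool) or numpy arrays (returns a
    boolean array, evaluated elementwise).
    """
    return expr.eval(assignment)


# ---------------------------------------------------------------------------
# Components and functions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Component:
    """A regulatory component. Boolean components have ``max_level = 1``."""

    name: str
    max_level: int = 1
    is_input: bool = False

    def __post_init__(self):
        if not self.name or not isinstance(self.name, str):
            raise ValidationError("component name must be a non-empty string")
        if self.max_level < 1:
            raise ValidationError(
                f"component {self.name!r}: max_level must be >= 1, got {self.max_level}"
            )


@dataclass(frozen=True)
class LogicalFunction:
    """Regulatory function of an internal component.

    ``terms`` is an ordered list of ``(level, expression)`` pairs with distinct
    levels, stored sorted descending. The target value of the component is the
    highest level whose expression holds, else 0. A Boolean function is the
    single pair ``(1, expr)``.
    """

    owner: str
    terms: tuple[tuple[int, Expr], ...]

    def __init__(self, owner: str, terms):
        terms = tuple((int(lv), ex) for lv, ex in terms)
        levels = [lv for lv, _ in terms]
        if len(set(levels)) != len(levels):
            raise ValidationError(f"function for {owner!r}: duplicate target levels")
        if any(lv < 1 for lv in levels):
            raise ValidationError(f"function for {owner!r}: term levels must be >= 1")
        object.__setattr__(self, "owner", owner)
        object.__setattr__(
            self, "terms", tuple(sorted(terms, key=lambda t: -t[0]))
        )

    @classmethod
    def boolean(cls, owner: str, expr: Expr) -> "LogicalFunction":
        return cls(owner, [(1, expr)])

    def target(self, assignment: Mapping[str, object]):
        """Highest level whose expression holds under ``assignment``, else 0.

        Vectorised when assignment values are arrays.
        """
        values = [v for v in assignment.values() if isinstance(v, np.ndarray)]
        if values:
            out = np.zeros(values[0].shape, dtype=np.int64)
            # ascending order: a later (higher) satisfied level overwrites
            for lv, ex in sorted(self.terms, key=lambda t: t[0]):
                out = np.where(ex.eval(assignment), lv, out)
            return out
        for lv, ex in self.terms:  # descending
            if ex.eval(assignment):
                return lv
        return 0


@dataclass(frozen=True)
class PriorityScheme:
    """Ordered priority classes over (component, direction) update events.

    ``classes[0]`` has the highest priority. Directions are ``"increase"``,
    ``"decrease"`` or ``"both"``. Every internal component's increase and
    decrease must each belong to exactly one class.
    """

    classes: tuple[frozenset[tuple[str, str]], ...]

    def __init__(self, classes):
        norm = []
        for cls_members in classes:
            members = frozenset(
                (str(name), str(direction)) for name, direction in cls_members
            )
            for _, d in members:
                if d not in ("increase", "decrease", "both"):
                    raise ValidationError(f"unknown priority direction {d!r}")
            norm.append(members)
        object.__setattr__(self, "classes", tuple(norm))

    def covered_directions(self, name: str) -> list[str]:
        out = []
        for members in self.classes:
            for n, d in members:
                if n == name:
                    out.extend(["increase", "decrease"] if d == "both" else [d])
        return out


@dataclass(frozen=True)
class CellState:
    """Levels of all components of one cell, in canonical (declaration) order."""

    levels: tuple[int, ...]

    def __init__(self, levels: Sequence[int]):
        object.__setattr__(self, "levels", tuple(int(v) for v in levels))


class LogicalModel:
    """A cellular logical model: components, functions, optional priorities.

    Component declaration order is the canonical state-vector order. Exactly
    the non-input components carry a :class:`LogicalFunction`.
    """

    def __init__(
        self,
        components: Sequence[Component],
        functions: Mapping[str, LogicalFunction] | Sequence[LogicalFunction],
        priorities: PriorityScheme | None = None,
    ):
        self.components: tuple[Component, ...] = tuple(components)
        if not isinstance(functions, Mapping):
            functions = {f.owner: f for f in functions}
        self.functions: dict[str, LogicalFunction] = dict(functions)
        self.priorities = priorities
        self._index = {c.name: i for i, c in enumerate(self.components)}
        self._validate()

    # -- introspection ----------------------------------------------------

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.components]

    @property
    def inputs(self) -> list[Component]:
        return [c for c in self.components if c.is_input]

    @property
    def internals(self) -> list[Component]:
        return [c for c in self.components if not c.is_input]

    def component(self, name: str) -> Component:
        return self.components[self._index[name]]

    def index(self, name: str) -> int:
        return self._index[name]

    def __eq__(self, other):
        if not isinstance(other, LogicalModel):
            return NotImplemented
        return (
            self.components == other.components
            and self.functions == other.functions
            and self.priorities == other.priorities
        )

    def __repr__(self):
        return (
            f"LogicalModel({len(self.inputs)} inputs, "
            f"{len(self.internals)} internal: {', '.join(self.names)})"
        )

    # -- state helpers -----------------------------------------------------

    def make_state(self, values: Mapping[str, int] | Sequence[int]) -> CellState:
        if isinstance(values, Mapping):
            unknown = set(values) - set(self._index)
            if unknown:
                raise ValidationError(f"unknown components {sorted(unknown)}")
            values = [values.get(c.name, 0) for c in self.components]
        state = CellState(values)
        self.check_state(state)
        return state

    def check_state(self, state: CellState) -> None:
        if len(state.levels) != len(self.components):
            raise ValidationError(
                f"state has {len(state.levels)} levels, model has "
                f"{len(self.components)} components"
            )
        for comp, v in zip(self.components, state.levels):
            if not 0 <= v <= comp.max_level:
                raise ValidationError(
                    f"level {v} out of range [0,{comp.max_level}] for {comp.name!r}"
                )

    def as_dict(self, state: CellState) -> dict[str, int]:
        return dict(zip(self.names, state.levels))

    def all_states(self) -> Iterator[CellState]:
        """Enumerate every state of the model (use on small models only)."""
        ranges = [range(c.max_level + 1) for c in self.components]
        for combo in itertools.product(*ranges):
            yield CellState(combo)

    # -- validation --------------------------------------------------------

    def _validate(self) -> None:
        if len(self._index) != len(self.components):
            raise ValidationError("duplicate component names")
        internal = {c.name for c in self.internals}
        have = set(self.functions)
        if have != internal:
            missing = internal - have
            extra = have - internal
            msg = []
            if missing:
                msg.append(f"internal components without function: {sorted(missing)}")
            if extra:
                msg.append(f"functions for non-internal components: {sorted(extra)}")
            raise ValidationError("; ".join(msg))
        for fn in self.functions.values():
            owner = self.component(fn.owner)
            for lv, ex in fn.terms:
                if lv > owner.max_level:
                    raise ValidationError(
                        f"function for {fn.owner!r}: level {lv} exceeds "
                        f"max_level {owner.max_level}"
                    )
                for atom in ex.atoms():
                    if atom.component not in self._index:
                        raise ValidationError(
                            f"function for {fn.owner!r}: atom references unknown "
                            f"component {atom.component!r}"
                        )
                    cmax = self.component(atom.component).max_level
                    if not 0 <= atom.level <= cmax + 1:
                        raise ValidationError(
                            f"function for {fn.owner!r}: atom level {atom.level} out "
                            f"of range for {atom.component!r} (max {cmax})"
                        )
        if self.priorities is not None:
            for c in self.internals:
                for d in ("increase", "decrease"):
                    n = self.priorities.covered_directions(c.name).count(d)
                    if n != 1:
                        raise ValidationError(
                            f"priority classes must cover {d} of {c.name!r} exactly "
                            f"once (found {n})"
                        )


# ---------------------------------------------------------------------------
# Single-cell update operations
# ---------------------------------------------------------------------------


def target_level(model: LogicalModel, component: str, state: CellState) -> int:
    """Target level of an internal ``component`` given the full cell state."""
    comp = model.component(component)
    if comp.is_input:
        raise ValidationError(
            f"{component!r} is an input component and has no regulatory function"
        )
    return model.functions[component].target(model.as_dict(state))


def step_component(current: int, target: int) -> int:
    """Move one level toward the target (stepwise multi-valued convention)."""
    if target > current:
        return current + 1
    if target < current:
        return current - 1
    return current


def _pending(model: LogicalModel, state: CellState) -> dict[str, int]:
    """Map internal component -> sign of its pending step (nonzero only)."""
    assignment = model.as_dict(state)
    out = {}
    for comp in model.internals:
        cur = state.levels[model.index(comp.name)]
        tgt = model.functions[comp.name].target(assignment)
        if tgt != cur:
            out[comp.name] = 1 if tgt > cur else -1
    return out


def update_cell(model: LogicalModel, state: CellState) -> CellState:
    """One synchronous update of the cell's internal components.

    All targets are computed from the argument state. Without priorities every
    internal component steps toward its target simultaneously. With priorities
    only the highest-priority class containing at least one applicable pending
    update fires; its applicable members step, everything else stays. Inputs
    are never modified.
    """
    pending = _pending(model, state)
    if not pending:
        return state
    if model.priorities is None:
        to_step = set(pending)
    else:
        to_step = set()
        for members in model.priorities.classes:
            for name, direction in members:
                sign = pending.get(name)
                if sign is None:
                    continue
                if (
                    direction == "both"
                    or (direction == "increase" and sign > 0)
                    or (direction == "decrease" and sign < 0)
                ):
                    to_step.add(name)
            if to_step:
                break
        if not to_step:
            return state
    levels = list(state.levels)
    for name in to_step:
        i = model.index(name)
        levels[i] = levels[i] + pending[name]
    return CellState(levels)


def is_cell_stable(model: LogicalModel, state: CellState) -> bool:
    """True iff every internal component already sits at its target level."""
    return not _pending(model, state)
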
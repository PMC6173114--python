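"""Vectorised whole-grid evaluation engine.

Internal module. The engine flattens the grid row-major and keeps one integer
vector per component. Neighbourhood bands are precomputed as padded index
matrices (one row per cell, entries are flat indices of the cells in the
band, with a validity mask), cached per (topology, dmin, dmax) so repeated
runs over the same lattice pay the breadth-first search only once.

Regulatory functions are evaluated through the same expression objects as the
scalar single-cell path (:mod:`hexlogic.logic_core`), just over arrays, so
both paths share one semantics.
"""

from __future__ import annotations

import numpy as np

from .epithelium import (
    LEVEL_DTYPE,
    CardAtom,
    EpitheliumModel,
    GridState,
)
from .errors import ValidationError
from .hexgrid import GridTopology
from .logic_core import And, BoolConst, Expr, Not, Or

_BAND_CACHE: dict[tuple, tuple[np.ndarray, np.ndarray]] = {}


def neighbor_band(topo: GridTopology, dmin: int, dmax: int):
    """(idx, valid): per-cell flat indices of the distance band, padded."""
    key = (topo, dmin, dmax)
    hit = _BAND_CACHE.get(key)
    if hit is not None:
        return hit
    n = topo.n_cells
    bands = []
    for cell in topo.cells():
        members = topo.cells_at_distance(cell, dmin, dmax)
        members.discard(cell)
        bands.append(sorted(topo.flat_index(x) for x in members))
    width = max((len(b) for b in bands), default=0)
    idx = np.zeros((n, max(width, 1)), dtype=np.int32)
    valid = np.zeros((n, max(width, 1)), dtype=bool)
    for i, b in enumerate(bands):
        idx[i, : len(b)] = b
        valid[i, : len(b)] = True
    _BAND_CACHE[key] = (idx, valid)
    return idx, valid


def _eval_vec(expr: Expr, atom_fn):
    if isinstance(expr, CardAtom):
        return atom_fn(expr)
    if isinstance(expr, BoolConst):
        return expr.value
    if isinstance(expr, Not):
        return np.logical_not(_eval_vec(expr.child, atom_fn))
    if isinstance(expr, And):
        out = True
        for c in expr.children:
            out = np.logical_and(out, _eval_vec(c, atom_fn))
        return out
    if isinstance(expr, Or):
        out = False
        for c in expr.children:
            out = np.logical_or(out, _eval_vec(c, atom_fn))
        return out
    raise ValidationError(f"unexpected node {type(expr).__name__} in integration rule")


class Engine:
    """Precomputed evaluation context for one epithelium model."""

    def __init__(self, epi: EpitheliumModel):
        self.epi = epi
        topo = epi.topology
        self.topo = topo
        self.n = topo.n_cells
        self.shape = (topo.height, topo.width)

        # cell -> model group
        names_per_cell = [epi.model_name_of(c) for c in topo.cells()]
        self.groups: list[tuple] = []  # (model, flat index array, bool mask)
        for mname in epi.models:
            gidx = np.array(
                [i for i, nm in enumerate(names_per_cell) if nm == mname],
                dtype=np.int64,
            )
            if gidx.size:
                self.groups.append((epi.models[mname], gidx))

        # component presence and role maps over the flat grid
        self.all_names = epi.all_component_names
        self.presence: dict[str, np.ndarray] = {
            name: np.zeros(self.n, dtype=bool) for name in self.all_names
        }
        self.input_presence: dict[str, np.ndarray] = {}
        for model, gidx in self.groups:
            for c in model.components:
                self.presence[c.name][gidx] = True
                if c.is_input:
                    self.input_presence.setdefault(
                        c.name, np.zeros(self.n, dtype=bool)
                    )[gidx] = True

        self.positional_arrays = {
            name: pmap.as_array(topo).reshape(-1)
            for name, pmap in epi.positional.items()
        }

        # perturbation clamps, split by the perturbed component's role
        self.input_clamps: list[tuple[str, int, np.ndarray]] = []
        self.internal_clamps: list[tuple[str, int, np.ndarray]] = []
        for p in epi.perturbations:
            comp = epi.component_any(p.component)
            if comp is None:
                continue
            mask = p.mask(topo).reshape(-1) & self.presence[p.component]
            entry = (p.component, p.fixed_level, mask)
            (self.input_clamps if comp.is_input else self.internal_clamps).append(entry)

        # bands needed by the integration rules
        for by_level in epi.integration.values():
            for rule in by_level.values():
                for atom in rule.expression.atoms():
                    if isinstance(atom, CardAtom):
                        neighbor_band(topo, atom.dmin, atom.dmax)

    # -- flat views --------------------------------------------------------

    def _flat(self, state: GridState) -> dict[str, np.ndarray]:
        return {name: arr.reshape(-1) for name, arr in state.levels.items()}

    # -- input resolution ---------------------------------------------------

    def resolve(self, state: GridState) -> GridState:
        """Inputs set from the argument state's internals; internals untouched."""
        out = state.copy()
        flat_in = self._flat(state)
        flat_out = self._flat(out)

        for name, arr in self.positional_arrays.items():
            pres = self.input_presence.get(name)
            if pres is None:
                continue
            flat_out[name][pres] = arr[pres]

        for name, by_level in self.epi.integration.items():
            pres = self.input_presence.get(name)
            if pres is None:
                continue
            value = np.zeros(self.n, dtype=np.int64)

            def atom_fn(atom: CardAtom):
                idx, valid = neighbor_band(self.topo, atom.dmin, atom.dmax)
                comp_flat = flat_in.get(atom.component)
                if comp_flat is None:
                    return np.zeros(self.n, dtype=bool)
                sat = (
                    valid
                    & self.presence[atom.component][idx]
                    & (comp_flat[idx] >= atom.value)
                )
                count = sat.sum(axis=1)
                if atom.quantifier == "atleast":
                    return count >= atom.k
                band_n = valid.sum(axis=1)
                return (band_n > 0) & (count == band_n)

            for level in sorted(by_level):
                holds = _eval_vec(by_level[level].expression, atom_fn)
                value = np.where(holds, level, value)
            flat_out[name][pres] = value[pres].astype(LEVEL_DTYPE)

        for name, lv, mask in self.input_clamps:
            flat_out[name][mask] = lv
        return out

    # -- internal dynamics ---------------------------------------------------

    def clamp_internals(self, state: GridState) -> GridState:
        out = state.copy()
        flat = self._flat(out)
        for name, lv, mask in self.internal_clamps:
            flat[name][mask] = lv
        return out

    def deltas(self, resolved: GridState) -> dict[str, np.ndarray]:
        """Pending stepwise move (-1/0/+1) of every internal component, per cell.

        Priority classes are honoured per cell; perturbation-clamped entries
        are forced to 0 (a clamped component never moves).
        """
        flat = self._flat(resolved)
        out: dict[str, np.ndarray] = {}
        for model, gidx in self.groups:
            assignment = {n: flat[n][gidx].astype(np.int64) for n in model.names}
            signs = {}
            for comp in model.internals:
                tgt = model.functions[comp.name].target(assignment)
                tgt = np.asarray(tgt, dtype=np.int64)
                if tgt.ndim == 0:
                    tgt = np.full(gidx.shape, int(tgt))
                signs[comp.name] = np.sign(tgt - assignment[comp.name])
            if model.priorities is not None:
                signs = self._apply_priorities(model, signs, gidx.size)
            for name, sg in signs.items():
                full = out.setdefault(name, np.zeros(self.n, dtype=np.int64))
                full[gidx] = sg
        for name, lv, mask in self.internal_clamps:
            if name in out:
                out[name][mask] = 0
        return out

    @staticmethod
    def _apply_priorities(model, signs, size):
        fired = np.zeros(size, dtype=bool)
        result = {name: np.zeros(size, dtype=np.int64) for name in signs}
        for members in model.priorities.classes:
            applicable: dict[str, np.ndarray] = {}
            for name, direction in members:
                sg = signs.get(name)
                if sg is None:
                    continue
                if direction == "increase":
                    m = sg > 0
                elif direction == "decrease":
                    m = sg < 0
                else:
                    m = sg != 0
                applicable[name] = applicable.get(name, False) | m
            if not applicable:
                continue
            class_pending = np.zeros(size, dtype=bool)
            for m in applicable.values():
                class_pending |= m
            fire_here = class_pending & ~fired
            for name, m in applicable.items():
                sel = fire_here & m
                result[name][sel] = signs[name][sel]
            fired |= class_pending
        return result

    def analyze(self, state: GridState):
        """(resolved-and-clamped state, deltas, stable?)."""
        cur = self.clamp_internals(state)
        resolved = self.resolve(cur)
        dl = self.deltas(resolved)
        stable = all(not d.any() for d in dl.values())
        return resolved, dl, stable

    def advance(
        self,
        resolved: GridState,
        deltas: dict[str, np.ndarray],
        selected: np.ndarray | None = None,
    ) -> GridState:
        """Apply the pending steps of the selected cells (None = all cells)."""
        out = resolved.copy()
        flat = self._flat(out)
        for name, d in deltas.items():
            if selected is not None:
                d = np.where(selected, d, 0)
            flat[name][:] = (flat[name].astype(np.int64) + d).astype(LEVEL_DTYPE)
        return out
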
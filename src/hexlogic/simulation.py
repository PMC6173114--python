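"""Tissue dynamics: synchronous and α-asynchronous updating.

At every tissue step the inputs of all cells are first resolved from the
current grid state (two-phase contract), then cells update their internal
components. Under the synchronous scheme every cell updates; under
α-asynchronism a uniformly drawn subset of exactly ``round(α·N)`` cells
updates while the rest hold their internal levels (α = 1 reproduces the
synchronous scheme exactly). A *stable pattern* — a fixed point of the full
synchronous update — is absorbing under every scheme, so stochastic runs
declare convergence when the current state passes :func:`is_stable`, never by
watching for repeated states.

Cycle detection (via hashed state history) applies only to the deterministic
synchronous scheme, where a revisited state proves a cyclic attractor.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from ._engine import Engine
from .epithelium import EpitheliumModel, GridState
from .errors import ConfigError, ValidationError

__all__ = [
    "SimulationConfig",
    "Trajectory",
    "is_stable",
    "step_synchronous",
    "step_alpha_async",
    "run",
    "clone_epithelium",
]

SYNCHRONOUS = "synchronous"
ALPHA_ASYNC = "alpha_async"


@dataclass(frozen=True)
class SimulationConfig:
    """Updating scheme and its parameters.

    ``alpha`` is the proportion of cells drawn (uniformly, without
    replacement) for update at each step; ``bernoulli=True`` switches to the
    per-cell independent-coin variant of α-asynchronism. ``seed`` feeds the
    random stream of stochastic schemes and is ignored by the synchronous
    scheme.
    """

    scheme: str = SYNCHRONOUS
    alpha: float = 1.0
    seed: int = 0
    max_steps: int = 1000
    bernoulli: bool = False

    def __post_init__(self):
        if self.scheme not in (SYNCHRONOUS, ALPHA_ASYNC):
            raise ConfigError(f"unknown scheme {self.scheme!r}")
        if not 0 < self.alpha <= 1:
            raise ConfigError(f"alpha must be in (0,1], got {self.alpha}")
        if self.max_steps < 1:
            raise ConfigError("max_steps must be >= 1")


@dataclass
class Trajectory:
    """States visited by one run, plus how the run ended.

    ``states[0]`` is the initial state after perturbation clamping (with its
    inputs resolved); each later entry is the state after one tissue update.
    ``steps_to_stability`` counts applied tissue updates, so a stable initial
    state converges in 0 steps. ``cycle_length`` is set only when the
    synchronous scheme revisited a state.
    """

    epi: EpitheliumModel
    config: SimulationConfig
    states: list[GridState] = field(default_factory=list)
    converged: bool = False
    steps_to_stability: int | None = None
    cycle_length: int | None = None
    changed_per_step: list[int] = field(default_factory=list)

    @property
    def final(self) -> GridState:
        return self.states[-1]

    def to_csv(self, path_or_file) -> None:
        """One row per (step, col, row, component, level); rows ordered by
        step, then row-major cell, then the cell model's declaration order."""
        own = isinstance(path_or_file, (str, bytes)) or hasattr(path_or_file, "__fspath__")
        fh = open(path_or_file, "w", newline="", encoding="utf-8") if own else path_or_file
        try:
            w = csv.writer(fh, lineterminator="\n")
            w.writerow(["step", "col", "row", "component", "level"])
            for step, state in enumerate(self.states):
                for cell in self.epi.topology.cells():
                    model = self.epi.model_of(cell)
                    for name in model.names:
                        w.writerow([step, cell.col, cell.row, name, state.level(name, cell)])
        finally:
            if own:
                fh.close()

    def to_csv_text(self) -> str:
        buf = io.StringIO()
        self.to_csv(buf)
        return buf.getvalue()


# ---------------------------------------------------------------------------
# Step operators
# ---------------------------------------------------------------------------


def is_stable(epi: EpitheliumModel, state: GridState) -> bool:
    """True iff the state (after input resolution and perturbation clamping)
    is a fixed point of the full synchronous update — a *stable pattern*,
    absorbing under every updating scheme."""
    _, _, stable = Engine(epi).analyze(state)
    return stable


def step_synchronous(epi: EpitheliumModel, state: GridState) -> GridState:
    """One deterministic tissue update of every cell."""
    eng = Engine(epi)
    resolved, deltas, _ = eng.analyze(state)
    return eng.advance(resolved, deltas, None)


def _selection(n: int, alpha: float, rng: np.random.Generator, bernoulli: bool) -> np.ndarray:
    if bernoulli:
        return rng.random(n) < alpha
    k = int(round(alpha * n))
    mask = np.zeros(n, dtype=bool)
    if k:
        mask[rng.choice(n, size=k, replace=False)] = True
    return mask


def step_alpha_async(
    epi: EpitheliumModel,
    state: GridState,
    alpha: float,
    rng: np.random.Generator,
    bernoulli: bool = False,
) -> GridState:
    """One α-asynchronous tissue update: exactly ``round(α·N)`` cells, drawn
    uniformly without replacement from ``rng``, apply their pending update."""
    if not 0 < alpha <= 1:
        raise ConfigError(f"alpha must be in (0,1], got {alpha}")
    eng = Engine(epi)
    resolved, deltas, _ = eng.analyze(state)
    selected = _selection(eng.n, alpha, rng, bernoulli)
    return eng.advance(resolved, deltas, selected)


# ---------------------------------------------------------------------------
# Full runs
# ---------------------------------------------------------------------------


def run(
    epi: EpitheliumModel,
    config: SimulationConfig,
    keep_states: bool = True,
    progress: Callable[[int, int], None] | None = None,
) -> Trajectory:
    """Iterate the configured step operator from ``epi.initial``.

    Stops at the first stable state (``converged=True``), at a revisited
    state under the synchronous scheme (``cycle_length`` set), or after
    ``max_steps`` updates. Identical (epithelium, config) give identical
    trajectories. With ``keep_states=False`` only the last state is retained.
    """
    findings = epi.validate()
    if findings:
        raise ValidationError(
            "epithelium model is invalid:\n  - " + "\n  - ".join(findings)
        )
    eng = Engine(epi)
    rng = np.random.default_rng(config.seed)
    internal_names = sorted(
        {c.name for m in epi.models.values() for c in m.internals}
    )
    traj = Trajectory(epi=epi, config=config)
    seen: dict[bytes, int] = {}
    cur = epi.initial

    for t in range(config.max_steps + 1):
        resolved, deltas, stable = eng.analyze(cur)
        if keep_states:
            traj.states.append(resolved)
        else:
            traj.states = [resolved]
        if stable:
            traj.converged = True
            traj.steps_to_stability = t
            break
        if config.scheme == SYNCHRONOUS:
            dg = resolved.digest(internal_names)
            prev = seen.get(dg)
            if prev is not None:
                traj.cycle_length = t - prev
                break
            seen[dg] = t
        if t == config.max_steps:
            break
        if config.scheme == SYNCHRONOUS:
            selected = None
        else:
            selected = _selection(eng.n, config.alpha, rng, config.bernoulli)
        nxt = eng.advance(resolved, deltas, selected)
        if progress is not None:
            progress(t, config.max_steps)
        n_changed = sum(
            int((nxt.levels[n] != resolved.levels[n]).sum()) for n in internal_names
            if n in nxt.levels
        )
        traj.changed_per_step.append(n_changed)
        cur = nxt

    return traj


def clone_epithelium(epi: EpitheliumModel, state: GridState) -> EpitheliumModel:
    """Deep copy of the epithelium taking ``state`` as its initial condition.

    The clone shares nothing with the original: editing its positional maps,
    rules or perturbations (e.g. removing a morphogen for a second simulation
    phase) leaves the original untouched.
    """
    clone = epi.copy()
    clone.initial = state.copy()
    return clone
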
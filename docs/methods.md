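# Methods

## The model

`hexlogic` simulates a mono-layer epithelium as a cellular automaton over a
2D hexagonal lattice. Each cell carries a *logical regulatory model*: a set
of components, each with a discrete level in `{0..max_level}` (Boolean when
`max_level = 1`). Components split into

- **internal components**, each with a regulatory function: an ordered list
  of `(level, expression)` pairs over threshold atoms
  (`component >= v`, `== v`, `< v`) combined with AND/OR/NOT. The target of
  the component is the highest level whose expression holds, else 0.
- **input components**, which carry no function inside the cell. Their
  values are imposed by the tissue: *positional* inputs from a fixed
  per-cell map, *integration* inputs from logical rules over the
  neighbourhood.

A cell update computes all internal targets from the current (input-resolved)
cell state and steps every off-target component **one level** toward its
target, simultaneously. The stepwise (±1) convention is the classical
multi-valued logical one; for Boolean components it coincides with jumping
to the target. With **priority classes** the (component, direction) pairs
are partitioned into ordered classes; a cell update fires only the
highest-priority class containing at least one applicable pending update and
steps exactly its applicable members. One class fires per cell update; we
chose this single-class firing over "all classes with pending updates fire"
because it is the strictest reading of ordered time scales, and it reduces
to the plain synchronous update when all updates share one class (property-
tested).

## Tissue geometry

Cells are addressed in 0-based odd-r offset coordinates (pointy-top
hexagons, odd rows shifted right). The choice of offset convention is
purely representational: any consistent one yields isomorphic dynamics.
Borders can be wrapped pairwise (rectangle / cylinder / torus). Vertical
wrapping requires an even row count, since joining an odd row to row 0 would
break the row-parity consistency of odd-r adjacency; this is rejected at
construction. Distances are defined operationally as shortest paths in the
wrapped adjacency graph and computed by breadth-first search — closed-form
offset-with-wrap formulas are error-prone and buy nothing at these sizes.
Per-(topology, band) neighbourhood index tables are cached process-wide.

## Integration rules

An integration rule gives one level of one input component as a logical
expression over neighbourhood-count atoms
`NAME >= v [dmin:dmax] (atleast k | all)`: at least `k` (or all) cells in
the distance band `[dmin, dmax]` have the named internal component at or
above `v`. Conventions:

- multi-level inputs take the **highest satisfied rule level**, else 0;
- `all` over an empty band is false — a border cell with no neighbours
  receives no signal;
- in heterogeneous tissues, a neighbour whose model lacks the tested
  component never satisfies the atom;
- rules may only reference internal components (signals are emitted
  molecules, not the receiving cell's receptors); this is a validation
  finding otherwise.

The concrete grammar is our own (the precedence-standard `| & ! ()` over the
atoms above); it is parsed by a small recursive-descent parser with
positioned error messages.

## Tissue update and schemes

Updates are **two-phase**: all inputs for step *t* are resolved from the
full grid state at step *t* (positional maps, then integration rules),
before any internal update. This makes the synchronous tissue update
independent of cell iteration order and lets the engine vectorise freely.

- **Synchronous** (default): every cell applies one cell update.
  Deterministic; cycles are detected by hashing the internal-state history,
  and a revisited state reports the cycle length.
- **α-asynchronous**: exactly `round(α·N)` cells, drawn uniformly without
  replacement, update; the rest hold their internal levels. We read the
  scheme's parameter as an exact proportion of cells; the per-cell
  independent Bernoulli(α) variant is available behind the `bernoulli`
  config flag but is not the default. `α = 1` reproduces the synchronous
  operator exactly (asserted bitwise on randomized instances).

**Stability.** A *stable pattern* is a fixed point of the full synchronous
update; it is absorbing under every scheme and any α. Stochastic runs
declare convergence when the current state passes this test — a sound
absorbing criterion — never by observing `k` identical consecutive states.
Step counts report applied tissue updates, with the initial state (after
perturbation clamping) as step 0.

**Perturbations** clamp a component to a fixed level over a region (or the
whole grid) and are re-applied after input resolution and after every
update, so clamped components never move; stability ignores their pending
updates. Overlapping regions for the same component are a validation
finding rather than being silently ordered.

**Clones** deep-copy the epithelium with the current grid state as the new
initial condition, for multi-phase protocols (e.g. run to a stable pattern,
clone, zero a positional input, continue).

## The engine

The grid state is one small-integer array per component name. Regulatory
expressions are evaluated over whole-grid arrays through the *same*
expression objects as the scalar single-cell path, so the two paths cannot
diverge semantically (and their agreement is property-tested anyway).
Integration atoms gather neighbour levels through the cached band index
tables and reduce with counting. Runs over a 50×50 grid cost roughly a
millisecond per step.

## The Delta–Notch fixture

The built-in lateral-inhibition cell has exactly two components: Green, the
integration input (the Notch-side readout induced by neighbouring Red), and
internal Red with `Red = NOT Green`. We deliberately model Green as the
input itself rather than inserting a third relay species (neighbour-signal
input → internal Green → internal Red): the two-marker form is the
idealised model as described, and the extra relay would add one tissue step
of latency per signalling hop, inflating convergence times several-fold and
changing the two-cell attractor structure. Consequences worth knowing:

- the two-cell synchronous system has a cyclic attractor of length 2
  (all-zero → both-Red → all-zero on the internal state), and its only
  stable states are the two polarized ones;
- with the contact rule, a tissue state is stable **iff** Green = "has a
  Red contact" cell-wise, Red = NOT Green, and the Red set is a maximal
  independent set of the contact graph. The test suite checks both
  directions.

Default study conditions (used by the acceptance script and the deep tests):
50×50 grid, all-zero initial state, α = 0.25, the three rule variants
`contact_atleast1`, `contact_all`, `dist3_atleast12`, rectangle or torus.

## What the synthetic conditions do and do not show

The fixture exercises juxtacrine signalling, distance-banded signalling,
border effects and updating noise, which is what the engine is for. It does
not emulate cell movement, division, death, or graded diffusible ligands
(positional maps are static by design); conclusions about real epithelia
require a cellular model calibrated for the tissue at hand, imported via
SBML qual.

## Numerical and formatting choices

- Levels are stored as 8-bit integers (logical models in practice use a
  handful of levels); targets are computed in 64-bit.
- `round(α·N)` uses Python's banker's rounding; with α·N integral (the
  documented settings) no tie ever arises. If `round(α·N) = 0` the step
  updates nothing — choose α ≥ 1/(2N) for progress.
- Trajectory CSV rows are ordered by step, then row-major cell, then the
  cell model's declaration order; files are UTF-8 with `\n` terminators,
  so identical runs are byte-identical across processes.
- Project YAML is emitted with sorted keys and inline SBML, making saves
  deterministic; the SBML writer normalises expressions (single-child
  conjunctions collapse), so round-trips are identity on normalised models.
- The default `max_steps` is 1000; the acceptance script uses 5000 to keep
  the convergence-time distribution uncensored. 100 seeded runs per setting
  balance range coverage against runtime (~15 s total for all four).
- Random streams are numpy `default_rng` generators; a run's trajectory is
  fully determined by (epithelium, config), including across processes.

## Known limitations

- No attractor enumeration of the composed tissue system (state spaces are
  astronomically large; simulation from chosen initial conditions is the
  method).
- SBML qual support covers the relational/logical MathML subset qual models
  use; arithmetic inside transition math is rejected with a clear error.
- Priority classes are per-cell; there is no tissue-level priority notion.
- One transition per output species; multi-transition models must be
  pre-merged.
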
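# hexlogic

Logical (Boolean and multi-valued) regulatory models on hexagonal cell
grids: a tissue-level cellular automaton for studying epithelial pattern
formation.

Qualitative "logical" models are the workhorse of regulatory-network
modelling: each component takes a discrete level in `{0..max}`, and logical
rules over the regulators' levels drive its evolution. `hexlogic` lifts this
single-cell formalism to a mono-layer epithelium. A 2D hexagonal lattice
(rectangle, cylinder or torus) carries one logical model per cell, and cells
communicate through their *input* components:

- **positional inputs** are held at fixed per-cell levels — a morphogen
  gradient painted over the grid;
- **integration inputs** are recomputed every step by logical *integration
  rules* over the neighbourhood, e.g. `Red>=1 [1:3] atleast 12`
  ("at least 12 cells at distance up to 3 have Red ≥ 1").

The tissue evolves under a **synchronous** update (every cell updates, each
stepping its internal components one level toward the targets given by its
rules) or under **α-asynchronism**: at each step a uniformly drawn subset of
exactly `round(α·N)` cells updates while the rest hold their state. A
*stable pattern* — a fixed point of the full synchronous update — is
absorbing under every scheme. Priority classes, region-restricted
perturbation clamps (knock-outs, ectopic expression), model clones for
multi-phase simulations, and SBML Level 3 `qual` import/export are all
supported.

Who is it for: modellers who have a cellular logical model (drawn in any
SBML-qual-capable editor) and want to ask tissue-scale questions — which
patterns are stable, how updating noise selects among them, what a clone or
a knock-out does to the pattern.

## The core example: Delta–Notch lateral inhibition

The built-in fixture is the idealised two-marker lateral-inhibition cell:
Green (the Notch-activity readout) is the cell's integration input, induced
when neighbouring cells present Red; Red (Delta) is the single internal
component with rule

    Red = NOT Green

On a grid with the contact rule `Red>=1 [1:1] atleast 1`, the stable
patterns are exactly the salt-and-pepper configurations whose Red cells form
a **maximal independent set** of the contact graph: no two Red cells touch,
and every non-Red cell touches a Red one. The fully synchronous tissue never
finds them (it oscillates); α-asynchronism with α = 0.25 converges reliably.

## Worked example

```python
from hexlogic import SimulationConfig, fixture_delta_notch, run

epi, config = fixture_delta_notch(50, 50, wrap="none",
                                  rule_variant="contact_atleast1",
                                  alpha=0.25, seed=1)
traj = run(epi, config)
print("converged:", traj.converged)
print("steps to stability:", traj.steps_to_stability)
red = int(traj.final.levels["Red"].sum())
print("Red cells in the stable pattern:", red)
```

prints

```
converged: True
steps to stability: 21
Red cells in the stable pattern: 591
```

i.e. this seed reaches a stable salt-and-pepper pattern after 21 tissue
updates, with 591 of the 2500 cells adopting the Red fate (the size of the
maximal independent set this run selected). Different seeds give different
stable patterns and step counts; the same seed always reproduces the same
trajectory, bit for bit.

The same run from the shell, using the shipped project file:

```
hexlogic simulate examples/delta_notch_50x50.yaml --out traj.csv
hexlogic render traj.csv --step 21 --component Red -o pattern.png
```

`hexlogic fixture delta-notch --help` writes the other printed variants
(`contactall`, `dist3-12`, torus wrapping); `hexlogic validate` checks a
project file and lists findings.

## Package layout

| module | contents |
| --- | --- |
| `hexlogic.logic_core` | components, logical functions, priority classes, single-cell update |
| `hexlogic.sbml_qual` | SBML Level 3 `qual` reader/writer |
| `hexlogic.hexgrid` | odd-r offset hexagonal lattice, wrapping, distance bands |
| `hexlogic.epithelium` | epithelium model, integration-rule grammar, positional inputs, perturbations |
| `hexlogic.simulation` | synchronous / α-asynchronous runs, stability and cycle detection, clones |
| `hexlogic.project` | YAML project dialect (load/save) |
| `hexlogic.cli`, `hexlogic.render` | command line and PNG rendering |

See `docs/methods.md` for the model semantics, parameter meanings and
numerical conventions.
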
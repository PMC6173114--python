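"""Tissue dynamics: stability, step operators, runs, clones.

The two-cell lateral-inhibition system is small enough for an exhaustive
independent oracle: its full state space (Green, Red per cell, 16 joint
configurations) is enumerated by hand below and compared state-for-state
with the engine.
"""

import itertools

import numpy as np
import pytest

from hexlogic import (
    ALPHA_ASYNC,
    SYNCHRONOUS,
    CellCoord,
    ConfigError,
    Component,
    EpitheliumModel,
    GridState,
    GridTopology,
    LogicalFunction,
    LogicalModel,
    PositionalInput,
    SimulationConfig,
    ValidationError,
    clone_epithelium,
    fixture_delta_notch,
    is_stable,
    run,
    step_alpha_async,
    step_synchronous,
)
from hexlogic.epithelium import parse_integration_rule
from hexlogic.logic_core import Atom


# ---------------------------------------------------------------------------
# Independent oracle for the two-cell system (1x2 grid, contact rule):
# state = (G_a, R_a, G_b, R_b). Inputs resolve as G_i = [R_other >= 1];
# the single internal component updates as R_i' = NOT G_i (resolved).
# ---------------------------------------------------------------------------


def oracle_resolve(s):
    ga, ra, gb, rb = s
    return (int(rb >= 1), ra, int(ra >= 1), rb)


def oracle_step(s):
    """Two-phase synchronous tissue update on the full 4-tuple."""
    ga, ra, gb, rb = oracle_resolve(s)
    return (ga, 1 - ga, gb, 1 - gb)


def oracle_stable(s):
    ga, ra, gb, rb = oracle_resolve(s)
    return ra == 1 - ga and rb == 1 - gb


ALL_16 = list(itertools.product((0, 1), repeat=4))


def two_cell_state(epi, s):
    ga, ra, gb, rb = s
    st = epi.zero_state()
    st.levels["Green"][:, 0] = [ga, gb]
    st.levels["Red"][:, 0] = [ra, rb]
    return st


def as_tuple(st):
    return (
        int(st.levels["Green"][0, 0]),
        int(st.levels["Red"][0, 0]),
        int(st.levels["Green"][1, 0]),
        int(st.levels["Red"][1, 0]),
    )


class TestTwoCellOracle:
    def test_engine_step_agrees_on_all_16_states(self):
        epi, _ = fixture_delta_notch(1, 2)
        for s in ALL_16:
            got = as_tuple(step_synchronous(epi, two_cell_state(epi, s)))
            assert got == oracle_step(s), s

    def test_stability_agrees_and_only_polarized_states_are_stable(self):
        epi, _ = fixture_delta_notch(1, 2)
        stable = set()
        for s in ALL_16:
            engine_says = is_stable(epi, two_cell_state(epi, s))
            assert engine_says == oracle_stable(s), s
            if engine_says:
                stable.add((s[1], s[3]))  # internal (R_a, R_b) pattern
        assert stable == {(0, 1), (1, 0)}  # the two polarized patterns

    def test_synchronous_run_from_zero_finds_cyclic_attractor(self):
        epi, _ = fixture_delta_notch(1, 2)
        traj = run(epi, SimulationConfig(scheme=SYNCHRONOUS, max_steps=50))
        assert not traj.converged
        assert traj.cycle_length == 2
        # trajectory agrees with iterating the oracle (inputs re-resolved on record)
        s = oracle_resolve((0, 0, 0, 0))
        for state in traj.states:
            assert as_tuple(state) == s
            s = oracle_resolve(oracle_step(s))

    def test_synchronous_run_from_stable_state_converges_in_zero_steps(self):
        epi, _ = fixture_delta_notch(1, 2)
        epi.initial = two_cell_state(epi, (1, 0, 0, 1))
        traj = run(epi, SimulationConfig(scheme=SYNCHRONOUS, max_steps=50))
        assert traj.converged and traj.steps_to_stability == 0


class TestStepOperators:
    def test_synchronous_50x50_oscillates(self):
        epi, _ = fixture_delta_notch(12, 12)
        traj = run(epi, SimulationConfig(scheme=SYNCHRONOUS, max_steps=200))
        assert not traj.converged

    def test_alpha_one_equals_synchronous(self):
        rng_state = np.random.default_rng(11)
        for variant in ["contact_atleast1", "contact_all", "dist3_atleast12"]:
            epi, _ = fixture_delta_notch(7, 6, rule_variant=variant)
            st = epi.zero_state()
            st.levels["Red"][:] = rng_state.integers(0, 2, (6, 7))
            st.levels["Green"][:] = rng_state.integers(0, 2, (6, 7))
            sync = step_synchronous(epi, st)
            asyn = step_alpha_async(epi, st, 1.0, np.random.default_rng(0))
            assert sync == asyn

    def test_alpha_selects_exact_count(self):
        epi, _ = fixture_delta_notch(10, 10)
        st = epi.zero_state()  # every cell has a pending Red update
        out = step_alpha_async(epi, st, 0.25, np.random.default_rng(5))
        changed = int((out.levels["Red"] != st.levels["Red"]).sum())
        assert changed == 25  # round(0.25 * 100)

    def test_alpha_out_of_range_rejected(self):
        epi, _ = fixture_delta_notch(3, 3)
        for alpha in (0.0, -0.1, 1.5):
            with pytest.raises(ConfigError):
                step_alpha_async(epi, epi.zero_state(), alpha, np.random.default_rng(0))

    def test_stable_pattern_absorbs_under_every_scheme(self):
        epi, _ = fixture_delta_notch(1, 2)
        stable = two_cell_state(epi, (0, 1, 1, 0))
        resolved = step_synchronous(epi, stable)
        assert as_tuple(resolved) == (0, 1, 1, 0)
        for seed in range(5):
            for alpha in (0.25, 0.5, 1.0):
                out = step_alpha_async(epi, stable, alpha, np.random.default_rng(seed))
                assert as_tuple(out) == (0, 1, 1, 0)


class TestRun:
    def test_seed_reproducibility_within_process(self):
        epi, cfg = fixture_delta_notch(10, 10)
        t1 = run(epi, cfg)
        t2 = run(epi, cfg)
        assert len(t1.states) == len(t2.states)
        for a, b in zip(t1.states, t2.states):
            assert a == b
        assert t1.steps_to_stability == t2.steps_to_stability

    def test_different_seeds_differ(self):
        epi, _ = fixture_delta_notch(10, 10)
        t1 = run(epi, SimulationConfig(ALPHA_ASYNC, 0.25, seed=1))
        t2 = run(epi, SimulationConfig(ALPHA_ASYNC, 0.25, seed=2))
        assert any(a != b for a, b in zip(t1.states, t2.states))

    def test_max_steps_cutoff(self):
        epi, _ = fixture_delta_notch(6, 6)
        traj = run(epi, SimulationConfig(ALPHA_ASYNC, 0.25, seed=0, max_steps=3))
        if not traj.converged:
            assert len(traj.states) == 4  # initial + 3 updates
        assert len(traj.changed_per_step) <= 3

    def test_invalid_model_refused(self):
        epi, cfg = fixture_delta_notch(4, 4)
        epi.integration.clear()
        with pytest.raises(ValidationError, match="invalid"):
            run(epi, cfg)

    def test_keep_states_false_retains_final_only(self):
        epi, cfg = fixture_delta_notch(8, 8)
        full = run(epi, cfg)
        slim = run(epi, cfg, keep_states=False)
        assert len(slim.states) == 1
        assert slim.final == full.final
        assert slim.steps_to_stability == full.steps_to_stability


def red_is_maximal_independent_set(epi, state):
    topo = epi.topology
    red = {c for c in topo.cells() if state.level("Red", c) >= 1}
    for c in topo.cells():
        nb_red = any(n in red for n in topo.neighbors(c))
        if c in red:
            if nb_red:
                return False  # two adjacent Red cells
            if state.level("Green", c) != 0:
                return False  # Red must pair with low Green
        else:
            if not nb_red:
                return False  # uncovered cell: set not maximal
            if state.level("Green", c) != 1:
                return False
    return True


class TestLateralInhibitionPattern:
    def test_final_patterns_are_maximal_independent_sets(self):
        epi, _ = fixture_delta_notch(8, 8)
        for seed in range(5):
            traj = run(epi, SimulationConfig(ALPHA_ASYNC, 0.25, seed=seed))
            assert traj.converged
            assert red_is_maximal_independent_set(epi, traj.final)

    def test_any_mis_configuration_is_stable(self):
        epi, _ = fixture_delta_notch(7, 7)
        topo = epi.topology
        # greedy maximal independent set, deterministic order
        red = set()
        for c in topo.cells():
            if not any(n in red for n in topo.neighbors(c)):
                red.add(c)
        st = epi.zero_state()
        for c in red:
            st.set_level("Red", c, 1)
        for c in topo.cells():
            st.set_level("Green", c, int(any(n in red for n in topo.neighbors(c))))
        assert is_stable(epi, st)

    def test_non_mis_configuration_is_unstable(self):
        epi, _ = fixture_delta_notch(5, 5)
        st = epi.zero_state()
        st.set_level("Red", CellCoord(1, 1), 1)
        st.set_level("Red", CellCoord(2, 1), 1)  # adjacent pair
        assert not is_stable(epi, st)


def single_cell_driver_epithelium():
    """1x1 grid, ternary positional input M pushing ternary X stepwise."""
    model = LogicalModel(
        [Component("M", max_level=2, is_input=True), Component("X", max_level=2)],
        [LogicalFunction("X", [(2, Atom("M", ">=", 2)), (1, Atom("M", ">=", 1))])],
    )
    return EpitheliumModel(
        GridTopology(1, 1),
        {"m": model},
        positional={"M": PositionalInput(2)},
    )


class TestClone:
    def test_clone_continues_deterministic_run(self):
        epi = single_cell_driver_epithelium()
        cfg = SimulationConfig(SYNCHRONOUS, max_steps=10)
        full = run(epi, cfg)
        assert full.converged and full.steps_to_stability == 2  # X: 0 -> 1 -> 2
        first = run(epi, SimulationConfig(SYNCHRONOUS, max_steps=1))
        clone = clone_epithelium(epi, first.final)
        rest = run(clone, cfg)
        resumed = first.states + rest.states[1:]
        assert len(resumed) == len(full.states)
        for a, b in zip(resumed, full.states):
            assert a == b

    def test_clone_is_deep_positional_edit_does_not_leak(self):
        epi = single_cell_driver_epithelium()
        traj = run(epi, SimulationConfig(SYNCHRONOUS, max_steps=10))
        clone = clone_epithelium(epi, traj.final)
        clone.positional["M"] = PositionalInput(0)  # remove the driving signal
        assert epi.positional["M"].default_level == 2
        back = run(clone, SimulationConfig(SYNCHRONOUS, max_steps=10))
        assert back.converged
        assert back.final.level("X", CellCoord(0, 0)) == 0

    def test_rule_swap_on_clone_changes_the_pattern(self):
        epi, _ = fixture_delta_notch(6, 6)
        traj = run(epi, SimulationConfig(ALPHA_ASYNC, 0.25, seed=3))
        assert traj.converged
        clone = clone_epithelium(epi, traj.final)
        clone.integration["Green"] = {
            1: parse_integration_rule("Red>=1 [1:1] all", "Green", 1)
        }
        again = run(clone, SimulationConfig(ALPHA_ASYNC, 0.25, seed=3))
        assert again.converged
        assert again.final != traj.final  # contact-all stabilises elsewhere
        assert epi.integration["Green"][1].expression.quantifier == "atleast"


class TestTrajectoryExport:
    def test_csv_schema_and_determinism(self):
        epi, _ = fixture_delta_notch(2, 2)
        traj = run(epi, SimulationConfig(ALPHA_ASYNC, 0.5, seed=4, max_steps=5))
        text = traj.to_csv_text()
        lines = text.strip().split("\n")
        assert lines[0] == "step,col,row,component,level"
        # row order: step, then row-major cell, then declaration order
        assert lines[1].startswith("0,0,0,Green,")
        assert lines[2].startswith("0,0,0,Red,")
        assert lines[3].startswith("0,1,0,Green,")
        n_cells, n_comps = 4, 2
        assert (len(lines) - 1) == len(traj.states) * n_cells * n_comps
        assert traj.to_csv_text() == text
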
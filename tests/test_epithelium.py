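"""Integration rules, input resolution, perturbations, model validation."""

import numpy as np
import pytest

from hexlogic import (
    And,
    CardAtom,
    CellCoord,
    Component,
    EpitheliumModel,
    GridState,
    GridTopology,
    IntegrationRule,
    LogicalFunction,
    LogicalModel,
    Not,
    Or,
    ParseError,
    Perturbation,
    PositionalInput,
    apply_perturbations,
    eval_integration_input,
    parse_integration_expression,
    parse_integration_rule,
    resolve_inputs,
    step_synchronous,
    validate,
)
from hexlogic.epithelium import rule_to_text
from hexlogic.fixtures import delta_notch_model, fixture_delta_notch
from hexlogic.logic_core import Atom


class TestRuleParser:
    @pytest.mark.parametrize(
        "text,expected",
        [
            ("Red>=1 [1:1] atleast 1", CardAtom("Red", 1, 1, 1, "atleast", 1)),
            ("Red>=1 [1:1] all", CardAtom("Red", 1, 1, 1, "all")),
            ("Red>=1 [1:3] atleast 12", CardAtom("Red", 1, 1, 3, "atleast", 12)),
            ("Dpp>=2 [2:4] atleast 3", CardAtom("Dpp", 2, 2, 4, "atleast", 3)),
        ],
    )
    def test_atoms(self, text, expected):
        assert parse_integration_expression(text) == expected

    def test_precedence_and_binds_tighter_than_or(self):
        e = parse_integration_expression(
            "A>=1 [1:1] all | B>=1 [1:1] atleast 2 & C>=1 [1:2] atleast 1"
        )
        assert isinstance(e, Or)
        assert isinstance(e.children[1], And)

    def test_negation_and_parentheses(self):
        e = parse_integration_expression(
            "!(A>=1 [1:1] atleast 1 | B>=1 [1:1] atleast 1)"
        )
        assert isinstance(e, Not)
        assert isinstance(e.child, Or)

    @pytest.mark.parametrize(
        "text,match",
        [
            ("Red>= [1:1] atleast 1", "expected"),
            ("Red>=1 [3:1] atleast 1", "inverted"),
            ("Red>=1 [0:1] atleast 1", "1 <= dmin <= dmax"),
            ("Red>=1 [1:1] atleast 0", "k >= 1"),
            ("Red>=1 [1:1] atleast 1 garbage", "trailing"),
            ("Red>=1 [1:1]", "atleast"),
            ("", "component name"),
            ("Red>=1 {1:1} all", "expected"),
        ],
    )
    def test_errors_carry_position(self, text, match):
        with pytest.raises(ParseError, match=match):
            parse_integration_expression(text)

    def test_text_round_trip(self):
        for text in [
            "Red>=1 [1:3] atleast 12",
            "!(A>=1 [1:1] all) & (B>=2 [2:3] atleast 4 | C>=1 [1:1] atleast 1)",
        ]:
            e = parse_integration_expression(text)
            assert parse_integration_expression(rule_to_text(e)) == e


class TestEvalIntegration:
    def test_contact_rule_counts_red_neighbors(self):
        epi, _ = fixture_delta_notch(5, 5)
        st = epi.zero_state()
        center = CellCoord(2, 2)
        nbs = sorted(epi.topology.neighbors(center))
        for nb in nbs[:2]:
            st.set_level("Red", nb, 1)
        assert eval_integration_input(epi, st, center, "Green") == 1

    def test_no_red_anywhere_gives_zero(self):
        epi, _ = fixture_delta_notch(5, 5)
        st = epi.zero_state()
        for cell in epi.topology.cells():
            assert eval_integration_input(epi, st, cell, "Green") == 0

    def test_all_rule_on_truncated_corner_band(self):
        epi, _ = fixture_delta_notch(5, 5, rule_variant="contact_all")
        st = epi.zero_state()
        corner = CellCoord(0, 0)
        band = epi.topology.neighbors(corner)
        for nb in band:
            st.set_level("Red", nb, 1)
        assert eval_integration_input(epi, st, corner, "Green") == 1
        st.set_level("Red", sorted(band)[0], 0)
        assert eval_integration_input(epi, st, corner, "Green") == 0

    def test_all_rule_empty_band_is_false(self):
        epi, _ = fixture_delta_notch(1, 1, rule_variant="contact_all")
        st = epi.zero_state()
        assert eval_integration_input(epi, st, CellCoord(0, 0), "Green") == 0

    def test_undeclared_input_rejected(self):
        epi, _ = fixture_delta_notch(3, 3)
        with pytest.raises(Exception, match="integration"):
            eval_integration_input(epi, epi.zero_state(), CellCoord(0, 0), "Red")


def graded_input_epithelium(width=4, height=3):
    """Single-cell model with a ternary positional input feeding internal X."""
    model = LogicalModel(
        [Component("M", max_level=2, is_input=True), Component("X", max_level=2)],
        [
            LogicalFunction(
                "X", [(2, Atom("M", ">=", 2)), (1, Atom("M", ">=", 1))]
            )
        ],
    )
    overrides = {}
    for row in range(height):
        for col in range(width):
            overrides[CellCoord(col, row)] = min(col, 2)
    return EpitheliumModel(
        GridTopology(width, height),
        {"m": model},
        positional={"M": PositionalInput(0, overrides)},
    )


class TestResolveInputs:
    def test_positional_gradient(self):
        epi = graded_input_epithelium()
        res = resolve_inputs(epi, epi.zero_state())
        for cell in epi.topology.cells():
            assert res.level("M", cell) == min(cell.col, 2)
            assert res.level("X", cell) == 0  # internals untouched

    def test_checkerboard_contact_rule(self):
        epi, _ = fixture_delta_notch(6, 6)
        st = epi.zero_state()
        for cell in epi.topology.cells():
            if (cell.col + cell.row) % 2 == 0:
                st.set_level("Red", cell, 1)
        res = resolve_inputs(epi, st)
        for cell in epi.topology.cells():
            has_red = any(
                st.level("Red", nb) >= 1 for nb in epi.topology.neighbors(cell)
            )
            assert res.level("Green", cell) == int(has_red)

    def test_idempotent_given_fixed_internals(self):
        epi, _ = fixture_delta_notch(6, 6)
        rng = np.random.default_rng(1)
        st = epi.zero_state()
        st.levels["Red"][:] = rng.integers(0, 2, (6, 6))
        once = resolve_inputs(epi, st)
        twice = resolve_inputs(epi, once)
        assert once == twice

    def test_depends_only_on_internals(self):
        epi, _ = fixture_delta_notch(6, 6)
        rng = np.random.default_rng(2)
        st = epi.zero_state()
        st.levels["Red"][:] = rng.integers(0, 2, (6, 6))
        scrambled = st.copy()
        scrambled.levels["Green"][:] = rng.integers(0, 2, (6, 6))
        assert resolve_inputs(epi, st) == resolve_inputs(epi, scrambled)

    def test_locality_far_flips_do_not_matter(self):
        epi, _ = fixture_delta_notch(12, 12, rule_variant="dist3_atleast12")
        rng = np.random.default_rng(3)
        st = epi.zero_state()
        st.levels["Red"][:] = rng.integers(0, 2, (12, 12))
        cell = CellCoord(2, 2)
        base = eval_integration_input(epi, st, cell, "Green")
        far = [
            c for c in epi.topology.cells() if epi.topology.hex_distance(cell, c) > 3
        ]
        for _ in range(10):
            pick = far[rng.integers(len(far))]
            st.set_level("Red", pick, 1 - st.level("Red", pick))
            assert eval_integration_input(epi, st, cell, "Green") == base


class TestPerturbations:
    def test_knockout_everywhere_sticks(self):
        epi, _ = fixture_delta_notch(4, 4)
        epi.perturbations.append(Perturbation("Red", 0))
        st = epi.zero_state()
        st.levels["Red"][:] = 1
        clamped = apply_perturbations(epi, st)
        assert not clamped.levels["Red"].any()
        after = step_synchronous(epi, clamped)
        assert not after.levels["Red"].any()

    def test_empty_list_is_identity(self):
        epi, _ = fixture_delta_notch(3, 3)
        st = epi.zero_state()
        st.levels["Red"][1, 1] = 1
        assert apply_perturbations(epi, st) == st

    def test_region_restricted_ectopic_expression(self):
        epi, _ = fixture_delta_notch(4, 4)
        region = frozenset({CellCoord(0, 0), CellCoord(1, 0)})
        epi.perturbations.append(Perturbation("Red", 1, region))
        out = apply_perturbations(epi, epi.zero_state())
        for cell in epi.topology.cells():
            assert out.level("Red", cell) == int(cell in region)

    def test_idempotent_and_commuting_on_disjoint_regions(self):
        epi, _ = fixture_delta_notch(4, 4)
        p1 = Perturbation("Red", 1, frozenset({CellCoord(0, 0)}))
        p2 = Perturbation("Red", 0, frozenset({CellCoord(3, 3)}))
        epi.perturbations.extend([p1, p2])
        st = epi.zero_state()
        once = apply_perturbations(epi, st)
        assert apply_perturbations(epi, once) == once
        epi.perturbations[:] = [p2, p1]
        assert apply_perturbations(epi, st) == once


class TestValidate:
    def test_fixture_is_clean(self):
        epi, _ = fixture_delta_notch(5, 5)
        assert validate(epi) == []

    def test_input_declared_both_ways(self):
        epi, _ = fixture_delta_notch(3, 3)
        epi.positional["Green"] = PositionalInput(0)
        findings = validate(epi)
        assert any("both positional and integration" in f for f in findings)

    def test_integration_atom_naming_an_input(self):
        epi, _ = fixture_delta_notch(3, 3)
        epi.integration["Green"][1] = parse_integration_rule(
            "Green>=1 [1:1] atleast 1", "Green", 1
        )
        findings = validate(epi)
        assert any("internal components" in f for f in findings)

    def test_undeclared_input_detected(self):
        epi, _ = fixture_delta_notch(3, 3)
        epi.integration.clear()
        findings = validate(epi)
        assert any("neither" in f for f in findings)

    def test_overlapping_perturbations_rejected(self):
        epi, _ = fixture_delta_notch(3, 3)
        epi.perturbations.extend(
            [
                Perturbation("Red", 1, frozenset({CellCoord(0, 0), CellCoord(1, 0)})),
                Perturbation("Red", 0, frozenset({CellCoord(1, 0)})),
            ]
        )
        findings = validate(epi)
        assert any("overlapping" in f for f in findings)

    def test_initial_out_of_range(self):
        epi, _ = fixture_delta_notch(3, 3)
        epi.initial.levels["Red"][0, 0] = 2  # Boolean component
        findings = validate(epi)
        assert any("outside" in f for f in findings)

    def test_rule_level_above_input_max(self):
        epi, _ = fixture_delta_notch(3, 3)
        epi.integration["Green"][2] = parse_integration_rule(
            "Red>=1 [1:1] atleast 3", "Green", 2
        )
        findings = validate(epi)
        assert any("exceeds max_level" in f for f in findings)


class TestGridState:
    def test_equality_and_copy_are_independent(self):
        a = GridState.filled(3, 2, ["X"], 0)
        b = a.copy()
        b.set_level("X", CellCoord(0, 0), 1)
        assert a != b
        assert a == GridState.filled(3, 2, ["X"], 0)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(Exception, match="shape"):
            GridState(3, 2, {"X": np.zeros((3, 3), dtype=np.int8)})
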
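"""Blackboard construction, gating soundness, WM binding, structure
readout and content-addressable retrieval."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conceptboard.blackboard import (
    KIND_ROLES,
    PoolExhaustedError,
    make_blackboard,
)
from conceptboard.fixtures import fixture


def tiny_bb(**kw):
    return make_blackboard({"cat": "N", "sees": "V"}, {"N": 2, "V": 1, "S": 1}, **kw)


class TestConstruction:
    def test_count_arithmetic_for_minimal_blackboard(self):
        """1 word, 1 N assembly, no matrices: 1 concept + 1 main + one
        population per sub-assembly + 3 per main-sub gating circuit
        (two directions per role)."""
        bb = make_blackboard({"cat": "N"}, {"N": 1}, role_pairs=(), word_matrices=False)
        n_roles = len(KIND_ROLES["N"])
        assert bb.population_count() == 1 + 1 + n_roles + 2 * 3 * n_roles
        assert bb.population_count() == bb.expected_population_count()

    def test_two_by_two_connection_matrix_has_four_nodes(self):
        bb = make_blackboard(
            {"a": "N", "b": "V"},
            {"N": 2, "V": 2},
            role_pairs=((("V", "t"), ("N", "t")),),
            word_matrices=False,
        )
        assert len(bb.role_matrices[("V", "t", "N", "t")].nodes) == 4

    def test_nine_word_sentence_structure_exceeds_300_populations(self):
        fx = fixture("bill-gates")
        bb = make_blackboard(fx.vocabulary, fx.pool_sizes)
        assert bb.population_count() > 300

    @pytest.mark.parametrize("name", ["cat-is-on-mat", "cat-sees-cat", "bill-gates"])
    def test_count_audit_matches_closed_form(self, name):
        fx = fixture(name)
        bb = make_blackboard(fx.vocabulary, fx.pool_sizes)
        assert bb.population_count() == bb.expected_population_count()

    def test_empty_vocabulary_rejected(self):
        with pytest.raises(ValueError):
            make_blackboard({}, {"N": 1})
        with pytest.raises(ValueError):
            make_blackboard({"cat": "N"}, {"N": 0})

    def test_pool_exhaustion_is_explicit(self):
        bb = tiny_bb()
        bb.recruit("V")
        with pytest.raises(PoolExhaustedError):
            bb.recruit("V")

    def test_recruitment_is_lowest_index_first(self):
        bb = tiny_bb()
        assert bb.recruit("N").name == "N1"
        assert bb.recruit("N").name == "N2"


class TestGates:
    def test_open_gate_activates_sub_assembly(self):
        bb = tiny_bb()
        bb.settle(60)
        sa = bb.assembly("V", 0)
        bb.open_role_gates("V", "v", True)
        bb.drive(sa.main, 1.0)
        for _ in range(200):
            bb.step(scan=False)
        assert bb.net.activity(sa.subs["v"]) > 0.3

    def test_closed_gate_blocks_flow(self):
        bb = tiny_bb()
        bb.settle(60)
        sa = bb.assembly("V", 0)
        bb.drive(sa.main, 1.0)
        for _ in range(200):
            bb.step(scan=False)
        assert bb.net.activity(sa.subs["v"]) < 0.02

    def test_sub_assembly_decays_after_gate_closes(self):
        bb = tiny_bb()
        bb.settle(60)
        sa = bb.assembly("V", 0)
        bb.open_role_gates("V", "v", True)
        bb.drive(sa.main, 1.0)
        for _ in range(200):
            bb.step(scan=False)
        bb.open_role_gates("V", "v", False)
        bb.drive(sa.main, 0.0)
        for _ in range(300):
            bb.step(scan=False)
        assert bb.net.activity(sa.subs["v"]) < 0.02

    def test_invalid_kind_role_rejected(self):
        bb = tiny_bb()
        with pytest.raises(ValueError):
            bb.open_role_gates("N", "pv", True)

    @settings(max_examples=5, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 1000))
    def test_gate_soundness_under_random_stimulation(self, seed):
        """With di never driven, sub-assemblies stay at baseline whatever
        the stimulation of mains and concepts."""
        rng = np.random.default_rng(seed)
        bb = tiny_bb()
        bb.settle(60)
        targets = [bb.assembly("N", 0).main, bb.assembly("V", 0).main,
                   bb.concepts["cat"].pop]
        for _ in range(5):
            pid = targets[rng.integers(len(targets))]
            bb.drive(pid, float(rng.uniform(0.3, 1.5)))
            for _ in range(rng.integers(20, 80)):
                bb.step(scan=False)
            bb.drive(pid, 0.0)
        for sa in bb.pools["N"] + bb.pools["V"]:
            for role, pid in sa.subs.items():
                assert bb.net.activity(pid) < 0.05


class TestBinding:
    def drive_pair(self, bb, a, b, role):
        bb.settle(60)
        bb.drive(a.main, 1.0)
        bb.drive(b.main, 1.0)
        bb.open_role_gates(a.kind, role, True)
        bb.open_role_gates(b.kind, role, True)

    def test_coactive_subs_ignite_wm(self):
        bb = tiny_bb()
        self.drive_pair(bb, bb.assembly("V", 0), bb.assembly("N", 1), "t")
        bound = []
        for _ in range(150):
            bound += bb.step(scan=True)
        assert bound == [("V1.t", "N2.t")]

    def test_single_active_sub_does_not_bind(self):
        bb = tiny_bb()
        bb.settle(60)
        sa = bb.assembly("V", 0)
        bb.drive(sa.main, 1.0)
        bb.open_role_gates("V", "t", True)
        bb.open_role_gates("N", "t", True)
        for _ in range(150):
            assert bb.step(scan=True) == []

    def test_multiple_coactivities_all_ignite_and_match_exhaustive_scan(self):
        """Both N sub-assemblies co-active with V1's: two ignitions, and
        a brute-force scan over every node agrees with the recorded set."""
        bb = tiny_bb()
        bb.settle(60)
        bb.drive(bb.assembly("V", 0).main, 1.0)
        bb.drive(bb.assembly("N", 0).main, 1.0)
        bb.drive(bb.assembly("N", 1).main, 1.0)
        bb.open_role_gates("V", "t", True)
        bb.open_role_gates("N", "t", True)
        for _ in range(150):
            bb.step(scan=True)
        bound = {(a, b) for _, a, b in bb.active_bindings()}
        assert bound == {("V1.t", "N1.t"), ("V1.t", "N2.t")}
        # exhaustive oracle: every node whose endpoints are now above
        # threshold must be exactly the ignited set
        expected = set()
        for matrix in list(bb.role_matrices.values()) + list(bb.word_matrices.values()):
            for node in matrix.nodes.values():
                if (
                    bb.net.activity(node.a) >= bb.ignition_threshold
                    and bb.net.activity(node.b) >= bb.ignition_threshold
                ):
                    expected.add((node.a, node.b))
        assert bound == expected

    def test_binding_persists_without_input(self):
        """Once ignited, WM stays above half its ignition level for well
        over a second with every drive removed."""
        bb = tiny_bb()
        self.drive_pair(bb, bb.assembly("V", 0), bb.assembly("N", 1), "t")
        for _ in range(150):
            bb.step(scan=True)
        wm = bb.role_node("V1", "t", "N2", "t").wm
        level = bb.net.activity(wm)
        bb.drive(bb.assembly("V", 0).main, 0.0)
        bb.drive(bb.assembly("N", 1).main, 0.0)
        bb.open_role_gates("V", "t", False)
        bb.open_role_gates("N", "t", False)
        for _ in range(1500):
            bb.step(scan=False)
        assert bb.net.activity(wm) >= 0.5 * level

    def test_fresh_blackboard_has_empty_structure(self):
        assert tiny_bb().bound_structure() == []

    def test_reset_clears_bindings(self):
        bb = tiny_bb()
        self.drive_pair(bb, bb.assembly("V", 0), bb.assembly("N", 1), "t")
        for _ in range(150):
            bb.step(scan=True)
        assert bb.bound_structure()
        bb.reset()
        assert bb.bound_structure() == []
        assert bb.recruit("N").name == "N1"


class TestStructureReadout:
    def test_cat_is_on_mat_connection_path(self, parsed_cat_is_on_mat):
        _, bb, _, _ = parsed_cat_is_on_mat
        triples = set(bb.bound_structure())
        assert triples == {
            ("cat", "word", "N1"),
            ("S1", "n", "N1"),
            ("is", "word", "V1"),
            ("S1", "v", "V1"),
            ("on", "word", "PP1"),
            ("V1", "pv", "PP1"),
            ("PP1", "pn", "N2"),
            ("mat", "word", "N2"),
        }

    def test_problem_of_two(self, parsed_cat_sees_cat):
        """*cat sees cat*: one in-situ concept assembly for cat, bound to
        two different structure assemblies (subject N1 and theme N2)."""
        _, bb, _, _ = parsed_cat_sees_cat
        assert sum(1 for w in bb.concepts if w == "cat") == 1
        cat_bindings = [t for t in bb.bound_structure() if t[0] == "cat"]
        assert sorted(b for _, _, b in cat_bindings) == ["N1", "N2"]

    def test_edge_list_export(self, parsed_cat_sees_cat, tmp_path):
        _, bb, _, _ = parsed_cat_sees_cat
        path = tmp_path / "edges.csv"
        bb.export_edge_list(path)
        lines = path.read_text().splitlines()
        assert lines[0] == "element_a,role,element_b"
        assert len(lines) == 1 + len(bb.bound_structure())


class TestRetrieve:
    WHERE_GATES = [
        ("N", "n"), ("S", "n"), ("S", "v"), ("V", "v"),
        ("V", "pv"), ("PP", "pv"), ("PP", "pn"), ("N", "pn"),
    ]

    def test_cue_cat_retrieves_mat(self, parsed_cat_is_on_mat):
        _, bb, _, _ = parsed_cat_is_on_mat
        words, _ = bb.retrieve("cat", self.WHERE_GATES, "N")
        assert words == {"mat"}

    def test_empty_blackboard_retrieves_nothing(self):
        bb = make_blackboard(
            fixture("cat-is-on-mat").vocabulary,
            fixture("cat-is-on-mat").pool_sizes,
        )
        words, _ = bb.retrieve("cat", self.WHERE_GATES, "N")
        assert words == set()

    def test_theme_retrieval_goes_through_n2(self, parsed_cat_sees_cat):
        """Theme retrieval returns the shared word *cat*, and the binding
        it flows through is N2 — confirmed by a graph walk over the bound
        structure, independent of the dynamics."""
        _, bb, _, _ = parsed_cat_sees_cat
        words, assemblies = bb.retrieve("sees", [("V", "t"), ("N", "t")], "N")
        assert words == {"cat"}
        theme = [b for a, role, b in bb.bound_structure() if a == "V1" and role == "t"]
        assert theme == ["N2"]

    def test_unknown_cue_rejected(self, parsed_cat_is_on_mat):
        _, bb, _, _ = parsed_cat_is_on_mat
        with pytest.raises(KeyError):
            bb.retrieve("unicorn", [], "N")


def test_blackboard_json_includes_bindings(parsed_cat_sees_cat):
    import json

    _, bb, _, _ = parsed_cat_sees_cat
    doc = json.loads(bb.to_json())
    assert doc["concepts"]["cat"] == "N"
    assert ["S1", "n", "N1"] in doc["bindings"]
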
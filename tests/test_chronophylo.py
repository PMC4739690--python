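import numpy as np
import pytest

from rhinopath import (
    CalibrationConfig,
    CalibrationError,
    NewickParseError,
    ValidationError,
    calibrate_basic,
    calibrate_equal,
    load_study_tree,
    load_taxon_profiles,
    prune_to_taxa,
    read_newick,
    write_newick,
)

from conftest import profile


class TestNewickIO:
    def test_topology_only(self):
        tree = read_newick("((A,B),C);")
        assert sorted(l.taxon.label for l in tree.leaf_node_iter()) == ["A", "B", "C"]

    def test_branch_lengths(self):
        tree = read_newick("((A:1,B:1):1,C:2);")
        lengths = sorted(
            nd.edge.length for nd in tree.preorder_node_iter() if nd.parent_node
        )
        assert lengths == [1, 1, 1, 2]

    @pytest.mark.parametrize("text", ["((A,B),C);", "((A:1.0,B:1.0):1.0,C:2.0);"])
    def test_round_trip(self, text):
        assert write_newick(read_newick(text)) == text

    @pytest.mark.parametrize(
        "bad, msg",
        [
            ("((A,B),C)", "missing terminal ';'"),
            ("((A,B)),C);", "unmatched"),
            ("((A,(B,C);", "unclosed"),
        ],
    )
    def test_parse_errors_carry_offsets(self, bad, msg):
        with pytest.raises(NewickParseError, match=msg):
            read_newick(bad)


TWO_TIP = "(A,B);"


class TestBasicCalibration:
    def test_tip_at_lad_when_terminal_ranges_extended(self):
        profiles = {"A": profile("A", 50, 46), "B": profile("B", 37, 34)}
        tt = calibrate_basic(
            read_newick(TWO_TIP), profiles,
            CalibrationConfig(method="basic", root_extension_myr=0),
        )
        assert tt.root_age == 50
        assert tt.tip_ages() == {"A": 46, "B": 34}
        assert sorted(tt.durations()) == [4, 16]

    def test_tip_at_fad_without_extension(self):
        profiles = {"A": profile("A", 50, 46), "B": profile("B", 37, 34)}
        tt = calibrate_basic(
            read_newick(TWO_TIP), profiles,
            CalibrationConfig(method="basic", root_extension_myr=0,
                              extend_tips_to_lad=False),
        )
        assert tt.tip_ages()["A"] == 50
        assert min(tt.durations()) == 0  # zero-duration branch permitted

    def test_equal_fads_give_zero_internal_branch(self):
        profiles = {k: profile(k, 40, 38) for k in "ABC"}
        tt = calibrate_basic(
            read_newick("((A,B),C);"), profiles,
            CalibrationConfig(method="basic", root_extension_myr=0),
        )
        ages = {nd.age for nd in tt.tree.preorder_internal_node_iter()}
        assert ages == {40}

    def test_missing_profile_named(self):
        with pytest.raises(CalibrationError, match="'B'"):
            calibrate_basic(read_newick(TWO_TIP), {"A": profile("A", 50, 46)},
                            CalibrationConfig(method="basic"))

    def test_polytomy_rejected(self):
        profiles = {k: profile(k, 40, 38) for k in "ABC"}
        with pytest.raises(CalibrationError, match="dichotomous"):
            calibrate_basic(read_newick("(A,B,C);"), profiles,
                            CalibrationConfig(method="basic"))


class TestEqualCalibration:
    def test_single_zero_chain_split_in_half(self):
        # root--X has 6 Myr, X--A has 0: the 6 are shared 3 and 3
        profiles = {"A": profile("A", 50, 50, extant=False),
                    "B": profile("B", 47, 44, extant=False),
                    "C": profile("C", 56, 53, extant=False)}
        tt = calibrate_equal(
            read_newick("((A,B),C);"), profiles,
            CalibrationConfig(root_extension_myr=0),
        )
        # internal node X (parent of A,B) had basic age 50, root age 56
        x = next(l for l in tt.tree.leaf_node_iter()
                 if l.taxon.label == "A").parent_node
        assert x.age == pytest.approx(53.0)
        assert x.edge.length == pytest.approx(3.0)
        assert tt.tip_ages() == {"A": 50, "B": 44, "C": 53}

    def test_two_consecutive_zeros_split_in_thirds(self):
        # a 9-Myr branch above two zero-duration branches becomes 3,3,3
        profiles = {k: profile(k, 50, 50, extant=False) for k in "ABC"}
        profiles["D"] = profile("D", 59, 55, extant=False)
        tt = calibrate_equal(
            read_newick("(((A,B),C),D);"), profiles,
            CalibrationConfig(root_extension_myr=0),
        )
        internal = [nd.edge.length for nd in tt.tree.preorder_internal_node_iter()
                    if nd.parent_node]
        assert sorted(internal) == pytest.approx([3.0, 3.0])
        ages = {round(nd.age, 9) for nd in tt.tree.preorder_internal_node_iter()}
        assert ages == {59, 56, 53}
        assert min(tt.durations()) > 0

    def test_fixed_point_when_no_zero_branches(self):
        profiles = {"A": profile("A", 50, 46), "B": profile("B", 37, 34)}
        cfg = CalibrationConfig(root_extension_myr=2.0)
        basic = calibrate_basic(read_newick(TWO_TIP), profiles, cfg)
        equal = calibrate_equal(read_newick(TWO_TIP), profiles, cfg)
        assert basic.root_to_tip_durations() == equal.root_to_tip_durations()
        assert sorted(basic.durations()) == sorted(equal.durations())

    def test_no_donor_is_explicit_error(self):
        profiles = {k: profile(k, 40, 38) for k in "ABC"}
        with pytest.raises(CalibrationError, match="root_extension"):
            calibrate_equal(read_newick("((A,B),C);"), profiles,
                            CalibrationConfig(root_extension_myr=0))

    def test_study_fixture_calibration(self):
        tt = calibrate_equal(load_study_tree(), load_taxon_profiles(),
                             CalibrationConfig(root_extension_myr=1.0))
        profiles = load_taxon_profiles()
        for taxon, age in tt.tip_ages().items():
            assert age == pytest.approx(profiles[taxon].lad_ma)
        assert tt.root_age >= 50.5  # at least the oldest FAD
        assert min(tt.durations()) > 0
        # extant tip sits at the present
        assert tt.tip_ages()["Diceros bicornis"] == 0.0

    def test_invariants_on_random_datasets(self, rng):
        from rhinopath.synth import _random_profiles, random_topology, SyntheticConfig

        cfg = SyntheticConfig(n_taxa=8, tree_source="random")
        for _ in range(30):
            labels = [f"t{i}" for i in range(8)]
            topo = random_topology(labels, rng)
            profiles = _random_profiles(labels, cfg, rng)
            ext = float(rng.uniform(0.5, 3.0))
            ccfg = CalibrationConfig(root_extension_myr=ext)
            basic = calibrate_basic(topo, profiles, ccfg)
            equal = calibrate_equal(topo, profiles, ccfg)
            assert min(equal.durations()) > 0
            for taxon, age in equal.tip_ages().items():
                assert age == pytest.approx(profiles[taxon].lad_ma)
            # conservation: root-to-tip durations match the basic solution
            b, e = basic.root_to_tip_durations(), equal.root_to_tip_durations()
            for taxon in b:
                assert e[taxon] == pytest.approx(b[taxon])
            # strict age ordering
            for nd in equal.tree.preorder_node_iter():
                if nd.parent_node is not None:
                    assert nd.parent_node.age > nd.age


class TestPrune:
    def test_prune_drops_and_suppresses(self):
        pruned = prune_to_taxa(read_newick("((A,B),C);"), {"A", "C"})
        assert write_newick(pruned) == "(A,C);"

    def test_prune_to_all_tips_is_identity(self):
        tree = read_newick("((A:1,B:2):3,C:4);")
        assert write_newick(prune_to_taxa(tree, {"A", "B", "C"})) == \
            "((A:1.0,B:2.0):3.0,C:4.0);"

    def test_durations_sum_across_suppressed_nodes(self):
        pruned = prune_to_taxa(read_newick("((A:1,B:2):3,(C:4,D:5):6);"), {"A", "C"})
        lengths = {l.taxon.label: l.edge.length for l in pruned.leaf_node_iter()}
        assert lengths == {"A": 4.0, "C": 10.0}

    def test_empty_keep_rejected(self):
        with pytest.raises(ValidationError):
            prune_to_taxa(read_newick("(A,B);"), set())

    def test_unknown_taxon_rejected(self):
        with pytest.raises(ValidationError, match="Z"):
            prune_to_taxa(read_newick("(A,B);"), {"A", "Z"})
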
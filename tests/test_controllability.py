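import numpy as np
import pytest

from carocontrol.controllability import (
    OrientationError,
    classify_category,
    control_node_identities,
    control_profile,
    enumerate_orientation_variants,
    maximum_matching,
)
from carocontrol.synthetic_data import sample_digraphs, small_instances
from conftest import make_network
from oracles import brute_control_counts, brute_max_matching


class TestMaximumMatching:
    def test_chain_matches_every_edge(self, chain):
        edges, matched, unmatched = maximum_matching(chain)
        assert len(edges) == 2 and unmatched == {"a"}

    def test_star_single_match(self, star):
        edges, matched, unmatched = maximum_matching(star)
        assert len(edges) == 1
        assert "a" in unmatched and len(unmatched) == 2

    def test_empty_edge_set_all_unmatched(self):
        net = make_network("iso", ["a", "b", "c"], [], [])
        _, matched, unmatched = maximum_matching(net)
        assert matched == set() and unmatched == {"a", "b", "c"}

    def test_matches_brute_force_on_small_digraphs(self):
        for net in small_instances(3):
            edges = [(r.substrate, r.product) for r in net.reactions.values()]
            m, matched, _ = maximum_matching(net)
            assert len(m) == brute_max_matching(edges), edges

    def test_unresolved_reversible_errors(self):
        net = make_network("x", ["d"], ["m", "p"], [("d", "m"), ("m", "p")],
                           reversible=[("m", "p")])
        with pytest.raises(OrientationError):
            maximum_matching(net)


class TestControlProfile:
    def test_chain_is_source_controlled(self, chain):
        p = control_profile(chain)
        assert (p.Nc, p.Ns, p.Ni, p.Ne) == (1, 1, 0, 0)
        assert p.eta == (1.0, 0.0, 0.0)

    def test_star_has_sink_control(self, star):
        p = control_profile(star)
        assert (p.Nc, p.Ns, p.Ni, p.Ne) == (2, 1, 0, 1)
        assert p.eta == (0.5, 0.0, 0.5)

    def test_merge_branch_needs_internal_control(self, merge_branch):
        p = control_profile(merge_branch)
        assert (p.Nc, p.Ns, p.Ni, p.Ne) == (3, 2, 1, 0)
        assert p.eta == (2 / 3, 1 / 3, 0.0)

    def test_decomposition_always_exact(self):
        for net in sample_digraphs(5, 150, seed=9):
            p = control_profile(net)
            assert p.Nc == p.Ns + p.Ni + p.Ne
            assert abs(sum(p.eta) - 1.0) < 1e-12

    def test_perfectly_matched_cycle_needs_one_control(self):
        cyc = make_network("cyc", [], ["a", "b", "c"],
                           [("a", "b"), ("b", "c"), ("c", "a")])
        p = control_profile(cyc)
        assert p.Nc == 1 and p.Ni == 1  # floor fires: cycle needs one control

    def test_disconnected_dietary_node_adds_one_source(self, merge_branch):
        from carocontrol.core_model import CarotenoidNetwork, Compound

        before = control_profile(merge_branch)
        grown = CarotenoidNetwork(
            "grown",
            list(merge_branch.compounds.values()) + [Compound("d9", "dietary")],
            merge_branch.reactions.values(),
        )
        after = control_profile(grown)
        assert after.Ns == before.Ns + 1 and after.Nc == before.Nc + 1

    def test_edge_reversal_swaps_sources_and_sinks(self):
        for net in sample_digraphs(4, 60, seed=3):
            g = net.to_digraph()
            rev = make_network(
                "rev", [], sorted(net.compounds),
                [(v, u) for u, v in g.edges],
            )
            p, prev = control_profile(net), control_profile(rev)
            sinks = sum(1 for v in g.nodes if g.out_degree(v) == 0)
            assert prev.Ns == sinks
            assert len(maximum_matching(net)[0]) == len(maximum_matching(rev)[0])

    def test_eta_invariant_under_relabeling(self, merge_branch):
        relabeled = make_network(
            "perm", ["x1", "x2"], ["y", "z1", "z2"],
            [("x1", "y"), ("x2", "y"), ("y", "z1"), ("y", "z2")],
        )
        assert control_profile(relabeled).eta == control_profile(merge_branch).eta


class TestControlNodeIdentities:
    def test_chain_only_source_unmatched(self, chain):
        ids = control_node_identities(chain)
        assert ids["a"]["can_be_unmatched"]
        assert not ids["b"]["can_be_unmatched"]
        assert not ids["c"]["can_be_unmatched"]

    def test_merge_branch_tie_between_products(self, merge_branch):
        ids = control_node_identities(merge_branch)
        assert ids["d1"]["can_be_unmatched"] and ids["d2"]["can_be_unmatched"]
        # either p1 or p2 can be left unmatched (matching tie), m never
        assert ids["p1"]["can_be_unmatched"] and ids["p2"]["can_be_unmatched"]
        assert not ids["m"]["can_be_unmatched"]
        # m is degree-symmetric (in 2, out 2): the degree-asymmetry rule does
        # not flag it, which is why counts come from the decomposition instead
        assert ids["m"]["role"] == "matched-like"

    def test_isolated_dietary_all_sources(self):
        net = make_network("iso", ["a", "b", "c"], [], [])
        ids = control_node_identities(net)
        assert all(v["can_be_unmatched"] and v["role"] == "source" for v in ids.values())


class TestOrientationVariants:
    def test_no_reversible_single_variant(self, chain):
        vs = enumerate_orientation_variants(chain)
        assert len(vs.variants) == 1
        assert vs.profiles[0] == control_profile(chain)

    def test_two_reversible_four_variants(self):
        net = make_network(
            "x", ["d"], ["m1", "m2", "m3"],
            [("d", "m1"), ("m1", "m2"), ("m2", "m3")],
            reversible=[("m1", "m2"), ("m2", "m3")],
        )
        vs = enumerate_orientation_variants(net)
        assert len(vs.variants) == 4

    def test_variant_profiles_match_oracle(self):
        net = make_network(
            "x", ["d"], ["m1", "m2"], [("d", "m1"), ("m1", "m2")],
            reversible=[("m1", "m2")],
        )
        vs = enumerate_orientation_variants(net)
        for variant, prof in zip(vs.variants, vs.profiles):
            edges = [(r.substrate, r.product) for r in variant.reactions.values()]
            nc, ns, ni, ne = brute_control_counts(sorted(variant.compounds), edges)
            assert (prof.Nc, prof.Ns, prof.Ni, prof.Ne) == (nc, ns, ni, ne)

    def test_cap_exceeded_errors(self):
        edges = [(f"m{i}", f"m{i+1}") for i in range(1, 6)]
        net = make_network(
            "x", ["d"], [f"m{i}" for i in range(1, 7)],
            [("d", "m1"), *edges], reversible=edges,
        )
        with pytest.raises(ValueError, match="cap"):
            enumerate_orientation_variants(net, cap=4)
        vs = enumerate_orientation_variants(net, cap=4, sample_seed=0, sample_size=8)
        assert vs.sampled and len(vs.variants) == 8

    def test_reaction_classes_cover_all_reactions(self, merge_branch):
        vs = enumerate_orientation_variants(merge_branch)
        assert set(vs.reaction_classes) == set(merge_branch.reactions)
        assert set(vs.reaction_classes.values()) <= {"always", "sometimes", "never"}


class TestClassifyCategory:
    def test_isolated_dietary_is_category_1(self):
        net = make_network("c1", ["d1", "d2"], [], [])
        assert classify_category(control_profile(net), net) == 1

    def test_single_chain_is_category_2(self, chain):
        assert classify_category(control_profile(chain), chain) == 2

    def test_degenerate_source_controlled_is_category_3(self):
        # two dietary inputs converging on one product: fully source
        # controlled (eta_s = 1) but degenerate
        net = make_network("deg", ["d1", "d2"], ["m"], [("d1", "m"), ("d2", "m")])
        prof = control_profile(net)
        assert prof.eta_s == 1.0
        assert classify_category(prof, net) == 3

    def test_merge_branch_is_category_4(self, merge_branch):
        assert classify_category(control_profile(merge_branch), merge_branch) == 4

    def test_star_is_category_6(self, star):
        assert classify_category(control_profile(star), star) == 6

    def test_two_parallel_chains_category_2(self):
        net = make_network(
            "two", ["d1", "d2"], ["m1", "m2"], [("d1", "m1"), ("d2", "m2")]
        )
        assert classify_category(control_profile(net), net) == 2
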
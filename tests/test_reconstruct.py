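"""Character matrices, clade consensus, and Sankoff parsimony."""

from __future__ import annotations

import itertools
import math
import random

import numpy as np
import pytest

from cactaintrons.io import parse_newick
from cactaintrons.reconstruct import (
    GAIN,
    LOSS,
    CharacterMatrix,
    ReconstructionConfig,
    build_character_matrix,
    clade_consensus_exons,
    enumerate_events,
    parsimony_reconstruct,
    replay_events,
)


def brute_force_min_cost(tree, tip_states, gain, loss):
    """Exhaustive minimum over all internal 0/1 labelings (oracle)."""
    internals = [n for n in tree.preorder_node_iter() if not n.is_leaf()]
    best = math.inf
    for assign in itertools.product((0, 1), repeat=len(internals)):
        state = dict(zip((id(n) for n in internals), assign))
        for leaf in tree.leaf_node_iter():
            state[id(leaf)] = tip_states[leaf.taxon.label]
        cost = 0.0
        for node in tree.preorder_node_iter():
            if node.parent_node is None:
                continue
            s, t = state[id(node.parent_node)], state[id(node)]
            cost += gain if (s, t) == (0, 1) else loss if (s, t) == (1, 0) else 0.0
        best = min(best, cost)
    return best


def random_tree(rng, n_tips):
    """Random rooted binary tree over T1..Tn as a newick string."""
    nodes = [f"T{i}" for i in range(1, n_tips + 1)]
    while len(nodes) > 1:
        i, j = sorted(rng.sample(range(len(nodes)), 2), reverse=True)
        a, b = nodes.pop(i), nodes.pop(j)
        nodes.append(f"({a},{b})")
    return nodes[0] + ";"


class TestCharacterMatrix:
    def test_fixture_rows(self, table1, fixture_regions):
        # map generic region labels to the published names via their spans
        span_to_name = {(563, 568): "G", (771, 783): "I", (879, 895): "II", (920, 936): "III"}
        order = [span_to_name[r.span] for r in fixture_regions.regions]
        matrix = build_character_matrix(
            table1, fixture_regions, taxa=list(table1.names)
        )
        def row(taxon):
            return dict(zip(order, matrix.row(taxon)))

        assert row("Baron") == {"G": 1, "I": 1, "II": 1, "III": 1}
        assert row("Storm") == {"G": 0, "I": 1, "II": 0, "III": 0}
        assert row("Horace") == {"G": 0, "I": 0, "II": 0, "III": 0}

    def test_intronless_taxon_gets_zero_row(self, table1, fixture_regions):
        matrix = build_character_matrix(
            table1, fixture_regions, taxa=list(table1.names) + ["PSL"], intronless=["PSL"]
        )
        assert matrix.row("PSL") == (0, 0, 0, 0)
        assert matrix.exon_counts["PSL"] == 1

    def test_undeclared_absent_taxon_is_an_error(self, table1, fixture_regions):
        with pytest.raises(ValueError, match="intronless"):
            build_character_matrix(table1, fixture_regions, taxa=["NotThere"])


class TestCladeConsensus:
    def test_majority_rules(self):
        tree = parse_newick("(((a1,a2),(a3,a4)),((b1,b2),b3));")
        clade_map = {f"a{i}": "A" for i in range(1, 5)} | {f"b{i}": "B" for i in range(1, 4)}
        exon_counts = {"a1": 2, "a2": 2, "a3": 1, "a4": 3, "b1": 2, "b2": 2, "b3": 2}
        out = clade_consensus_exons(tree, clade_map, exon_counts)
        assert out["A"] == (2, False)  # 2 is modal among [2,2,1,3]
        assert out["B"] == (2, False)

    def test_tie_takes_larger_count_and_flags(self):
        tree = parse_newick("(a,b,c,d);")
        out = clade_consensus_exons(
            tree, {t: "X" for t in "abcd"}, {"a": 1, "b": 1, "c": 3, "d": 3}
        )
        assert out["X"] == (3, True)

    def test_unassigned_taxon_is_an_error(self):
        tree = parse_newick("(a,b);")
        with pytest.raises(ValueError, match="not assigned"):
            clade_consensus_exons(tree, {"a": "X"}, {"a": 1, "b": 2})


class TestParsimony:
    def test_all_present_means_present_root_and_no_events(self):
        tree = parse_newick("((A,B),(C,D));")
        m = CharacterMatrix(("A", "B", "C", "D"), ("c1",), np.ones((4, 1), dtype=int))
        recon = parsimony_reconstruct(tree, m)
        assert recon.root_states == {"c1": 1}
        assert recon.events == [] and recon.total_cost == 0

    def test_balanced_split_equal_costs_has_cost_one(self):
        tree = parse_newick("((A,B),(C,D));")
        m = CharacterMatrix(("A", "B", "C", "D"), ("c1",), np.array([[1], [1], [0], [0]]))
        recon = parsimony_reconstruct(tree, m, ReconstructionConfig(gain_cost=1, loss_cost=1))
        assert recon.total_cost == 1
        assert recon.total_cost == brute_force_min_cost(
            tree, {"A": 1, "B": 1, "C": 0, "D": 0}, 1, 1
        )

    def test_clade_specific_character_is_a_single_stem_gain(self):
        # carrier clade cd nested deep enough that the loss-only account
        # needs three independent losses (cost 3) versus one gain (cost 2)
        tree = parse_newick("((((C,D)cd,(E,F)ef)x,(G,H)gh)y,(A,B)ab);")
        states = {t: 1 if t in "CD" else 0 for t in "ABCDEFGH"}
        m = CharacterMatrix(
            tuple("ABCDEFGH"), ("c1",), np.array([[states[t]] for t in "ABCDEFGH"])
        )
        recon = parsimony_reconstruct(tree, m)
        assert [e.as_tuple() for e in recon.events] == [("cd", "c1", GAIN)]
        assert recon.root_states == {"c1": 0}
        # oracle agreement on the same instance
        assert recon.total_cost == brute_force_min_cost(tree, states, 2.0, 1.0)

    def test_tip_absent_from_tree_is_an_error(self):
        tree = parse_newick("(A,B);")
        m = CharacterMatrix(("A", "Z"), ("c1",), np.zeros((2, 1), dtype=int))
        with pytest.raises(ValueError, match="absent from tree"):
            parsimony_reconstruct(tree, m)

    def test_cost_matches_brute_force_on_random_trees(self):
        """Sankoff == exhaustive enumeration for <= 8 tips, arbitrary costs."""
        rng = random.Random(1234)
        for _ in range(200):
            n = rng.randint(2, 8)
            tree = parse_newick(random_tree(rng, n))
            tip_states = {f"T{i}": rng.randint(0, 1) for i in range(1, n + 1)}
            gain = rng.choice([0.5, 1.0, 2.0, 3.5, 10.0])
            loss = rng.choice([0.5, 1.0, 2.0, 3.5, 10.0])
            m = CharacterMatrix(
                tuple(tip_states), ("c1",),
                np.array([[tip_states[t]] for t in tip_states]),
            )
            recon = parsimony_reconstruct(
                tree, m, ReconstructionConfig(gain_cost=gain, loss_cost=loss)
            )
            assert recon.total_cost == pytest.approx(
                brute_force_min_cost(tree, tip_states, gain, loss)
            )
            # the event list realizes exactly the minimal cost
            realized = sum(gain if e.kind == GAIN else loss for e in recon.events)
            assert realized == pytest.approx(recon.total_cost)

    def test_infinite_gain_cost_is_dollo(self):
        """With unpayable gains, each present character is gained at most once
        (equivalently: the root carries it and only losses occur)."""
        rng = random.Random(5)
        for _ in range(50):
            n = rng.randint(3, 8)
            tree = parse_newick(random_tree(rng, n))
            tip_states = {f"T{i}": rng.randint(0, 1) for i in range(1, n + 1)}
            if not any(tip_states.values()):
                continue
            m = CharacterMatrix(
                tuple(tip_states), ("c1",),
                np.array([[tip_states[t]] for t in tip_states]),
            )
            recon = parsimony_reconstruct(
                tree, m, ReconstructionConfig(gain_cost=math.inf, loss_cost=1.0)
            )
            gains = [e for e in recon.events if e.kind == GAIN]
            assert len(gains) == 0 and recon.root_states["c1"] == 1

    def test_replaying_events_reproduces_tip_states(self):
        rng = random.Random(77)
        for _ in range(50):
            n = rng.randint(2, 8)
            tree = parse_newick(random_tree(rng, n))
            data = np.array(
                [[rng.randint(0, 1) for _ in range(3)] for _ in range(n)]
            )
            m = CharacterMatrix(
                tuple(f"T{i}" for i in range(1, n + 1)), ("c1", "c2", "c3"), data
            )
            recon = parsimony_reconstruct(tree, m)
            tips = replay_events(recon)
            for i, taxon in enumerate(m.taxa):
                assert tuple(tips[taxon][c] for c in m.characters) == tuple(data[i])

    def test_root_tie_policy_prefers_presence_and_flags(self):
        tree = parse_newick("(A,B);")
        m = CharacterMatrix(("A", "B"), ("c1",), np.array([[1], [0]]))
        recon = parsimony_reconstruct(tree, m, ReconstructionConfig(gain_cost=1, loss_cost=1))
        assert recon.root_states["c1"] == 1
        assert recon.ambiguous_root_characters == ("c1",)
        recon2 = parsimony_reconstruct(
            tree, m, ReconstructionConfig(gain_cost=1, loss_cost=1, root_tie="absence")
        )
        assert recon2.root_states["c1"] == 0


class TestCladeFixture:
    def test_root_has_three_introns_and_four_exons(self, clade_fixture):
        tree, matrix = clade_fixture
        recon = parsimony_reconstruct(tree, matrix)
        events, summary = enumerate_events(recon)
        assert summary["root_introns"] == ["I", "II", "III"]
        assert summary["root_exon_count"] == 4

    def test_single_gain_of_g_on_gamma_stem(self, clade_fixture):
        tree, matrix = clade_fixture
        recon = parsimony_reconstruct(tree, matrix)
        gains = [e for e in recon.events if e.kind == GAIN]
        assert [e.as_tuple() for e in gains] == [("gamma", "G", GAIN)]

    def test_zero_event_reconstruction_has_empty_event_list(self):
        tree = parse_newick("((A,B),(C,D));")
        m = CharacterMatrix(("A", "B", "C", "D"), ("c1",), np.ones((4, 1), dtype=int))
        events, summary = enumerate_events(parsimony_reconstruct(tree, m))
        assert events == []
        assert summary["root_exon_count"] == 2
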
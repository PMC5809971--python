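"""Perfect phylogeny construction, incompatible-site placement, rooting and
newick round-tripping."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from conftest import random_mutation_tree
from ylineage.phylogeny import (
    CladeTree,
    GenotypeMatrix,
    Node,
    _sankoff,
    build_perfect_phylogeny,
    collapse_zero_mutation_branches,
    four_gamete_compatible,
    from_newick,
    map_incompatible_sites,
    midpoint_root,
    polarize,
    to_newick,
)
from ylineage.simulate import SimConfig, simulate_genealogy, sprinkle_mutations


def matrix_from_columns(samples, columns: dict[int, list[int]]) -> GenotypeMatrix:
    positions = np.array(sorted(columns), dtype=np.int64)
    calls = np.stack([np.array(columns[int(p)], dtype=np.int8) for p in positions],
                     axis=1)
    return GenotypeMatrix(list(samples), positions, calls)


class TestFourGametes:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            ((0, 0, 1, 1), (0, 1, 0, 1), False),  # all four gametes
            ((1, 1, 0, 0), (1, 0, 0, 0), True),  # nested
            ((1, 0, 0, 0), (0, 0, 0, 1), True),  # disjoint
        ],
    )
    def test_textbook_cases(self, a, b, expected):
        assert four_gamete_compatible(np.array(a), np.array(b)) is expected

    def test_missing_calls_excluded_pairwise(self):
        a = np.array([0, 0, 1, 1, -1])
        b = np.array([0, 1, 0, -1, 1])
        # with the missing pairs removed only gametes 00,01,10 remain
        assert four_gamete_compatible(a, b)

    def test_symmetric(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            a = rng.integers(0, 2, size=8)
            b = rng.integers(0, 2, size=8)
            assert four_gamete_compatible(a, b) == four_gamete_compatible(b, a)


class TestPolarize:
    def test_outgroup_defines_ancestral_state(self):
        m = matrix_from_columns(
            ["OUT", "A", "B"], {10: [1, 0, 0], 20: [0, 1, 1]}
        )
        out, anchored, dropped = polarize(m, outgroup="OUT")
        assert anchored
        # site 10: outgroup carries 1 -> flipped; A,B become derived
        assert list(out.column(10)) == [0, 1, 1]
        assert list(out.column(20)) == [0, 1, 1]
        assert dropped == []

    def test_majority_rule_without_outgroup(self):
        m = matrix_from_columns(["A", "B", "C"], {10: [1, 1, 0]})
        out, anchored, _ = polarize(m)
        assert not anchored
        assert list(out.column(10)) == [0, 0, 1]


class TestBuildPerfectPhylogeny:
    def test_two_samples_one_site(self):
        m = matrix_from_columns(["A", "B"], {50: [0, 1]})
        tree, deferred = build_perfect_phylogeny(m)
        assert deferred == []
        assert {t.name for t in tree.tips()} == {"A", "B"}
        assert tree.tip("B").mutations == [50]
        assert tree.tip("A").mutations == []

    def test_caterpillar_from_containment(self):
        # carrier sets {A,B}, {A}, {C,D} force ((A,B),(C,D))
        m = matrix_from_columns(
            ["A", "B", "C", "D"],
            {10: [1, 1, 0, 0], 20: [1, 0, 0, 0], 30: [0, 0, 1, 1]},
        )
        tree, deferred = build_perfect_phylogeny(m)
        assert deferred == []
        clades = {c for i, c in tree.clades().items() if tree.node(i).mutations}
        assert frozenset({"A", "B"}) in clades
        assert frozenset({"A"}) in clades
        assert frozenset({"C", "D"}) in clades

    def test_incompatible_site_deferred(self):
        m = matrix_from_columns(
            ["A", "B", "C", "D"],
            {10: [1, 1, 0, 0], 20: [0, 1, 1, 0]},
        )
        tree, deferred = build_perfect_phylogeny(m)
        assert deferred == [20]

    def test_identical_carrier_sets_share_a_branch(self):
        m = matrix_from_columns(
            ["A", "B", "C"], {10: [1, 1, 0], 20: [1, 1, 0]}
        )
        tree, _ = build_perfect_phylogeny(m)
        assignment = tree.branch_assignment()
        assert assignment[10] == assignment[20]

    def test_zero_derived_site_rejected(self):
        m = matrix_from_columns(["A", "B"], {10: [0, 0]})
        with pytest.raises(ValueError, match="zero derived"):
            build_perfect_phylogeny(m)

    def test_tip_count_additivity(self):
        truth = simulate_genealogy(
            SimConfig(seed=5, n_modern=25, ancient_tips=(),
                      effective_size_years=20_000)
        )
        matrix, _ = sprinkle_mutations(truth, seed=6)
        tree, _ = build_perfect_phylogeny(matrix)
        counts = tree.tip_counts()
        for node in tree.internal_nodes():
            assert counts[node.id] == sum(counts[c.id] for c in node.children)

    def test_simulation_roundtrip_recovers_topology(self):
        cfg = SimConfig(seed=11, n_modern=50, ancient_tips=(),
                        effective_size_years=30_000)
        truth = simulate_genealogy(cfg)
        matrix, _ = sprinkle_mutations(truth, seed=12)
        tree, deferred = build_perfect_phylogeny(matrix)
        assert deferred == []
        recovered = {
            clade
            for nid, clade in tree.clades().items()
            if tree.node(nid).mutations
        }
        true_clades = truth.tree.clades()
        expected = {
            true_clades[n.id]
            for n in truth.tree.preorder()
            if n.parent is not None and truth.branch_mutation_counts.get(n.id, 0) > 0
        }
        assert recovered == expected

    def test_implied_matrix_reproduces_unique_sites(self):
        m = matrix_from_columns(
            ["A", "B", "C", "D"],
            {10: [1, 1, 0, 0], 20: [1, 0, 0, 0], 30: [0, 0, 1, 1],
             40: [0, 1, 0, 0]},
        )
        tree, deferred = build_perfect_phylogeny(m)
        assert deferred == []
        clades = tree.clades()
        for pos, nid in tree.branch_assignment().items():
            assert m.carriers(pos) == clades[nid]


class TestSmallParsimony:
    def test_opposite_sides_recurrent(self, balanced_four_tip_tree):
        m = matrix_from_columns(["A", "B", "C", "D"], {99: [1, 0, 1, 0]})
        result = map_incompatible_sites(balanced_four_tip_tree, m)
        assert result.verdicts[99] == "recurrent"
        assert result.changes[99] == 2

    def test_compatible_site_is_unique(self, balanced_four_tip_tree):
        m = matrix_from_columns(["A", "B", "C", "D"], {99: [1, 1, 0, 0]})
        result = map_incompatible_sites(balanced_four_tip_tree, m)
        assert result.verdicts[99] == "unique"
        assert result.changes[99] == 1

    def test_triallelic_two_independent_placements(self, balanced_four_tip_tree):
        # alt1 marks {A,B}, alt2 marks {C,D}
        m = matrix_from_columns(["A", "B", "C", "D"], {99: [1, 1, 2, 2]})
        result = map_incompatible_sites(balanced_four_tip_tree, m)
        assert result.verdicts[99] == "triallelic"
        assert result.changes[99] == 2
        carrying = [
            n.id
            for n in balanced_four_tip_tree.preorder()
            if 99 in (n.mutations or [])
        ]
        assert len(carrying) == 2

    def test_unassigned_direction_on_root_adjacent_branch(self):
        root = Node(mutations=[])
        left = root.add(Node(mutations=[1]))
        left.add(Node(name="A", mutations=[]))
        left.add(Node(name="B", mutations=[]))
        right = root.add(Node(mutations=[2]))
        right.add(Node(name="C", mutations=[]))
        right.add(Node(name="D", mutations=[]))
        tree = CladeTree(root)
        m = matrix_from_columns(["A", "B", "C", "D"], {99: [1, 1, 0, 0]})
        anchored = map_incompatible_sites(tree.copy(), m, polarity_anchored=True)
        free = map_incompatible_sites(tree.copy(), m, polarity_anchored=False)
        assert anchored.verdicts[99] == "unique"
        assert free.verdicts[99] == "unassigned_direction"

    def test_sankoff_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(42)
        for _ in range(30):
            n_tips = int(rng.integers(4, 9))
            tree = random_mutation_tree(rng, n_tips)
            states = {
                t.name: int(rng.integers(0, 2)) for t in tree.tips()
            }
            if len(set(states.values())) < 2:
                first = tree.tips()[0].name
                states[first] = 1 - states[first]
            changes, _ = _sankoff(tree, states, root_state=0)
            # oracle: enumerate all internal-node state assignments
            internals = tree.internal_nodes()
            best = None
            for combo in itertools.product([0, 1], repeat=len(internals) - 1):
                assigned = {tree.root.id: 0}
                for node, s in zip(internals[1:], combo):
                    assigned[node.id] = s
                for t in tree.tips():
                    assigned[t.id] = states[t.name]
                total = sum(
                    1
                    for node in tree.preorder()
                    if node.parent is not None
                    and assigned[node.id] != assigned[node.parent.id]
                )
                best = total if best is None else min(best, total)
            assert changes == best


class TestMidpointRoot:
    def test_two_tips_split_evenly(self):
        root = Node(mutations=[])
        root.add(Node(name="u", mutations=list(range(1, 11))))
        root.add(Node(name="v", mutations=[]))
        rooted = midpoint_root(CladeTree(root))
        assert sorted(c.length for c in rooted.root.children) == [5, 5]

    def test_three_tip_brute_force(self):
        # pairwise distances 10 (A,B), 8 (A,C), 6 (B,C): root on the 10-path,
        # 5 mutations from each endpoint
        root = Node(mutations=[])
        root.add(Node(name="A", mutations=list(range(1, 7))))
        root.add(Node(name="B", mutations=list(range(10, 14))))
        root.add(Node(name="C", mutations=list(range(20, 22))))
        rooted = midpoint_root(CladeTree(root))
        from ylineage.chronology import _tip_path_counts

        dist = _tip_path_counts(rooted.root)
        assert dist["A"] == 5 and dist["B"] == 5

    def test_idempotent_when_already_midpoint(self):
        root = Node(mutations=[])
        root.add(Node(name="u", mutations=list(range(1, 6))))
        root.add(Node(name="v", mutations=list(range(10, 15))))
        tree = CladeTree(root)
        assert midpoint_root(tree) is tree

    def test_all_zero_lengths_rejected(self):
        root = Node(mutations=[])
        root.add(Node(name="u", mutations=[]))
        root.add(Node(name="v", mutations=[]))
        with pytest.raises(ValueError):
            midpoint_root(CladeTree(root))


class TestNewick:
    def test_roundtrip_five_tips(self):
        rng = np.random.default_rng(3)
        tree = random_mutation_tree(rng, 5)
        again = from_newick(to_newick(tree))
        assert again.same_shape(tree)

    def test_multifurcation_preserved(self):
        # eight sister clades hanging off one node, as in a star-like
        # expansion structure
        root = Node(mutations=[])
        hub = root.add(Node(mutations=[1]))
        for i in range(8):
            hub.add(Node(name=f"T{i}", mutations=[10 + i]))
        root.add(Node(name="OUT", mutations=[99]))
        tree = CladeTree(root)
        again = from_newick(to_newick(tree))
        assert again.same_shape(tree)
        hub_again = [n for n in again.preorder() if len(n.children) == 8]
        assert len(hub_again) == 1

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            from_newick("")
        with pytest.raises(ValueError):
            from_newick("((A:1,B:2;")  # malformed


class TestCollapse:
    def test_zero_mutation_branches_become_multifurcations(self):
        root = Node(mutations=[])
        inner = root.add(Node(mutations=[]))  # no mutations: unobservable
        inner.add(Node(name="A", mutations=[1]))
        inner.add(Node(name="B", mutations=[2]))
        root.add(Node(name="C", mutations=[3]))
        collapsed = collapse_zero_mutation_branches(CladeTree(root))
        assert len(collapsed.root.children) == 3
        assert all(t.is_tip for t in collapsed.root.children)
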
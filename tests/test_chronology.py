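"""Rho statistics, Saillard SDs, calibration, time conversion and the
star-like index."""

from __future__ import annotations

import math

import numpy as np
import pytest

from conftest import annotate_counts, random_mutation_tree
from ylineage.chronology import (
    NodeChronology,
    RateCalibration,
    _mu_from_deltas,
    calibrate_rate,
    chronology_table,
    compare_chronologies,
    date_split_node,
    rho,
    rho_sd,
    starlike_index,
    to_years,
)
from ylineage.phylogeny import CladeTree, Node
from ylineage.pipeline import make_star_tree
from ylineage.simulate import SimConfig, simulate_genealogy, sprinkle_mutations


def oracle_rho(node: Node) -> float:
    """Recursive form rho(v) = sum_c (n_c/n)(rho(c) + l_c): the independent
    cross-check of the direct tip-path average."""

    def n_tips(v: Node) -> int:
        return 1 if v.is_tip else sum(n_tips(c) for c in v.children)

    if node.is_tip:
        return 0.0
    n = n_tips(node)
    return sum(
        (n_tips(c) / n) * (oracle_rho(c) + c.length) for c in node.children
    )


def oracle_rho_var(node: Node) -> float:
    """Recursive Saillard variance: SD^2(v) = sum_c (n_c/n)^2 (l_c + SD^2(c))."""

    def n_tips(v: Node) -> int:
        return 1 if v.is_tip else sum(n_tips(c) for c in v.children)

    if node.is_tip:
        return 0.0
    n = n_tips(node)
    return sum(
        (n_tips(c) / n) ** 2 * (c.length + oracle_rho_var(c))
        for c in node.children
    )


class TestRho:
    def test_star_two_tips_three_mutations(self):
        tree = make_star_tree([3, 3])
        assert rho(tree, tree.root) == 3.0

    def test_unbalanced_mean(self):
        tree = make_star_tree([2, 4])
        assert rho(tree, tree.root) == 3.0

    def test_tip_rho_is_zero(self):
        tree = make_star_tree([3, 3])
        assert rho(tree, tree.tips()[0]) == 0.0

    def test_recursion_matches_direct_computation(self):
        rng = np.random.default_rng(17)
        for _ in range(50):
            tree = random_mutation_tree(rng, int(rng.integers(3, 12)))
            for node in tree.internal_nodes():
                assert rho(tree, node) == pytest.approx(oracle_rho(node))
                assert rho_sd(tree, node) ** 2 == pytest.approx(
                    oracle_rho_var(node)
                )


class TestRhoSd:
    def test_two_tip_star(self):
        tree = make_star_tree([3, 3])
        assert round(rho_sd(tree, tree.root), 2) == 1.22

    def test_three_tip_star(self):
        tree = make_star_tree([2, 2, 2])
        assert round(rho_sd(tree, tree.root), 2) == 0.82
        assert rho_sd(tree, tree.root) == pytest.approx(math.sqrt(6) / 3)

    def test_single_tip_chain_is_sqrt_l(self):
        root = Node(mutations=[])
        root.add(Node(name="A", mutations=list(range(1, 10))))
        root.add(Node(name="B", mutations=[]))
        tree = CladeTree(root)
        # below the root, A's subtree is a single branch of 9 mutations
        node_a = tree.tip("A")
        assert rho_sd(tree, tree.root) == pytest.approx(
            math.sqrt(9 * (1 / 2) ** 2)
        )
        assert rho_sd(tree, node_a) == 0.0


class TestCalibration:
    def star_with_ancient(self) -> CladeTree:
        root = Node(mutations=[])
        for i in range(5):
            root.add(Node(name=f"M{i}", mutations=list(range(100 * i + 1,
                                                             100 * i + 11))))
        root.add(Node(name="ANC", mutations=list(range(900, 903))))
        return CladeTree(root)

    def test_moment_estimator_arithmetic(self):
        # delta = rho_modern - m_c = 10 - 2.65 over age 10,000 yr and 1 Mb
        assert _mu_from_deltas([10 - 2.65], [10_000.0], 1e6) == pytest.approx(
            7.35e-10
        )

    def test_star_tree_estimate(self):
        cal = calibrate_rate(self.star_with_ancient(), [("ANC", 10_000.0)],
                             L_eff=1e6)
        assert cal.mu == pytest.approx(7e-10)
        assert cal.years_per_mutation == pytest.approx(1 / (7e-10 * 1e6))

    def test_zero_age_tips_excluded_not_divided(self):
        tree = self.star_with_ancient()
        cal = calibrate_rate(tree, [("ANC", 10_000.0), ("M0", 0.0)], L_eff=1e6)
        assert cal.mu == pytest.approx(7e-10)
        with pytest.raises(ValueError):
            calibrate_rate(tree, [("M0", 0.0)], L_eff=1e6)

    def test_calibration_tip_needs_modern_relatives(self):
        root = Node(mutations=[])
        inner = root.add(Node(mutations=[1]))
        inner.add(Node(name="ANC1", mutations=[2]))
        inner.add(Node(name="ANC2", mutations=[3]))
        root.add(Node(name="M0", mutations=[4]))
        tree = CladeTree(root)
        with pytest.raises(ValueError, match="modern"):
            calibrate_rate(
                tree, [("ANC1", 8000.0), ("ANC2", 9000.0)], L_eff=1e6
            )

    def test_parameter_recovery_small(self):
        # quick recovery sanity at reduced scale (full check in acceptance)
        mus = []
        for seed in range(5):
            cfg = SimConfig(seed=seed, n_modern=60)
            truth = simulate_genealogy(cfg)
            matrix, _ = sprinkle_mutations(truth, seed=seed + 100)
            from ylineage.phylogeny import build_perfect_phylogeny

            tree, _ = build_perfect_phylogeny(matrix)
            tips = [(n, a) for n, a in truth.tip_ages.items() if a > 0]
            mus.append(calibrate_rate(tree, tips, L_eff=cfg.L).mu)
        assert np.mean(mus) == pytest.approx(0.735e-9, rel=0.35)


class TestTimeConversion:
    @pytest.mark.parametrize(
        "rho_value, expected_kya",
        [(628.78, 256.54), (25.09, 10.24), (0.0, 0.0)],
    )
    def test_years_per_mutation_conversion(self, rho_value, expected_kya):
        entry = NodeChronology(node_id=0, rho=rho_value, sd_rho=1.0, n_tips=2)
        to_years(entry, 408.0)
        assert round(entry.time_years / 1000.0, 2) == expected_kya

    def test_sd_converts_without_rate_uncertainty(self):
        entry = NodeChronology(node_id=0, rho=628.78, sd_rho=20.46, n_tips=150)
        to_years(entry, 408.0)
        assert round(entry.sd_time_years / 1000.0, 2) == 8.35

    def test_rate_calibration_supplies_constant(self):
        cal = RateCalibration(mu=0.735e-9, L_eff=3_335_000)
        assert round(cal.years_per_mutation) == 408


class TestStarlike:
    def test_published_high_value(self):
        res = starlike_index(14.06, 1.19, 18)
        assert round(res.value, 2) == 0.55
        assert res.high

    def test_pure_star_is_exactly_one(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            lengths = [int(x) for x in rng.integers(1, 30, size=rng.integers(2, 15))]
            tree = make_star_tree(lengths)
            s = starlike_index(
                rho(tree, tree.root), rho_sd(tree, tree.root), len(lengths)
            )
            assert s.value == pytest.approx(1.0)

    def test_internal_structure_lowers_index(self):
        root = Node(mutations=[])
        inner = root.add(Node(mutations=[1, 2, 3]))
        inner.add(Node(name="A", mutations=[4]))
        inner.add(Node(name="B", mutations=[5]))
        root.add(Node(name="C", mutations=[6]))
        tree = CladeTree(root)
        s = starlike_index(rho(tree, tree.root), rho_sd(tree, tree.root), 3)
        assert s.value < 1.0

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            starlike_index(1.0, 0.0, 4)
        with pytest.raises(ValueError):
            starlike_index(1.0, 1.0, 1)


class TestSplitDating:
    def test_interpolation(self):
        assert date_split_node(10_000, 2_000, 1, 3) == pytest.approx(8_000)

    def test_boundaries(self):
        assert date_split_node(10_000, 2_000, 0, 3) == 10_000
        assert date_split_node(10_000, 2_000, 3, 0) == 2_000

    def test_invalid_counts(self):
        with pytest.raises(ValueError):
            date_split_node(10_000, 2_000, -1, 3)
        with pytest.raises(ValueError):
            date_split_node(10_000, 2_000, 0, 0)


class TestConcordance:
    def test_perfect_linearity(self):
        a = [1.0, 2.0, 5.0, 9.0]
        assert compare_chronologies(a, [2 * x for x in a]) == pytest.approx(1.0)
        assert compare_chronologies(a, a) == pytest.approx(1.0)

    def test_hand_computed_five_points(self):
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        b = np.array([2.0, 1.0, 4.0, 3.0, 6.0])
        cov = np.mean((a - a.mean()) * (b - b.mean()))
        r2 = cov**2 / (np.var(a) * np.var(b))
        assert compare_chronologies(a, b) == pytest.approx(r2)
        assert compare_chronologies(b, a) == pytest.approx(r2)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            compare_chronologies([1, 1, 1], [1, 2, 3])


class TestChronologyTable:
    def test_unbiased_node_ages_on_simulations(self):
        # mean rho x years-per-mutation tracks the true TMRCA
        mu, L = 0.735e-9, 3_300_000
        ypm = 1 / (mu * L)
        errors = []
        for seed in range(100):
            cfg = SimConfig(seed=seed, n_modern=10, ancient_tips=(),
                            effective_size_years=50_000.0)
            truth = simulate_genealogy(cfg)
            sprinkle_mutations(truth, seed=seed + 10_000)
            annotated = annotate_counts(truth.tree, truth.branch_mutation_counts)
            errors.append(
                rho(annotated, annotated.root) * ypm - truth.tmrca
            )
        se = np.std(errors) / np.sqrt(len(errors))
        assert abs(np.mean(errors)) < 3 * se

    def test_table_columns_and_starlike_flag(self):
        tree = make_star_tree([3, 3])
        table = chronology_table(tree, 408.0)
        row = table.iloc[0]
        assert row["rho"] == 3.00
        assert row["sd_rho"] == 1.22
        assert row["time_kya"] == 1.22
        assert row["sd_time_kya"] == 0.50
        assert row["starlike"] == 1.0 and bool(row["starlike_high"])
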
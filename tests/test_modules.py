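from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from painnet.graphs import NullEnsemble, ThresholdedGraph, proportional_threshold
from painnet.modules import (
    ModularPartition,
    classify_hubs,
    compare_partitions,
    labels_from_mapping,
    modular_link_stats,
    node_profiles,
    optimize_partition,
    signed_modularity_value,
)
from painnet.pipeline import group_graph, subject_condition_matrices
from painnet.roi import load_ground_truth_partition, load_roi_table
from painnet.synth import GroundTruth, default_ground_truth, generate_cohort

from conftest import clique_pair_graph


# ---------------------------------------------------------------------- oracles

def all_set_partitions(items):
    """Enumerate every partition of a list (restricted-growth strings)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for smaller in all_set_partitions(rest):
        for i, block in enumerate(smaller):
            yield smaller[:i] + [[first] + block] + smaller[i + 1:]
        yield [[first]] + smaller


def brute_force_betweenness(A: np.ndarray) -> np.ndarray:
    """Unnormalized betweenness by explicit shortest-path enumeration."""
    n = A.shape[0]
    g = nx.from_numpy_array((A != 0).astype(int))
    bc = np.zeros(n)
    for s, t in combinations(range(n), 2):
        if not nx.has_path(g, s, t):
            continue
        paths = list(nx.all_shortest_paths(g, s, t))
        for p in paths:
            for v in p[1:-1]:
                bc[v] += 1.0 / len(paths)
    return bc


def random_signed_graph(n, seed, p_edge=0.6, signed=True):
    rng = np.random.default_rng(seed)
    A = np.zeros((n, n))
    for i, j in combinations(range(n), 2):
        if rng.random() < p_edge:
            w = rng.uniform(0.2, 1.0)
            if signed and rng.random() < 0.3:
                w = -w
            A[i, j] = A[j, i] = w
    return ThresholdedGraph(A=A, density=p_edge,
                            node_labels=[f"n{i}" for i in range(n)])


# ------------------------------------------------------------- modularity value

class TestSignedModularityValue:
    def test_single_module_gives_zero(self):
        g = clique_pair_graph(4)
        assert signed_modularity_value(g, np.zeros(8, int)) == pytest.approx(
            0.0, abs=1e-12)

    def test_singletons_on_positive_graph_negative(self):
        g = clique_pair_graph(4)
        assert signed_modularity_value(g, np.arange(8)) < 0

    def test_two_cliques_correct_labels_give_half(self):
        g = clique_pair_graph(4)
        labels = np.array([0] * 4 + [1] * 4)
        assert signed_modularity_value(g, labels) == pytest.approx(0.5, abs=1e-12)

    def test_invariant_under_relabeling(self):
        g = random_signed_graph(9, seed=0)
        rng = np.random.default_rng(1)
        labels = rng.integers(0, 3, size=9)
        q1 = signed_modularity_value(g, labels)
        perm = {0: 7, 1: 2, 2: 5}
        q2 = signed_modularity_value(g, np.array([perm[c] for c in labels]))
        assert q1 == pytest.approx(q2, abs=1e-12)

    def test_accepts_mapping_form(self):
        g = clique_pair_graph(3)
        mapping = {lab: ("A" if i < 3 else "B")
                   for i, lab in enumerate(g.node_labels)}
        assert signed_modularity_value(g, mapping) == pytest.approx(0.5)

    def test_reduces_to_newman_girvan_without_negative_edges(self):
        g = random_signed_graph(8, seed=2, signed=False)
        labels = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        gx = nx.from_numpy_array(g.A)
        expected = nx.community.modularity(
            gx, [set(range(4)), set(range(4, 8))], weight="weight")
        assert signed_modularity_value(g, labels) == pytest.approx(expected, abs=1e-12)


# ----------------------------------------------------------------- optimization

class TestOptimizePartition:
    def test_recovers_two_disconnected_cliques_exactly(self):
        g = clique_pair_graph(4)
        part = optimize_partition(g, n_restarts=5, seed=0)
        assert part.Q == pytest.approx(0.5, abs=1e-12)
        assert sorted(part.module_sizes.tolist()) == [4, 4]
        assert len({part.labels[i] for i in range(4)}) == 1
        assert len({part.labels[i] for i in range(4, 8)}) == 1

    def test_deterministic_given_seed(self):
        g = random_signed_graph(12, seed=3)
        p1 = optimize_partition(g, n_restarts=10, seed=42)
        p2 = optimize_partition(g, n_restarts=10, seed=42)
        np.testing.assert_array_equal(p1.labels, p2.labels)
        assert p1.Q == p2.Q

    def test_found_q_dominates_planted_labels(self, pain_mats, truth34):
        _, graph = group_graph(pain_mats, 0.30)
        part = optimize_partition(graph, n_restarts=20, seed=1)
        planted = labels_from_mapping(truth34, graph.node_labels)
        assert part.Q >= signed_modularity_value(graph, planted) - 1e-12

    def test_q_recomputable_from_labels(self):
        g = random_signed_graph(10, seed=4)
        part = optimize_partition(g, n_restarts=10, seed=5)
        assert signed_modularity_value(g, part.labels) == pytest.approx(
            part.Q, abs=1e-12)

    def test_edgeless_graph_returns_trivial_partition(self):
        g = ThresholdedGraph(A=np.zeros((5, 5)), density=0.1,
                             node_labels=list("abcde"))
        part = optimize_partition(g, seed=0)
        assert part.Q == 0.0 and part.n_modules == 1

    @pytest.mark.parametrize("n,seed", [(6, 10), (7, 11), (8, 12), (9, 13)])
    def test_matches_exhaustive_enumeration(self, n, seed):
        """The optimizer attains the global optimum found by enumerating
        every set partition (graphs small enough to enumerate)."""
        g = random_signed_graph(n, seed=seed)
        best = -np.inf
        for blocks in all_set_partitions(list(range(n))):
            labels = np.empty(n, int)
            for c, block in enumerate(blocks):
                labels[block] = c
            best = max(best, signed_modularity_value(g, labels))
        part = optimize_partition(g, n_restarts=20, seed=seed)
        assert part.Q == pytest.approx(best, abs=1e-10)


# ------------------------------------------------------------------ comparisons

class TestComparePartitions:
    def test_identical_partitions(self):
        a = np.array([0, 0, 1, 1, 2])
        res = compare_partitions(a, a.copy())
        assert res["nmi"] == pytest.approx(1.0)
        assert res["exact_match_after_relabel"]

    def test_relabeled_partition_is_exact_match(self):
        a = np.array([0, 0, 1, 1])
        b = np.array([5, 5, 2, 2])
        res = compare_partitions(a, b)
        assert res["nmi"] == pytest.approx(1.0)
        assert res["exact_match_after_relabel"]

    def test_one_block_vs_singletons_nmi_zero(self):
        res = compare_partitions(np.zeros(8, int), np.arange(8))
        assert res["nmi"] == pytest.approx(0.0)
        assert not res["exact_match_after_relabel"]

    def test_node_set_mismatch_rejected(self):
        with pytest.raises(ValueError, match="node set"):
            compare_partitions({"a": 0, "b": 0}, {"a": 0, "c": 0})


# ------------------------------------------------------------------- node roles

class TestNodeProfiles:
    def test_all_links_internal_gives_zero_pc(self):
        g = clique_pair_graph(4)
        part = ModularPartition(labels=np.array([0] * 4 + [1] * 4), Q=0.5,
                                node_labels=g.node_labels)
        prof = node_profiles(g, part)
        assert np.all(prof["pc"] == 0.0)

    def test_even_four_way_split_gives_pc_three_quarters(self):
        # hub node 0 linked to one node in each of 4 modules (itself in m0)
        A = np.zeros((9, 9))
        for j in (1, 3, 5, 7):
            A[0, j] = A[j, 0] = 1.0
        # pad each module with an extra edge so every module is nonempty
        for a, b in ((1, 2), (3, 4), (5, 6), (7, 8)):
            A[a, b] = A[b, a] = 1.0
        g = ThresholdedGraph(A=A, density=0.2,
                             node_labels=[f"n{i}" for i in range(9)])
        labels = np.array([0, 0, 0, 1, 1, 2, 2, 3, 3])
        prof = node_profiles(g, ModularPartition(labels=labels, Q=0.0,
                                                 node_labels=g.node_labels))
        assert prof.loc[0, "pc"] == pytest.approx(1 - 4 * 0.25**2)  # 0.75

    def test_star_center_betweenness_ten(self):
        A = np.zeros((6, 6))
        A[0, 1:] = A[1:, 0] = 1.0
        g = ThresholdedGraph(A=A, density=0.33,
                             node_labels=[f"n{i}" for i in range(6)])
        prof = node_profiles(
            g, ModularPartition(labels=np.zeros(6, int), Q=0.0,
                                node_labels=g.node_labels))
        assert prof.loc[0, "b"] == pytest.approx(10.0)  # (n-1)(n-2)/2
        assert np.all(prof.loc[1:, "b"] == 0.0)

    @pytest.mark.parametrize("seed", [20, 21, 22])
    def test_betweenness_matches_brute_force_oracle(self, seed):
        g = random_signed_graph(8, seed=seed, p_edge=0.4)
        part = ModularPartition(labels=np.zeros(8, int), Q=0.0,
                                node_labels=g.node_labels)
        prof = node_profiles(g, part)
        np.testing.assert_allclose(prof["b"], brute_force_betweenness(g.A),
                                   atol=1e-9)

    def test_wmd_zero_when_module_degrees_identical(self):
        g = clique_pair_graph(4)
        part = ModularPartition(labels=np.array([0] * 4 + [1] * 4), Q=0.5,
                                node_labels=g.node_labels)
        prof = node_profiles(g, part)
        assert np.all(prof["z_wmd"] == 0.0)  # SD = 0 inside each clique

    def test_isolated_node_flagged_with_zero_pc(self):
        A = np.zeros((4, 4))
        A[0, 1] = A[1, 0] = 1.0
        g = ThresholdedGraph(A=A, density=0.1, node_labels=list("abcd"))
        prof = node_profiles(
            g, ModularPartition(labels=np.zeros(4, int), Q=0.0,
                                node_labels=g.node_labels))
        assert prof.loc[2, "isolated"] and prof.loc[2, "pc"] == 0.0


# ----------------------------------------------------------------------- hubs

def _null_from(degree, betweenness):
    return NullEnsemble(
        metrics={"degree": np.asarray(degree, float),
                 "betweenness": np.asarray(betweenness, float)},
        n_realizations=len(degree), seed=0,
    )


class TestClassifyHubs:
    def test_wmd_and_pc_rule_defines_connector_hub(self):
        prof = pd.DataFrame({
            "node": ["x", "y"], "module": [0, 1], "k": [5, 5], "b": [1.0, 1.0],
            "z_wmd": [1.2, 0.8], "pc": [0.50, 0.50], "isolated": [False, False],
        })
        null = _null_from(np.full((99, 2), 5.0), np.full((99, 2), 1.0))
        out = classify_hubs(prof, null)
        assert bool(out.loc[0, "hub_connector"])  # z_wmd 1.2 > 1.0, pc 0.5 > 0.45
        assert not out.loc[1, "hub_connector"]

    def test_pc_threshold_recomputable_as_mean_plus_sd(self):
        prof = pd.DataFrame({
            "node": list("abcd"), "module": [0] * 4, "k": [3] * 4, "b": [0.0] * 4,
            "z_wmd": [1.5] * 4, "pc": [0.2, 0.2, 0.2, 0.6],
            "isolated": [False] * 4,
        })
        null = _null_from(np.full((50, 4), 3.0), np.zeros((50, 4)))
        out = classify_hubs(prof, null, pc_mode="mean_plus_sd")
        thr = out.attrs["thresholds"]["pc_threshold"]
        assert thr == pytest.approx(np.mean(prof.pc) + np.std(prof.pc))
        assert out["hub_connector"].tolist() == [False, False, False, True]

    def test_exchangeable_nodes_yield_no_static_hubs(self):
        # complete graph: every shuffle keeps degree = n-1 everywhere
        k = np.full(6, 5.0)
        null = _null_from(np.tile(k, (200, 1)), np.zeros((200, 6)))
        prof = pd.DataFrame({
            "node": list("abcdef"), "module": [0] * 6, "k": k, "b": np.zeros(6),
            "z_wmd": np.zeros(6), "pc": np.zeros(6), "isolated": [False] * 6,
        })
        out = classify_hubs(prof, null)
        assert not out["hub_static"].any()
        assert not out["hub_dynamical"].any()

    def test_static_hub_rate_on_null_graphs_calibrated(self):
        """Running hub detection on graphs drawn from the null itself
        should flag no more than alpha (+2 SE) of nodes."""
        from painnet.graphs import random_equivalents

        g = random_signed_graph(20, seed=30, p_edge=0.4)
        null = random_equivalents(g, n_realizations=199, seed=31)
        alpha = 0.05
        rng = np.random.default_rng(32)
        calls = total = 0
        for _ in range(100):
            S = g.A.copy()
            iu = np.triu_indices(20, 1)
            vals = S[iu]
            rng.shuffle(vals)
            S = np.zeros_like(g.A)
            S[iu] = vals
            S = S + S.T
            gs = ThresholdedGraph(A=S, density=g.density,
                                  node_labels=g.node_labels)
            part = ModularPartition(labels=np.zeros(20, int), Q=0.0,
                                    node_labels=g.node_labels)
            out = classify_hubs(node_profiles(gs, part), null, alpha=alpha)
            calls += int(out["hub_static"].sum())
            total += 20
        rate = calls / total
        se = np.sqrt(alpha * (1 - alpha) / total)
        assert rate <= alpha + 2 * se

    def test_missing_null_rejected(self):
        prof = pd.DataFrame({"node": ["a"], "module": [0], "k": [1], "b": [0.0],
                             "z_wmd": [0.0], "pc": [0.0], "isolated": [False]})
        with pytest.raises(ValueError, match="null ensemble"):
            classify_hubs(prof, None)


# ------------------------------------------------------------------ link stats

class TestModularLinkStats:
    def test_disconnected_cliques_have_no_inter_links(self):
        g = clique_pair_graph(4)
        part = ModularPartition(labels=np.array([0] * 4 + [1] * 4), Q=0.5,
                                node_labels=g.node_labels)
        ls = modular_link_stats(g, part)
        assert ls["inter_counts"].sum() == 0
        assert ls["intra_counts"].tolist() == [6, 6]
        np.testing.assert_allclose(ls["intra_proportions"], 1.0)

    def test_complete_graph_equal_halves(self):
        A = 1.0 - np.eye(8)
        g = ThresholdedGraph(A=A, density=1.0,
                             node_labels=[f"n{i}" for i in range(8)])
        part = ModularPartition(labels=np.array([0] * 4 + [1] * 4), Q=0.0,
                                node_labels=g.node_labels)
        ls = modular_link_stats(g, part)
        assert ls["total_intra"] == 12  # 2 * C(4,2)
        assert ls["total_inter"] == 16  # 4 * 4
        assert ls["average_strength"] == pytest.approx(7.0)

    @pytest.mark.parametrize("seed", [40, 41])
    def test_intra_plus_inter_equals_edge_count(self, seed):
        g = random_signed_graph(12, seed=seed)
        part = optimize_partition(g, n_restarts=5, seed=seed)
        ls = modular_link_stats(g, part)
        assert ls["total_intra"] + ls["total_inter"] == g.edge_count


# ------------------------------------------------------- planted-partition runs

def _recover(within_r, between_r, seed, n_restarts=20):
    table = load_roi_table()
    truth = load_ground_truth_partition(table)
    gt = GroundTruth(partition=truth, within_r=within_r, between_r=between_r)
    cohort, _ = generate_cohort(table, gt, n_subjects=4, n_sessions=2,
                                preset="group2", seed=seed)
    mats = subject_condition_matrices(cohort, "pain")
    _, graph = group_graph(mats, 0.30)
    part = optimize_partition(graph, n_restarts=n_restarts, seed=seed)
    planted = labels_from_mapping(truth, graph.node_labels)
    return compare_partitions(part.labels, planted)["nmi"]


def test_recovery_degrades_as_module_contrast_shrinks():
    """Planted-partition recovery weakens monotonically over a 3-point
    grid of shrinking within-minus-between correlation gaps."""
    seeds = (60, 61, 62)
    grid = [(0.6, 0.1), (0.4, 0.25), (0.3, 0.27)]
    mean_nmi = [np.mean([_recover(w, b, s) for s in seeds]) for w, b in grid]
    assert mean_nmi[0] >= mean_nmi[1] >= mean_nmi[2]
    assert mean_nmi[0] > 0.95  # strong contrast: essentially perfect
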
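import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

import sitefid as sf


def stats_from_counts(counts: dict, ant: str, caste="worker", colony="C"):
    per_site = pd.DataFrame(
        {
            "n": pd.Series(counts, dtype=float),
            "mean_dwell": 0.0,
            "rt_restricted_mean": 0.0,
        }
    )
    per_site.index.name = "site"
    return sf.SiteStats(
        colony_id=colony, ant_id=ant, caste=caste, per_site=per_site
    )


class TestVolumeOfIntersection:
    def test_identical_distributions_give_one(self):
        assert sf.volume_of_intersection([2, 2, 1], [2, 2, 1]) == pytest.approx(1.0)
        # proportionality is enough: normalization removes scale
        assert sf.volume_of_intersection([2, 2, 1], [4, 4, 2]) == pytest.approx(1.0)

    def test_disjoint_supports_give_zero(self):
        assert sf.volume_of_intersection([1, 2, 0, 0], [0, 0, 3, 1]) == 0.0

    def test_hand_half_overlap(self):
        assert sf.volume_of_intersection([1, 1, 0], [0, 1, 1]) == pytest.approx(0.5)

    def test_all_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            sf.volume_of_intersection([0, 0], [1, 2])

    def test_symmetry_bounds_and_tv_identity(self):
        """VI is symmetric, in [0,1], and equals 1 - total variation."""
        rng = np.random.default_rng(4)
        for _ in range(50):
            a = rng.integers(0, 10, size=12).astype(float)
            b = rng.integers(0, 10, size=12).astype(float)
            if a.sum() == 0 or b.sum() == 0:
                continue
            vi = sf.volume_of_intersection(a, b)
            assert vi == pytest.approx(sf.volume_of_intersection(b, a))
            assert 0.0 <= vi <= 1.0 + 1e-12
            pa, pb = a / a.sum(), b / b.sum()
            tv = 0.5 * np.abs(pa - pb).sum()
            assert vi == pytest.approx(1.0 - tv)

    def test_mapping_inputs_align_on_site_union(self):
        vi = sf.volume_of_intersection({0: 1, 5: 1}, {5: 1, 9: 1})
        assert vi == pytest.approx(0.5)


class TestBuildNetwork:
    def test_zero_overlap_edges_dropped(self):
        s1 = stats_from_counts({0: 3}, "a")
        s2 = stats_from_counts({0: 3}, "b")
        s3 = stats_from_counts({9: 2}, "c")
        net = sf.build_network([s1, s2, s3])
        assert net.graph.number_of_edges() == 1
        assert net.graph.has_edge("a", "b")

    def test_strength_is_sum_of_incident_weights(self):
        ants = [stats_from_counts({0: 1, 1: 1}, f"a{i}") for i in range(4)]
        net = sf.build_network(ants)
        for a in net.ants:
            assert net.strength(a) == pytest.approx(3.0)

    def test_single_ant_rejected(self):
        with pytest.raises(ValueError):
            sf.build_network([stats_from_counts({0: 1}, "a")])


def planted_two_block(n_per_block=8, within=0.8, between=0.05):
    g = nx.Graph()
    ants = [f"a{i}" for i in range(2 * n_per_block)]
    for a in ants:
        g.add_node(a, caste="worker")
    for i, j in itertools.combinations(range(2 * n_per_block), 2):
        same = (i < n_per_block) == (j < n_per_block)
        g.add_edge(ants[i], ants[j], weight=within if same else between)
    return sf.OverlapNetwork(colony_id="P", graph=g), [
        set(ants[:n_per_block]),
        set(ants[n_per_block:]),
    ]


def exhaustive_best_two_partition(net):
    """Brute-force maximum-modularity bipartition (independent oracle)."""
    g = net.graph
    nodes = list(g.nodes)
    best_q, best = -np.inf, None
    for bits in range(1, 2 ** (len(nodes) - 1)):
        left = {nodes[i] for i in range(len(nodes)) if (bits >> i) & 1}
        right = set(nodes) - left
        if not right:
            continue
        q = nx.community.modularity(g, [left, right], weight="weight")
        if q > best_q:
            best_q, best = q, [left, right]
    return best, best_q


class TestCommunities:
    def test_planted_partition_recovered_and_matches_exhaustive_oracle(self):
        net, planted = planted_two_block()
        oracle, _ = exhaustive_best_two_partition(net)
        assert sorted(map(sorted, oracle)) == sorted(map(sorted, planted))
        part = sf.detect_communities(net, seed=1)
        groups = {}
        for a, c in part.membership.items():
            groups.setdefault(c, set()).add(a)
        assert sorted(map(sorted, groups.values())) == sorted(
            map(sorted, planted)
        )

    def test_modal_partition_over_seeds_is_planted(self):
        net, planted = planted_two_block()
        hits = 0
        for seed in range(20):
            part = sf.detect_communities(net, seed=seed)
            groups = {}
            for a, c in part.membership.items():
                groups.setdefault(c, set()).add(a)
            if sorted(map(sorted, groups.values())) == sorted(
                map(sorted, planted)
            ):
                hits += 1
        assert hits > 10

    def test_fixed_seed_is_reproducible(self):
        net, _ = planted_two_block()
        a = sf.detect_communities(net, seed=3)
        b = sf.detect_communities(net, seed=3)
        assert a.membership == b.membership

    def test_disconnected_cliques_form_two_communities(self):
        g = nx.Graph()
        for block, names in enumerate((["a", "b", "c"], ["x", "y", "z"])):
            for u in names:
                g.add_node(u, caste="worker")
            for u, v in itertools.combinations(names, 2):
                g.add_edge(u, v, weight=1.0)
        net = sf.OverlapNetwork(colony_id="D", graph=g)
        part = sf.detect_communities(net, seed=0)
        assert part.n_communities == 2

    def test_uniform_complete_graph_is_unpartitioned(self):
        g = nx.complete_graph(8)
        nx.set_edge_attributes(g, 1.0, "weight")
        g = nx.relabel_nodes(g, {i: f"a{i}" for i in range(8)})
        for a in g.nodes:
            g.nodes[a]["caste"] = "worker"
        net = sf.OverlapNetwork(colony_id="U", graph=g)
        part = sf.detect_communities(net, seed=0)
        assert not part.partitioned

    def test_greedy_fallback_agrees_on_planted_network(self):
        net, planted = planted_two_block()
        part = sf.detect_communities(net, seed=0, method="greedy")
        groups = {}
        for a, c in part.membership.items():
            groups.setdefault(c, set()).add(a)
        assert sorted(map(sorted, groups.values())) == sorted(map(sorted, planted))


class TestLabelAndMap:
    def _colony(self):
        queen = stats_from_counts({0: 5, 1: 3}, "Q", caste="queen")
        w1 = stats_from_counts({0: 2, 1: 4}, "w1")
        w2 = stats_from_counts({8: 2, 9: 4}, "w2")
        w3 = stats_from_counts({8: 4, 9: 2}, "w3")
        return [queen, w1, w2, w3]

    def test_queen_community_labelled_nurse(self):
        stats = self._colony()
        net = sf.build_network(stats)
        part = sf.detect_communities(net, seed=0)
        part, cmap = sf.label_and_map(part, stats)
        assert part.label_of("Q") == "nurse"
        assert part.label_of("w2") == "other"

    def test_member_mean_visits(self):
        stats = self._colony()
        net = sf.build_network(stats)
        part = sf.detect_communities(net, seed=0)
        part, cmap = sf.label_and_map(part, stats)
        nurse = cmap[cmap["label"] == "nurse"].set_index("site")
        assert nurse.at[0, "mean_visits"] == pytest.approx((5 + 2) / 2)

    def test_consensus_counts_from_site_tests(self):
        stats = self._colony()
        net = sf.build_network(stats)
        part = sf.detect_communities(net, seed=0)
        tests = pd.DataFrame(
            [
                {"colony": "C", "ant": "Q", "site": 0, "metric": "n",
                 "classification": "attracted"},
                {"colony": "C", "ant": "w1", "site": 0, "metric": "n",
                 "classification": "attracted"},
                {"colony": "C", "ant": "w1", "site": 1, "metric": "n",
                 "classification": "neutral"},
            ]
        )
        part, cmap = sf.label_and_map(part, stats, tests)
        nurse = cmap[cmap["label"] == "nurse"].set_index("site")
        assert nurse.at[0, "consensus_count"] == 2
        assert nurse.at[1, "consensus_count"] == 0

    def test_queenless_colony_warns_and_indexes_labels(self):
        stats = [
            stats_from_counts({0: 5}, "w1"),
            stats_from_counts({0: 4}, "w2"),
            stats_from_counts({9: 4}, "w3"),
            stats_from_counts({9: 5}, "w4"),
        ]
        net = sf.build_network(stats)
        part = sf.detect_communities(net, seed=0)
        if part.partitioned:
            with pytest.warns(UserWarning, match="no queen"):
                part, _ = sf.label_and_map(part, stats)
            assert all(l.startswith("community_") for l in part.labels.values())
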
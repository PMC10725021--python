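"""Centrality/bridge indices and pathways against exhaustive oracles."""

import itertools

import numpy as np
import pytest

from psychnet.data import NetworkModel
from psychnet.exceptions import SpecError
from psychnet.metrics import centrality, pathway_subnetwork, select_domains, shortest_path

from conftest import random_network


def brute_force_indices(net):
    """Independent summation oracle for all four centrality indices."""
    out = {}
    for i, v in enumerate(net.nodes):
        s = ei = bs = bei = 0.0
        for j, u in enumerate(net.nodes):
            if i == j or net.weights[i, j] == 0:
                continue
            w = net.weights[i, j]
            contrib = w if net.sign_defined[i, j] else abs(w)
            s += abs(w)
            ei += contrib
            if net.communities[v] != net.communities[u]:
                bs += abs(w)
                bei += contrib
        out[v] = (s, ei, bs, bei)
    return out


def brute_force_shortest(net, source, target, metric="weighted"):
    """Exhaustive enumeration over all simple paths."""
    idx = {v: i for i, v in enumerate(net.nodes)}
    best = None
    others = [v for v in net.nodes if v not in (source, target)]
    for r in range(len(others) + 1):
        for mid in itertools.permutations(others, r):
            path = [source, *mid, target]
            dist = 0.0
            ok = True
            for a, b in zip(path, path[1:]):
                w = net.weights[idx[a], idx[b]]
                if w == 0:
                    ok = False
                    break
                dist += 1.0 if metric == "hops" else 1.0 / abs(w)
            if ok and (best is None or dist < best[0] - 1e-12
                       or (abs(dist - best[0]) <= 1e-12 and path < best[1])):
                best = (dist, path)
    return best


def two_community_net(weights, communities):
    nodes = sorted(communities)
    p = len(nodes)
    w = np.zeros((p, p))
    for (a, b), v in weights.items():
        i, j = nodes.index(a), nodes.index(b)
        w[i, j] = w[j, i] = v
    return NetworkModel(nodes=nodes, communities=communities, weights=w,
                        sign_defined=np.ones((p, p), dtype=bool))


class TestCentrality:
    def test_definitional_example(self):
        net = two_community_net({("A", "B"): 0.3, ("A", "C"): -0.2},
                                {"A": "c1", "B": "c1", "C": "c1"})
        tab = centrality(net)
        assert tab.loc["A", "strength"] == pytest.approx(0.5)
        assert tab.loc["A", "expected_influence"] == pytest.approx(0.1)

    def test_bridge_decomposition_example(self):
        net = two_community_net({("A", "B"): 0.3, ("A", "C"): -0.2},
                                {"A": "c1", "B": "c1", "C": "c2"})
        tab = centrality(net)
        assert tab.loc["A", "bridge_strength"] == pytest.approx(0.2)
        assert tab.loc["A", "bridge_ei"] == pytest.approx(-0.2)
        within = tab.loc["A", "strength"] - tab.loc["A", "bridge_strength"]
        assert within == pytest.approx(0.3)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(100):
            net = random_network(rng, p=int(rng.integers(3, 8)))
            tab = centrality(net)
            oracle = brute_force_indices(net)
            for v, (s, ei, bs, bei) in oracle.items():
                assert tab.loc[v, "strength"] == pytest.approx(s, abs=1e-12)
                assert tab.loc[v, "expected_influence"] == pytest.approx(ei, abs=1e-12)
                assert tab.loc[v, "bridge_strength"] == pytest.approx(bs, abs=1e-12)
                assert tab.loc[v, "bridge_ei"] == pytest.approx(bei, abs=1e-12)

    def test_all_positive_network_strength_equals_ei(self, rng):
        net = random_network(rng, p=6, signed=False)
        tab = centrality(net)
        np.testing.assert_allclose(tab["strength"], tab["expected_influence"], atol=1e-12)
        np.testing.assert_allclose(tab["bridge_strength"], tab["bridge_ei"], atol=1e-12)

    def test_node_permutation_invariance(self, rng):
        net = random_network(rng, p=6)
        perm = list(rng.permutation(net.p))
        permuted = NetworkModel(
            nodes=[net.nodes[i] for i in perm],
            communities=net.communities,
            weights=net.weights[np.ix_(perm, perm)],
            sign_defined=net.sign_defined[np.ix_(perm, perm)],
        )
        a = centrality(net).sort_index()
        b = centrality(permuted).sort_index()
        np.testing.assert_allclose(a[["strength", "expected_influence"]].to_numpy(),
                                   b[["strength", "expected_influence"]].to_numpy(),
                                   atol=1e-12)

    def test_single_community_has_zero_bridge(self, rng):
        net = random_network(rng, p=5, communities={f"N{i+1}": "only" for i in range(5)})
        tab = centrality(net)
        assert (tab["bridge_strength"] == 0).all()
        assert (tab["bridge_ei"] == 0).all()


class TestShortestPath:
    def test_two_node_network(self):
        net = two_community_net({("A", "B"): 0.25}, {"A": "x", "B": "x"})
        res = shortest_path(net, "A", "B")
        assert res.path == ["A", "B"]
        assert res.total_distance == pytest.approx(4.0)

    def test_strong_detour_beats_weak_direct_edge(self):
        net = two_community_net(
            {("A", "B"): 0.1, ("A", "Z"): 0.4, ("Z", "B"): 0.4},
            {"A": "x", "B": "x", "Z": "x"},
        )
        res = shortest_path(net, "A", "B")
        assert res.path == ["A", "Z", "B"]
        assert res.total_distance == pytest.approx(5.0)

    def test_hops_metric_prefers_direct_edge(self):
        net = two_community_net(
            {("A", "B"): 0.1, ("A", "Z"): 0.4, ("Z", "B"): 0.4},
            {"A": "x", "B": "x", "Z": "x"},
        )
        res = shortest_path(net, "A", "B", metric="hops")
        assert res.path == ["A", "B"]

    def test_disconnected_pair(self):
        net = two_community_net({("A", "B"): 0.5}, {"A": "x", "B": "x", "C": "y"})
        res = shortest_path(net, "A", "C")
        assert not res.exists
        assert res.total_distance == np.inf

    def test_matches_enumeration_oracle(self, rng):
        for _ in range(60):
            net = random_network(rng, p=7, density=0.45)
            nodes = net.nodes
            s, t = nodes[0], nodes[-1]
            res = shortest_path(net, s, t)
            oracle = brute_force_shortest(net, s, t)
            if oracle is None:
                assert not res.exists
            else:
                assert res.exists
                assert res.total_distance == pytest.approx(oracle[0], abs=1e-9)
                assert res.path == oracle[1]

    def test_unknown_node_fatal(self):
        net = two_community_net({("A", "B"): 0.5}, {"A": "x", "B": "x"})
        with pytest.raises(SpecError):
            shortest_path(net, "A", "Q")
        with pytest.raises(SpecError):
            shortest_path(net, "A", "A")


class TestPathwaySubnetwork:
    def test_star_hub_is_unique_intermediary(self):
        weights = {("S1", "H"): 0.5, ("S2", "H"): 0.5, ("H", "T1"): 0.5, ("H", "T2"): 0.5}
        comms = {"S1": "f", "S2": "f", "H": "b", "T1": "s", "T2": "s"}
        net = two_community_net(weights, comms)
        res = pathway_subnetwork(net, ["S1", "S2"], ["T1", "T2"])
        assert res.intermediaries == {"H"}
        assert all(len(r.path) == 3 for r in res.pathways)

    def test_fully_disconnected_domains(self):
        weights = {("S1", "S2"): 0.4, ("T1", "T2"): 0.4}
        comms = {"S1": "f", "S2": "f", "T1": "s", "T2": "s"}
        net = two_community_net(weights, comms)
        res = pathway_subnetwork(net, ["S1", "S2"], ["T1", "T2"])
        assert res.edges == set()
        assert all(not r.exists for r in res.pathways)

    def test_set_validation(self):
        net = two_community_net({("A", "B"): 0.5}, {"A": "x", "B": "x"})
        with pytest.raises(SpecError):
            pathway_subnetwork(net, ["A"], ["A"])
        with pytest.raises(SpecError):
            pathway_subnetwork(net, [], ["A"])


class TestSelectDomains:
    @staticmethod
    def _net(cross_weight, domain):
        comms = {"s1": "ISI", "s2": "ISI", "f1": domain, "f2": domain}
        weights = {("s1", "s2"): 0.4, ("f1", "f2"): 0.4}
        if cross_weight:
            weights[("f1", "s1")] = cross_weight
        return two_community_net(weights, comms)

    def test_zero_edge_domain_excluded(self):
        nets = {"CTQ": self._net(0.0, "CTQ"), "EPQ": self._net(0.2, "EPQ")}
        assert select_domains(nets, "ISI") == ["EPQ"]

    def test_single_touch_retained(self):
        nets = {"SSRS": self._net(-0.05, "SSRS")}
        assert select_domains(nets, "ISI") == ["SSRS"]

    def test_three_of_four_retained(self):
        nets = {
            "EPQ": self._net(0.2, "EPQ"),
            "IRCDS": self._net(0.1, "IRCDS"),
            "CTQ": self._net(0.0, "CTQ"),
            "SSRS": self._net(-0.1, "SSRS"),
        }
        assert select_domains(nets, "ISI") == ["EPQ", "IRCDS", "SSRS"]
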
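"""Centralities, path statistics and the power-law degree-distribution fit."""

from __future__ import annotations

import networkx as nx
import numpy as np
import pytest

from conftest import random_network
from gametenet import (
    ValidationError,
    betweenness,
    closeness,
    degrees,
    fit_power_law,
    generate_powerlaw_network,
    new_network,
    path_stats,
)
from helpers_oracles import betweenness_oracle, closeness_oracle, ols_loglog_oracle


def complete(n):
    return new_network(edges=[(f"P{i}", f"P{j}") for i in range(n) for j in range(i + 1, n)])


class TestDegrees:
    def test_complete_and_star(self):
        assert set(degrees(complete(4)).values()) == {3}
        star = new_network(edges=[("hub", f"L{i}") for i in range(5)])
        d = degrees(star)
        assert d["hub"] == 5 and all(d[f"L{i}"] == 1 for i in range(5))

    def test_handshake_identity(self, rng):
        net = random_network(rng, n_max=30)
        assert sum(degrees(net).values()) == 2 * net.number_of_edges()

    def test_isolated_node_zero(self):
        assert degrees(new_network(["A"]))["A"] == 0


class TestBetweenness:
    def test_path_and_star(self):
        bc = betweenness(new_network(edges=[("A", "B"), ("B", "C")]))
        assert bc == pytest.approx({"A": 0.0, "B": 1.0, "C": 0.0})
        star = new_network(edges=[("hub", f"L{i}") for i in range(6)])
        bc = betweenness(star)
        assert bc["hub"] == pytest.approx(1.0)
        assert all(bc[f"L{i}"] == 0.0 for i in range(6))

    def test_complete_graph_zero(self):
        assert set(betweenness(complete(5)).values()) == {0.0}

    def test_five_cycle_matches_enumeration(self):
        cyc = new_network(edges=[(f"P{i}", f"P{(i + 1) % 5}") for i in range(5)])
        bc = betweenness(cyc)
        oracle = betweenness_oracle(cyc)
        for v in cyc.nodes:
            assert bc[v] == pytest.approx(oracle[v], abs=1e-9)
        assert len(set(round(x, 9) for x in bc.values())) == 1

    def test_tiny_networks_all_zero(self):
        assert betweenness(new_network(edges=[("A", "B")])) == {"A": 0.0, "B": 0.0}


class TestCloseness:
    def test_complete_graph_is_one(self):
        assert set(closeness(complete(4)).values()) == {1.0}

    def test_path_values(self):
        cc = closeness(new_network(edges=[("A", "B"), ("B", "C")]))
        assert cc == pytest.approx({"A": 2 / 3, "B": 1.0, "C": 2 / 3})

    def test_isolated_node_zero(self):
        net = new_network(["A", "B", "C"], [("A", "B")])
        assert closeness(net)["C"] == 0.0


class TestOracleEquivalence:
    def test_centralities_match_bfs_oracles(self, rng):
        for _ in range(15):
            net = random_network(rng, n_max=40)
            bc, bco = betweenness(net), betweenness_oracle(net)
            cc, cco = closeness(net), closeness_oracle(net)
            for v in net.nodes:
                assert bc[v] == pytest.approx(bco[v], abs=1e-9)
                assert cc[v] == pytest.approx(cco[v], abs=1e-9)

    def test_metrics_invariant_under_relabeling(self, rng):
        net = random_network(rng, n_max=30)
        perm = list(net.nodes)
        rng.shuffle(perm)
        mapping = dict(zip(net.nodes, perm))
        relabeled = nx.relabel_nodes(net, mapping)
        bc, bc2 = betweenness(net), betweenness(relabeled)
        cc, cc2 = closeness(net), closeness(relabeled)
        for v in net.nodes:
            assert bc2[mapping[v]] == pytest.approx(bc[v], abs=1e-12)
            assert cc2[mapping[v]] == pytest.approx(cc[v], abs=1e-12)

    def test_adding_intra_component_edge_never_decreases_closeness(self, rng):
        # the monotonicity statement holds when the reachable set is
        # unchanged; an edge that bridges two components can legitimately
        # lower an endpoint's component-restricted closeness by making
        # distant nodes reachable
        for _ in range(10):
            net = random_network(rng, n_max=20, p=0.1)
            comps = list(nx.connected_components(net))
            non_edges = [
                (a, b)
                for comp in comps
                for a in sorted(comp)
                for b in sorted(comp)
                if a < b and not net.has_edge(a, b)
            ]
            if not non_edges:
                continue
            a, b = non_edges[int(rng.integers(len(non_edges)))]
            before = closeness(net)
            net.add_edge(a, b)
            after = closeness(net)
            assert after[a] >= before[a] - 1e-12
            assert after[b] >= before[b] - 1e-12


class TestPathStats:
    def test_complete_graph(self):
        stats = path_stats(complete(5))
        assert stats.histogram == {1: 10}
        assert stats.characteristic_path_length == 1.0

    def test_path_on_four_nodes(self):
        net = new_network(edges=[("A", "B"), ("B", "C"), ("C", "D")])
        stats = path_stats(net)
        assert stats.histogram == {1: 3, 2: 2, 3: 1}
        assert stats.characteristic_path_length == pytest.approx(10 / 6)

    def test_unreachable_pairs_excluded(self):
        net = new_network(edges=[("A", "B"), ("C", "D")])
        stats = path_stats(net)
        assert stats.histogram == {1: 2}
        assert stats.characteristic_path_length == 1.0

    def test_no_connected_pairs_is_explicitly_undefined(self):
        stats = path_stats(new_network(["A", "B"]))
        assert stats.histogram == {}
        assert stats.characteristic_path_length is None

    def test_total_matches_component_arithmetic(self, rng):
        for _ in range(10):
            net = random_network(rng, n_max=40, p=0.08)
            expected = sum(
                len(comp) * (len(comp) - 1) // 2
                for comp in nx.connected_components(net)
            )
            assert path_stats(net).n_pairs == expected


class TestPowerLawFit:
    def test_exact_inverse_square_distribution(self):
        deg: dict[str, int] = {}
        i = 0
        for k, count in [(1, 64), (2, 16), (4, 4), (8, 1)]:
            for _ in range(count):
                deg[f"P{i}"] = k
                i += 1
        fit = fit_power_law(deg)
        assert fit.exponent == pytest.approx(-2.0, abs=1e-9)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-9)
        assert fit.n_points == 4

    def test_flat_distribution_has_zero_slope(self):
        deg = {f"P{i}": k for k in (1, 2, 3) for i in range(k * 10, k * 10 + 5)}
        fit = fit_power_law(deg)
        assert fit.exponent == pytest.approx(0.0, abs=1e-12)

    def test_matches_closed_form_ols(self, rng):
        for _ in range(20):
            n = int(rng.integers(30, 200))
            deg = {f"P{i}": int(rng.integers(1, 15)) for i in range(n)}
            ks, counts = np.unique(list(deg.values()), return_counts=True)
            if len(ks) < 2:
                continue
            fit = fit_power_law(deg)
            slope, intercept, r2 = ols_loglog_oracle(ks, counts / counts.sum())
            assert fit.exponent == pytest.approx(slope, abs=1e-9)
            assert fit.intercept == pytest.approx(intercept, abs=1e-9)
            assert fit.r_squared == pytest.approx(r2, abs=1e-9)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValidationError):
            fit_power_law({"A": 3, "B": 3})
        with pytest.raises(ValidationError):
            fit_power_law({"A": 0})

    def test_preferential_attachment_is_scale_free_like(self):
        net = generate_powerlaw_network(1500, 3, seed=42)
        fit = fit_power_law(degrees(net))
        assert fit.exponent < -1.0
        assert fit.r_squared > 0.6
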
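"""Bipartite construction, SEI/SPOI/SPOR, projection and summaries."""

from __future__ import annotations

import math

import networkx as nx
import numpy as np
import pytest

import spornet as sn
from spornet.network import (
    build_bipartite,
    distribution_stats,
    encounter_sets,
    project,
    sei,
    shared_counts,
    spoi,
    spor,
    summarize,
    threshold_sweep,
)


class TestBipartite:
    def test_toy_involvement_edges(self, toy_events, toy_encounters):
        bip = build_bipartite(toy_events, toy_encounters)
        n_edges = sum(len(e) for e in bip.involvement.values())
        assert n_edges == 4  # five actions collapse to four involvement edges
        assert bip.involvement["P4"]["E2"] == 2  # provider 4 acted twice
        assert bip.involvement["P1"]["E1"] == 1

    def test_no_events_gives_empty_network(self, toy_encounters):
        bip = build_bipartite([], toy_encounters)
        assert bip.n_providers == 0
        assert bip.n_encounters == 2

    def test_unknown_encounter_rejected(self, toy_encounters):
        with pytest.raises(ValueError, match="EX"):
            build_bipartite([sn.ProviderEvent("P1", "EX")], toy_encounters)

    def test_networkx_view_is_bipartite(self, toy_events, toy_encounters):
        g = build_bipartite(toy_events, toy_encounters).to_networkx()
        assert g.number_of_edges() == 4
        assert g.edges["provider:P4", "encounter:E2"]["action_count"] == 2


class TestEncounterSets:
    def test_restricted_to_analysis_encounters(self):
        bip = sn.BipartiteNetwork(
            involvement={"P1": {"E1": 1, "E2": 1, "E3": 1}, "P2": {"E3": 2}},
            encounters={},
        )
        sets = encounter_sets(bip, ["E1", "E2"])
        assert sets["P1"] == {"E1", "E2"}
        assert "P2" not in sets  # all encounters lack outcomes -> excluded

    def test_toy_covers_both_encounters(self, toy_events, toy_encounters):
        bip = build_bipartite(toy_events, toy_encounters)
        sets = encounter_sets(bip, ["E1", "E2"])
        assert set().union(*sets.values()) == {"E1", "E2"}


class TestIndices:
    def test_sei_identity(self):
        a = frozenset(f"E{i}" for i in range(5))
        assert sei(a, a) == 1.0

    def test_sei_direct_count(self):
        assert sei({"e1", "e2", "e3"}, {"e3", "e4"}) == 0.25

    def test_sei_disjoint_is_contract_violation(self):
        with pytest.raises(ValueError):
            sei({"e1"}, {"e2"})

    def test_spoi_constant_r_collapses_to_sei(self):
        a, b = {"e1", "e2", "e3"}, {"e3", "e4"}
        r = {e: 0.7 for e in a | b}
        assert spoi(a, b, r) == pytest.approx(sei(a, b), abs=1e-12)

    def test_spoi_direct_sum(self):
        r = {"e1": 1.0, "e2": 0.5, "e3": 0.5}
        assert spoi({"e1", "e2"}, {"e1", "e3"}, r) == 0.5

    def test_spoi_zero_mass_raises(self):
        r = {"e1": 0.0, "e2": 0.0}
        with pytest.raises(ZeroDivisionError):
            spoi({"e1"}, {"e1", "e2"}, r)

    def test_spor_division_and_guard(self):
        assert spor(0.25, 0.5) == 2.0
        with pytest.raises(ValueError):
            spor(0.0, 0.5)

    def test_exclusive_pair_spor_is_exactly_one(self):
        rng = np.random.default_rng(0)
        a = frozenset(f"E{i}" for i in range(6))
        r = {e: float(v) for e, v in zip(sorted(a), rng.uniform(0.2, 0.9, 6))}
        assert spor(sei(a, a), spoi(a, a, r)) == 1.0

    def test_symmetry_and_bound_random(self):
        rng = np.random.default_rng(1)
        universe = [f"E{i}" for i in range(40)]
        for _ in range(200):
            a = frozenset(rng.choice(universe, rng.integers(1, 30), replace=False))
            b = frozenset(rng.choice(universe, rng.integers(1, 30), replace=False))
            if not a & b:
                continue
            r = {e: float(rng.uniform(0.01, 1)) for e in universe}
            s, q = sei(a, b), spoi(a, b, r)
            assert s == sei(b, a)
            assert q == spoi(b, a, r)
            assert s <= 1 and q <= 1
            assert spor(s, q) <= 1 / s + 1e-12

    def test_oracle_equivalence_brute_force(self):
        # independent brute-force set arithmetic, element by element
        def brute_sei(a, b):
            inter = sum(1 for x in a if x in b)
            union = len(set(list(a) + list(b)))
            return inter / union

        def brute_spoi(a, b, r):
            num = sum(r[x] for x in sorted(x for x in a if x in b))
            den = sum(r[x] for x in sorted(set(list(a) + list(b))))
            return num / den

        rng = np.random.default_rng(42)
        universe = [f"E{i}" for i in range(60)]
        checked = 0
        while checked < 1000:
            a = frozenset(rng.choice(universe, rng.integers(1, 31), replace=False))
            b = frozenset(rng.choice(universe, rng.integers(1, 31), replace=False))
            if not a & b:
                continue
            r = {e: float(rng.uniform(0.0, 1.0)) for e in universe}
            assert sei(a, b) == brute_sei(a, b)
            assert spoi(a, b, r) == pytest.approx(brute_spoi(a, b, r), rel=1e-12)
            checked += 1


class TestProjection:
    @staticmethod
    def bip_with_shared(n_shared, extra_a=2, extra_b=2):
        """Two providers sharing n_shared encounters plus private ones."""
        shared = {f"S{i}": 1 for i in range(n_shared)}
        inv = {
            "PA": {**shared, **{f"A{i}": 1 for i in range(extra_a)}},
            "PB": {**shared, **{f"B{i}": 1 for i in range(extra_b)}},
        }
        encs = {}
        for encs_of in inv.values():
            for eid in encs_of:
                encs[eid] = sn.EncounterRecord(eid, 1, {})
        return sn.BipartiteNetwork(involvement=inv, encounters=encs)

    def r_for(self, bip):
        rng = np.random.default_rng(9)
        return {eid: float(rng.uniform(0.2, 0.9)) for eid in bip.encounters}

    def test_boundary_at_threshold(self):
        bip = self.bip_with_shared(6)
        net = project(bip, self.r_for(bip), min_shared=6)
        assert net.number_of_edges() == 1
        data = net.edges["PA", "PB"]
        assert data["shared_count"] == 6
        assert data["spor"] == pytest.approx(data["spoi"] / data["sei"])

    def test_below_threshold_excluded(self):
        bip = self.bip_with_shared(5)
        net = project(bip, self.r_for(bip), min_shared=6)
        assert net.number_of_edges() == 0
        assert net.number_of_nodes() == 0  # isolated providers dropped

    def test_min_shared_must_be_at_least_two(self):
        bip = self.bip_with_shared(3)
        with pytest.raises(ValueError):
            project(bip, self.r_for(bip), min_shared=1)

    def test_monotone_sparsification(self, small_null_study):
        _, bipartite, _, r = small_null_study
        nets = [project(bipartite, r, t) for t in (2, 4, 6, 8, 10)]
        nodes = [n.number_of_nodes() for n in nets]
        edges = [n.number_of_edges() for n in nets]
        assert nodes == sorted(nodes, reverse=True)
        assert edges == sorted(edges, reverse=True)
        assert edges[-1] > 0  # sweep reaches threshold 10 with content

    def test_shared_counts_only_coincident_pairs(self):
        sets = {"A": frozenset({"e1"}), "B": frozenset({"e1"}), "C": frozenset({"e2"})}
        counts = shared_counts(sets)
        assert counts == {("A", "B"): 1}


class TestSummaries:
    def test_triangle(self):
        g = nx.complete_graph(3)
        s = summarize(g)
        assert s.density == 1.0
        assert s.mean_degree == 2.0
        assert s.diameter == 1

    def test_path_of_three(self):
        g = nx.path_graph(3)
        s = summarize(g)
        assert s.diameter == 2
        assert s.mean_clustering == 0.0

    def test_star_of_five_leaves(self):
        s = summarize(nx.star_graph(5))
        assert s.mean_degree == pytest.approx(10 / 6)

    def test_disconnected_uses_largest_component(self):
        g = nx.path_graph(4)
        g.add_edge("x", "y")
        s = summarize(g)
        assert s.diameter == 3  # from the 4-node path, not the dyad

    def test_empty_network_errors(self):
        with pytest.raises(ValueError):
            summarize(nx.Graph())


class TestThresholdSweep:
    def test_single_edge_network(self):
        bip = TestProjection.bip_with_shared(6)
        rng = np.random.default_rng(2)
        r = {eid: float(rng.uniform(0.3, 0.9)) for eid in bip.encounters}
        (stats,) = threshold_sweep(bip, r, [6])
        net = project(bip, r, 6)
        assert stats.n_edges == 1
        assert stats.mean == pytest.approx(net.edges["PA", "PB"]["spor"])
        assert stats.sd == 0.0

    def test_empty_threshold_gives_zero_counts_nan_stats(self):
        bip = TestProjection.bip_with_shared(3)
        rng = np.random.default_rng(2)
        r = {eid: float(rng.uniform(0.3, 0.9)) for eid in bip.encounters}
        (stats,) = threshold_sweep(bip, r, [8])
        assert stats.n_edges == 0 and stats.n_providers == 0
        assert math.isnan(stats.mean) and math.isnan(stats.p95)

    def test_invalid_thresholds(self, small_null_study):
        _, bipartite, _, r = small_null_study
        with pytest.raises(ValueError):
            threshold_sweep(bipartite, r, [])
        with pytest.raises(ValueError):
            threshold_sweep(bipartite, r, [1, 6])

    def test_percentiles_match_sorted_array_oracle(self):
        # linear interpolation between order statistics, checked against a
        # hand-rolled oracle on 100 random SPOR samples
        def oracle(values, q):
            xs = sorted(values)
            h = (len(xs) - 1) * q / 100.0
            lo = math.floor(h)
            hi = min(lo + 1, len(xs) - 1)
            return xs[lo] + (h - lo) * (xs[hi] - xs[lo])

        rng = np.random.default_rng(8)
        for _ in range(100):
            spors = rng.lognormal(0, 0.3, size=int(rng.integers(2, 40)))
            g = nx.Graph()
            for i, s in enumerate(spors):
                g.add_edge(f"a{i}", f"b{i}", spor=float(s))
            stats = distribution_stats(g, threshold=6)
            assert stats.p5 <= stats.p10 <= stats.p90 <= stats.p95
            for q, got in ((5, stats.p5), (10, stats.p10), (90, stats.p90), (95, stats.p95)):
                assert got == pytest.approx(oracle(spors, q), rel=1e-9)
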
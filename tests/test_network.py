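"""Molecular network construction and edge-pruning rules."""

import itertools

import networkx as nx
import numpy as np
import pytest

from cocomet.network import (
    NetworkConfig,
    build_network,
    cap_family_size,
    drop_singletons,
    families,
    library_search,
    mutual_topk_filter,
)
from cocomet.spectra import ToleranceConfig, filter_spectrum, modified_cosine

from conftest import apply_edge_rules_brute_force, make_spectrum, random_spectrum


def graph_from_scores(scores: dict, nodes=None, n_matched: int = 10) -> nx.Graph:
    g = nx.Graph()
    if nodes:
        g.add_nodes_from(nodes)
    for (a, b), s in scores.items():
        g.add_edge(a, b, score=s, n_matched=n_matched)
    return g


class TestMutualTopK:
    def test_k1_triangle_keeps_best_edge_only(self):
        g = graph_from_scores({("A", "B"): 0.9, ("B", "C"): 0.8, ("A", "C"): 0.75})
        out = mutual_topk_filter(g, k=1)
        assert set(map(frozenset, out.edges)) == {frozenset({"A", "B"})}
        assert set(out.nodes) == {"A", "B", "C"}

    def test_low_degree_network_unchanged(self):
        g = graph_from_scores({("A", "B"): 0.9, ("C", "D"): 0.8})
        out = mutual_topk_filter(g, k=2)
        assert set(out.edges) == set(g.edges)

    def test_star_loses_centres_weakest_edge(self):
        k = 3
        scores = {("Z", f"L{i}"): 0.9 - 0.01 * i for i in range(k + 1)}
        out = mutual_topk_filter(graph_from_scores(scores), k=k)
        lost = frozenset({"Z", f"L{k}"})  # the centre's lowest-scoring edge
        assert set(map(frozenset, out.edges)) == set(map(frozenset, scores)) - {lost}


class TestCapFamilySize:
    def test_small_components_unchanged(self):
        g = graph_from_scores({("A", "B"): 0.9, ("B", "C"): 0.8})
        assert set(cap_family_size(g, 3).edges) == set(g.edges)

    def test_path_split_at_weakest_edge(self):
        g = graph_from_scores(
            {("A", "B"): 0.9, ("B", "C"): 0.8, ("C", "D"): 0.95, ("D", "E"): 0.85}
        )
        out = cap_family_size(g, 3)
        assert frozenset({"B", "C"}) not in set(map(frozenset, out.edges))
        assert {frozenset(c) for c in nx.connected_components(out)} == {
            frozenset({"A", "B"}),
            frozenset({"C", "D", "E"}),
        }

    def test_uniform_k4_tie_broken_by_node_ids(self):
        scores = {e: 0.8 for e in itertools.combinations("ABCD", 2)}
        out1 = cap_family_size(graph_from_scores(scores), 2)
        out2 = cap_family_size(graph_from_scores(dict(reversed(list(scores.items())))), 2)
        assert set(map(frozenset, out1.edges)) == set(map(frozenset, out2.edges))
        assert all(len(c) <= 2 for c in nx.connected_components(out1))

    def test_never_removes_nodes(self):
        scores = {e: 0.8 for e in itertools.combinations(range(10), 2)}
        out = cap_family_size(graph_from_scores(scores), 3)
        assert set(out.nodes) == set(range(10))


class TestDropSingletons:
    def test_isolated_node_removed(self):
        g = graph_from_scores({("A", "B"): 0.9}, nodes=["A", "B", "C"])
        assert set(drop_singletons(g).nodes) == {"A", "B"}

    def test_connected_network_unchanged(self):
        g = graph_from_scores({("A", "B"): 0.9, ("B", "C"): 0.8})
        assert set(drop_singletons(g).nodes) == {"A", "B", "C"}

    def test_all_singletons_empty_display(self):
        g = nx.Graph()
        g.add_nodes_from("ABC")
        assert len(drop_singletons(g)) == 0


class TestBuildNetwork:
    def test_identical_pair_connected(self):
        rng = np.random.default_rng(3)
        peaks = [(60.0 + 20 * i, float(rng.uniform(10, 90))) for i in range(8)]
        a = make_spectrum(peaks, fid="a")
        b = make_spectrum(peaks, fid="b")
        g = build_network([a, b])
        assert g.has_edge("a", "b")
        assert g.edges["a", "b"]["score"] == pytest.approx(1.0, abs=1e-9)

    def test_too_few_shared_peaks_no_edge(self):
        # perfect cosine on 3 shared peaks still fails min_matched
        peaks = [(60.0, 5.0), (80.0, 7.0), (120.0, 9.0)]
        g = build_network([make_spectrum(peaks, fid="a"), make_spectrum(peaks, fid="b")])
        assert g.number_of_edges() == 0

    def test_single_spectrum_gives_node_only_network(self):
        g = build_network([make_spectrum([(60.0, 5.0)], fid="a")])
        assert set(g.nodes) == {"a"} and g.number_of_edges() == 0

    def test_mixed_polarity_rejected(self):
        a = make_spectrum([(60.0, 5.0)], fid="a", polarity="positive")
        b = make_spectrum([(60.0, 5.0)], fid="b", polarity="negative")
        with pytest.raises(ValueError, match="polarity"):
            build_network([a, b])

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_equals_sequential_brute_force_rules(self, seed):
        """Full build == independent threshold -> mutual-k -> cap pipeline
        on the pairwise modified-cosine table (tight config so every rule
        actually fires)."""
        rng = np.random.default_rng(seed)
        spectra = [
            filter_spectrum(random_spectrum(rng, 8, f"s{i:02d}", grid=True, precursor=400.0))
            for i in range(15)
        ]
        cfg = NetworkConfig(score_threshold=0.1, min_matched=1, mutual_k=2, max_family_size=4)
        built = build_network(spectra, cfg)

        scores, nm = {}, {}
        for a, b in itertools.combinations(spectra, 2):
            r = modified_cosine(a, b)
            key = frozenset({a.feature_id, b.feature_id})
            scores[key], nm[key] = r.score, r.n_matched
        expect = apply_edge_rules_brute_force(
            [s.feature_id for s in spectra], scores, nm, cfg
        )
        assert set(map(frozenset, built.edges)) == expect

    def test_order_invariant(self, default_dataset):
        _, pos, _, _, _ = default_dataset
        filtered = [filter_spectrum(s) for s in pos]
        g1 = build_network(filtered)
        g2 = build_network(list(reversed(filtered)))
        assert set(map(frozenset, g1.edges)) == set(map(frozenset, g2.edges))

    def test_recovers_planted_families(self, default_dataset):
        _, pos, _, _, truth = default_dataset
        g = build_network([filter_spectrum(s) for s in pos])
        planted = {}
        for s in pos:
            planted.setdefault(truth.family_of[s.feature_id], set()).add(s.feature_id)
        assert set(families(g)) == {frozenset(v) for v in planted.values()}


class TestLibrarySearch:
    def _library(self):
        rng = np.random.default_rng(5)
        entries = []
        for i in range(3):
            peaks = [(60.0 + 20 * j + 200 * i, float(rng.uniform(10, 90))) for j in range(8)]
            entries.append(make_spectrum(peaks, precursor=500.0 + 200 * i, fid=f"lib{i}"))
        return entries

    def test_exact_entry_ranked_first_with_score_one(self):
        lib = self._library()
        query = make_spectrum(lib[1].peaks, precursor=lib[1].precursor_mz, fid="q")
        matches = library_search(filter_spectrum(query), lib)
        assert matches and matches[0].library_id == "lib1"
        assert matches[0].score == pytest.approx(1.0, abs=1e-9)

    def test_five_shared_peaks_is_not_enough(self):
        lib = self._library()
        query = make_spectrum(lib[0].peaks[:5], precursor=lib[0].precursor_mz, fid="q")
        assert library_search(filter_spectrum(query), lib) == []

    def test_sorted_matches_equal_brute_force(self):
        lib = self._library()
        query = make_spectrum(lib[2].peaks, precursor=lib[2].precursor_mz, fid="q")
        qf = filter_spectrum(query)
        matches = library_search(qf, lib)
        expect = []
        for entry in lib:
            r = modified_cosine(qf, filter_spectrum(entry))
            if r.score > 0.7 and r.n_matched >= 6:
                expect.append((entry.feature_id, r.score, r.n_matched))
        expect.sort(key=lambda e: (-e[1], e[0]))
        assert [(m.library_id, m.score, m.n_matched) for m in matches] == [
            (e[0], pytest.approx(e[1]), e[2]) for e in expect
        ]

    def test_empty_library(self):
        q = filter_spectrum(make_spectrum([(60.0, 5.0)], fid="q"))
        assert library_search(q, []) == []
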
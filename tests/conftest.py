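"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately re-derive results by exhaustive
enumeration or direct simulation, independent of the library's
implementations, so tests compare two routes to the same answer.
"""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np
import pytest

from cocomet.spectra import (
    Ms2Spectrum,
    Polarity,
    ToleranceConfig,
    spectrum_from_peaks,
)


# ---------------------------------------------------------------- helpers
def make_spectrum(peaks, precursor=500.0, polarity="positive", rt=1.0, fid="s"):
    return spectrum_from_peaks(fid, precursor, polarity, rt, peaks)


def random_spectrum(rng: np.random.Generator, n_peaks: int, fid: str = "r",
                    precursor: float | None = None, grid: bool = False) -> Ms2Spectrum:
    """Random spectrum; with ``grid=True`` peak m/z sit on a >=1 Da grid so
    all tolerance matches are unambiguous."""
    if precursor is None:
        precursor = float(rng.uniform(200, 800))
    if grid:
        mz = rng.choice(np.arange(60, 180), size=n_peaks, replace=False).astype(float)
    else:
        mz = rng.uniform(50, precursor - 25, size=n_peaks)
    mz = np.sort(mz)
    inten = rng.uniform(1, 100, size=n_peaks)
    return Ms2Spectrum(fid, precursor, Polarity.POSITIVE, 1.0, mz, inten)


# ---------------------------------------------------------------- oracles
def brute_force_modified_cosine(a: Ms2Spectrum, b: Ms2Spectrum,
                                tol: ToleranceConfig | None = None):
    """Optimal-assignment modified cosine by exhaustive enumeration of all
    one-to-one candidate pairings.  Returns (best score, n_matched of a
    best pairing, number of distinct optimal pairings)."""
    tol = tol or ToleranceConfig()
    if len(a) == 0 or len(b) == 0:
        return 0.0, 0, 1
    wa = np.sqrt(a.intensity)
    wa = wa / np.linalg.norm(wa)
    wb = np.sqrt(b.intensity)
    wb = wb / np.linalg.norm(wb)
    dprec = b.precursor_mz - a.precursor_mz
    cand_of = [
        [
            j
            for j in range(len(b))
            if abs(a.mz[i] - b.mz[j]) <= tol.fragment_tol_da
            or abs(a.mz[i] + dprec - b.mz[j]) <= tol.fragment_tol_da
        ]
        for i in range(len(a))
    ]

    # enumerate every one-to-one assignment: each leaf is one pairing
    leaves: list[tuple[float, int, frozenset]] = []

    def rec(i, used_b, score, nm, pairs):
        if i == len(cand_of):
            leaves.append((score, nm, frozenset(pairs)))
            return
        rec(i + 1, used_b, score, nm, pairs)  # peak i unmatched
        for j in cand_of[i]:
            if j not in used_b:
                rec(i + 1, used_b | {j}, score + wa[i] * wb[j], nm + 1, pairs + [(i, j)])

    rec(0, frozenset(), 0.0, 0, [])
    best_score = max(s for s, _, _ in leaves)
    optimal = {p for s, _, p in leaves if s >= best_score - 1e-12}
    best_nm = max(nm for s, nm, _ in leaves if s >= best_score - 1e-12)
    return best_score, best_nm, len(optimal)


def apply_edge_rules_brute_force(nodes, scores, n_matched, cfg):
    """Independent sequential application of threshold -> mutual top-k ->
    family cap to a pairwise score table.

    ``scores``/``n_matched`` are dicts keyed by frozenset({a, b}).
    Returns the surviving edge set as a set of frozensets.
    """
    # 1. threshold
    edges = {
        e for e in scores
        if scores[e] > cfg.score_threshold and n_matched[e] >= cfg.min_matched
    }
    # 2. mutual top-k on the thresholded edge set
    def topk(node):
        nbrs = []
        for e in edges:
            if node in e:
                (other,) = e - {node}
                nbrs.append(other)
        nbrs.sort(key=lambda o: (-scores[frozenset({node, o})], o))
        return set(nbrs[: cfg.mutual_k])

    tk = {n: topk(n) for n in nodes}
    edges = {e for e in edges if all((e - {n}).issubset(tk[n]) for n in e)}
    # 3. family cap: repeatedly remove lowest-scoring edge of an oversized
    # component (component picked by smallest member, ties by node pair)
    while True:
        g = nx.Graph()
        g.add_nodes_from(nodes)
        g.add_edges_from(tuple(e) for e in edges)
        oversized = [c for c in nx.connected_components(g) if len(c) > cfg.max_family_size]
        if not oversized:
            return edges
        comp = min(oversized, key=lambda c: min(c))
        worst = min(
            (e for e in edges if e.issubset(comp)),
            key=lambda e: (scores[e], tuple(sorted(e))),
        )
        edges = edges - {worst}


def greedy_merge_oracle(pos_nodes, neg_nodes, cfg):
    """Brute-force greedy cross-polarity pairing: nodes are dicts with
    ``neutral`` and ``rt``; returns the accepted (pos_id, neg_id) set."""
    from cocomet.merge import ppm_difference

    cand = []
    for p, dp in pos_nodes.items():
        for n, dn in neg_nodes.items():
            ppm = ppm_difference(dp["neutral"], dn["neutral"])
            drt = abs(dp["rt"] - dn["rt"])
            if ppm < cfg.ppm_tol and drt < cfg.rt_tol_min:
                cand.append((ppm, drt, p, n))
    cand.sort()
    used_p, used_n, out = set(), set(), set()
    for ppm, drt, p, n in cand:
        if p not in used_p and n not in used_n:
            used_p.add(p)
            used_n.add(n)
            out.add((p, n))
    return out


@pytest.fixture(scope="session")
def default_dataset():
    """The default synthetic study: 5 families x 4 members, 4 replicates
    per group, 4 planted 8-fold coculture-enriched compounds, seed 17."""
    from cocomet.simulate import SimulationConfig, generate_dataset

    cfg = SimulationConfig(seed=17)
    pos, neg, table, truth = generate_dataset(cfg)
    return cfg, pos, neg, table, truth
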
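"""Molecular network construction and the GNPS edge-pruning rules.

A molecular network is an undirected graph whose nodes are LC-MS/MS
features and whose edges connect spectrally similar features.  Edges are
admitted in three ordered steps:

1. **Threshold** — keep pairs with modified-cosine score above a threshold
   and at least ``min_matched`` matched fragment peaks.
2. **Mutual top-k** — keep an edge only if each endpoint ranks in the
   other's top ``k`` most similar neighbors.
3. **Family cap** — repeatedly remove the lowest-scoring edge from any
   connected component ("molecular family") larger than ``max_family_size``
   until all families fit.

Connected components of the result are interpreted as families of
structurally related metabolites.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx

from .spectra import Ms2Spectrum, SimilarityResult, ToleranceConfig, modified_cosine

__all__ = [
    "NetworkConfig",
    "LibraryMatch",
    "build_network",
    "mutual_topk_filter",
    "cap_family_size",
    "drop_singletons",
    "library_search",
    "families",
]


@dataclass(frozen=True)
class NetworkConfig:
    """Edge admission rules.

    Defaults follow standard GNPS networking practice: cosine > 0.70,
    at least 6 matched peaks, mutual top-10 neighbors, families capped at
    100 nodes.
    """

    score_threshold: float = 0.70
    min_matched: int = 6
    mutual_k: int = 10
    max_family_size: int = 100

    def __post_init__(self) -> None:
        if not 0.0 <= self.score_threshold <= 1.0:
            raise ValueError("score_threshold must be in [0, 1]")
        for name in ("min_matched", "mutual_k", "max_family_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


@dataclass(frozen=True)
class LibraryMatch:
    """A query spectrum matched against a library spectrum."""

    query_id: str
    library_id: str
    score: float
    n_matched: int


def _node_attrs(s: Ms2Spectrum) -> dict:
    return {
        "precursor_mz": float(s.precursor_mz),
        "rt": float(s.rt),
        "polarity": s.polarity.value,
    }


def build_network(
    spectra: list[Ms2Spectrum],
    cfg: NetworkConfig | None = None,
    tol: ToleranceConfig | None = None,
) -> nx.Graph:
    """Build a molecular network from filtered spectra of one polarity.

    All pairwise modified cosines are computed, then the three edge rules
    (threshold, mutual top-k, family cap) are applied in order.  The
    result is deterministic: all rank and removal ties are broken by node
    id.  Fewer than two spectra yield a node-only network.
    """
    cfg = cfg or NetworkConfig()
    tol = tol or ToleranceConfig()
    polarities = {s.polarity for s in spectra}
    if len(polarities) > 1:
        raise ValueError("build_network requires spectra of a single polarity")
    ids = [s.feature_id for s in spectra]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate feature ids in spectra")

    g = nx.Graph()
    for s in spectra:
        g.add_node(s.feature_id, **_node_attrs(s))
    for i in range(len(spectra)):
        for j in range(i + 1, len(spectra)):
            res = modified_cosine(spectra[i], spectra[j], tol)
            if res.score > cfg.score_threshold and res.n_matched >= cfg.min_matched:
                g.add_edge(
                    spectra[i].feature_id,
                    spectra[j].feature_id,
                    score=res.score,
                    n_matched=res.n_matched,
                )
    g = mutual_topk_filter(g, cfg.mutual_k)
    g = cap_family_size(g, cfg.max_family_size)
    return g


def mutual_topk_filter(network: nx.Graph, k: int = 10) -> nx.Graph:
    """Keep edge (a, b) iff b is among a's ``k`` highest-scoring neighbors
    and vice versa.  Rank ties are broken by ascending node id; the node
    set is unchanged."""
    if k < 1:
        raise ValueError("k must be >= 1")
    top: dict = {}
    for node in network.nodes:
        nbrs = sorted(
            network.adj[node].items(),
            key=lambda kv: (-kv[1]["score"], kv[0]),
        )
        top[node] = {n for n, _ in nbrs[:k]}
    out = network.copy()
    for a, b in list(network.edges):
        if b not in top[a] or a not in top[b]:
            out.remove_edge(a, b)
    return out


def cap_family_size(network: nx.Graph, max_size: int = 100) -> nx.Graph:
    """Remove lowest-scoring edges until no connected component exceeds
    ``max_size`` nodes.

    Components are recomputed after every single removal; score ties are
    broken by the ascending (min id, max id) node pair.  Only edges are
    removed, never nodes.
    """
    if max_size < 1:
        raise ValueError("max_size must be >= 1")
    out = network.copy()
    while True:
        oversized = [c for c in nx.connected_components(out) if len(c) > max_size]
        if not oversized:
            return out
        comp = min(oversized, key=lambda c: min(c))  # deterministic pick
        worst = min(
            out.subgraph(comp).edges(data="score"),
            key=lambda e: (e[2], tuple(sorted((e[0], e[1])))),
        )
        out.remove_edge(worst[0], worst[1])


def drop_singletons(network: nx.Graph) -> nx.Graph:
    """Return the display network: nodes of degree 0 removed.

    Quantitative tables elsewhere keep every feature; this only affects
    what is drawn (isolated, self-similar-only nodes are truncated).
    """
    out = network.copy()
    out.remove_nodes_from([n for n in network.nodes if network.degree[n] == 0])
    return out


def families(network: nx.Graph) -> list[frozenset]:
    """Connected components (molecular families), sorted by smallest member."""
    comps = [frozenset(c) for c in nx.connected_components(network)]
    return sorted(comps, key=lambda c: min(c))


def library_search(
    query: Ms2Spectrum,
    library: list[Ms2Spectrum],
    tol: ToleranceConfig | None = None,
    score_threshold: float = 0.70,
    min_matched: int = 6,
    prefilter: bool = True,
) -> list[LibraryMatch]:
    """Match a query spectrum against a spectral library.

    Library spectra are passed through the same two spectral filters as
    the input data (unless ``prefilter=False`` because they are already
    filtered), then scored with the modified cosine.  Matches require
    score > ``score_threshold`` and at least ``min_matched`` matched
    peaks, and are returned sorted by descending score (ties by library
    id).
    """
    from .spectra import filter_spectrum

    tol = tol or ToleranceConfig()
    out: list[LibraryMatch] = []
    for entry in library:
        lib = filter_spectrum(entry, tol) if prefilter else entry
        res: SimilarityResult = modified_cosine(query, lib, tol)
        if res.score > score_threshold and res.n_matched >= min_matched:
            out.append(LibraryMatch(query.feature_id, entry.feature_id, res.score, res.n_matched))
    return sorted(out, key=lambda m: (-m.score, m.library_id))
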
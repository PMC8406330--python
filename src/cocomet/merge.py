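"""Cross-polarity network merging.

The same neutral molecule can appear twice in an untargeted experiment:
once as its [M+H]+ adduct in the positive-mode network and once as [M-H]-
in the negative-mode network.  This module reconciles the two by
adduct-correcting every precursor m/z to a neutral mass and greedily
pairing positive/negative nodes that agree in neutral mass (ppm scale)
and retention time.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx

from .spectra import PROTON_MASS_DA, Polarity

__all__ = ["MergeConfig", "neutral_mass", "ppm_difference", "merge_networks"]


@dataclass(frozen=True)
class MergeConfig:
    """Matching tolerances for cross-polarity reconciliation.

    Both comparisons are strict ("less than"): neutral masses must agree
    to better than ``ppm_tol`` parts per million and retention times to
    better than ``rt_tol_min`` minutes.
    """

    ppm_tol: float = 20.0
    rt_tol_min: float = 0.15
    proton_mass_da: float = PROTON_MASS_DA

    def __post_init__(self) -> None:
        if self.ppm_tol <= 0 or self.rt_tol_min <= 0:
            raise ValueError("tolerances must be positive")


def neutral_mass(mz: float, polarity: Polarity | str, proton_mass_da: float = PROTON_MASS_DA) -> float:
    """Adduct-corrected neutral mass: subtract a proton for [M+H]+,
    add one for [M-H]-.  Raises if the result would be non-positive."""
    pol = Polarity(polarity)
    if pol is Polarity.POSITIVE:
        m = mz - proton_mass_da
    else:
        m = mz + proton_mass_da
    if m <= 0:
        raise ValueError(f"invalid m/z {mz} for polarity {pol.value}: non-positive neutral mass")
    return m


def ppm_difference(x: float, y: float) -> float:
    """Relative mass difference in parts per million, referenced to the
    mean of the two masses."""
    return 1e6 * abs(x - y) / ((x + y) / 2.0)


def merge_networks(pos: nx.Graph, neg: nx.Graph, cfg: MergeConfig | None = None) -> nx.Graph:
    """Merge a positive- and a negative-mode network into one graph of
    neutral molecules.

    Candidate pairs are (positive node, negative node) whose neutral
    masses differ by < ``ppm_tol`` ppm and retention times by
    < ``rt_tol_min`` minutes.  Pairs are accepted greedily by ascending
    ppm difference (ties by ascending RT difference, then node ids), each
    node at most once.  Unpaired nodes pass through unchanged.  Edges of
    both input networks are inherited onto the merged nodes; if two input
    edges collapse onto the same merged pair, the higher cosine score is
    kept.

    Merged node attributes: ``members`` (sorted tuple of source feature
    ids), ``neutral_mass`` and ``rt`` (mean over members), ``polarity``
    ("merged", "positive" or "negative").
    """
    cfg = cfg or MergeConfig()
    for g, want in ((pos, "positive"), (neg, "negative")):
        for n, d in g.nodes(data=True):
            if d.get("polarity") != want:
                raise ValueError(f"node {n!r} has polarity {d.get('polarity')!r}, expected {want}")

    def neutral(g: nx.Graph, n) -> float:
        d = g.nodes[n]
        return neutral_mass(d["precursor_mz"], d["polarity"], cfg.proton_mass_da)

    candidates = []
    for p, dp in pos.nodes(data=True):
        mp = neutral(pos, p)
        for n, dn in neg.nodes(data=True):
            mn = neutral(neg, n)
            ppm = ppm_difference(mp, mn)
            drt = abs(dp["rt"] - dn["rt"])
            if ppm < cfg.ppm_tol and drt < cfg.rt_tol_min:
                candidates.append((ppm, drt, p, n))
    candidates.sort(key=lambda c: (c[0], c[1], c[2], c[3]))

    pair_of: dict = {}
    used_pos: set = set()
    used_neg: set = set()
    for ppm, drt, p, n in candidates:
        if p in used_pos or n in used_neg:
            continue
        used_pos.add(p)
        used_neg.add(n)
        pair_of[p] = n
        pair_of[n] = p

    merged = nx.Graph()
    node_map: dict = {}

    def merged_id(members: tuple) -> str:
        return "+".join(str(m) for m in members)

    for g in (pos, neg):
        for n, d in g.nodes(data=True):
            if n in node_map:
                continue
            if n in pair_of:
                other = pair_of[n]
                og = neg if g is pos else pos
                members = tuple(sorted((str(n), str(other))))
                mid = merged_id(members)
                nm = (neutral(g, n) + neutral(og, other)) / 2.0
                rt = (g.nodes[n]["rt"] + og.nodes[other]["rt"]) / 2.0
                merged.add_node(mid, members=members, neutral_mass=nm, rt=rt, polarity="merged")
                node_map[n] = mid
                node_map[other] = mid
            else:
                members = (str(n),)
                mid = merged_id(members)
                merged.add_node(
                    mid,
                    members=members,
                    neutral_mass=neutral(g, n),
                    rt=d["rt"],
                    polarity=d["polarity"],
                )
                node_map[n] = mid

    for g in (pos, neg):
        for a, b, d in g.edges(data=True):
            ma, mb = node_map[a], node_map[b]
            if ma == mb:
                continue
            if merged.has_edge(ma, mb):
                if d["score"] > merged.edges[ma, mb]["score"]:
                    merged.edges[ma, mb].update(score=d["score"], n_matched=d["n_matched"])
            else:
                merged.add_edge(ma, mb, **d)
    return merged
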
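"""Three-way node color/transparency encoding for network figures.

Each node carries three group-mean intensities (fungal monoculture,
bacterial monoculture, coculture).  The **hue** places the node on a
color wheel between three anchor hues: each group's anchor is a unit
vector at its anchor angle, the vectors are weighted by the normalized
intensities, and the hue is the angle of the resultant.  A pure
single-group node lands exactly on that group's anchor; equal intensities
cancel to a neutral gray.

The **alpha** (opacity) encodes how different the three means are: the
range d = max - min is normalized to the min/max of a reference group's
means over all nodes (the coculture, by default), clipped to [0, 1] and
square-root transformed, so strongly group-specific features are opaque
and flat features fade out.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

__all__ = ["NodeStyle", "ColorConfig", "three_way_hue", "node_alpha", "style_table"]


@dataclass(frozen=True)
class NodeStyle:
    """Hue in degrees [0, 360) (None for neutral, all-equal nodes) and
    opacity alpha in [0, 1]."""

    hue: float | None
    alpha: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must be in [0, 1]")


@dataclass(frozen=True)
class ColorConfig:
    """Anchor hues per group (degrees) and the group whose min/max
    normalize alpha."""

    anchor_hues: tuple[float, float, float] = (0.0, 120.0, 240.0)
    reference_group: str = "coculture"

    def __post_init__(self) -> None:
        if len(set(self.anchor_hues)) != 3:
            raise ValueError("anchor hues must be distinct")


_NEUTRAL_EPS = 1e-9


def three_way_hue(
    values: tuple[float, float, float], cfg: ColorConfig | None = None
) -> float | None:
    """Hue of the intensity-weighted vector sum of the three anchors.

    ``values`` are the three group-mean intensities (non-negative, not
    all zero); they are normalized to sum 1 before weighting.  Returns
    the resultant angle in degrees in [0, 360), or ``None`` when the
    weighted vectors cancel (all groups equal) — the neutral case,
    rendered mid-gray.
    """
    cfg = cfg or ColorConfig()
    vals = [float(v) for v in values]
    if len(vals) != 3:
        raise ValueError("exactly three group values required")
    if any(v < 0 for v in vals):
        raise ValueError("group values must be non-negative")
    total = sum(vals)
    if total == 0:
        raise ValueError("all-zero intensities have no hue")
    x = y = 0.0
    for v, h in zip(vals, cfg.anchor_hues):
        w = v / total
        x += w * math.cos(math.radians(h))
        y += w * math.sin(math.radians(h))
    if math.hypot(x, y) < _NEUTRAL_EPS:
        return None
    return math.degrees(math.atan2(y, x)) % 360.0


def node_alpha(
    values: tuple[float, float, float], ref_min: float, ref_max: float
) -> float:
    """Opacity from the between-group intensity range.

    d = max(values) - min(values) is normalized to the reference range
    [ref_min, ref_max] (the min and max of the reference group's means
    over the node set), clipped to [0, 1], then square-root transformed.
    """
    if ref_max <= ref_min:
        raise ValueError("degenerate reference range: ref_max must exceed ref_min")
    d = max(values) - min(values)
    d_norm = (d - ref_min) / (ref_max - ref_min)
    d_norm = min(1.0, max(0.0, d_norm))
    return math.sqrt(d_norm)


def style_table(
    network: nx.Graph,
    means: pd.DataFrame,
    cfg: ColorConfig | None = None,
    group_order: tuple[str, str, str] | None = None,
) -> pd.DataFrame:
    """One style record per displayed node.

    ``means`` is a features x groups DataFrame of group-mean intensities;
    nodes absent from it get zero means (and no hue).  ``group_order``
    fixes which group maps to which anchor hue; it defaults to the sorted
    column order.  The reference min/max for alpha come from
    ``cfg.reference_group``'s column.

    Returns a DataFrame indexed by node with columns ``hue`` (NaN when
    neutral or all-zero), ``alpha`` and ``neutral``.
    """
    cfg = cfg or ColorConfig()
    if group_order is None:
        group_order = tuple(sorted(means.columns))
    if len(group_order) != 3:
        raise ValueError("exactly three groups required")
    if cfg.reference_group not in means.columns:
        raise ValueError(f"reference group {cfg.reference_group!r} not in means")
    ref = means[cfg.reference_group]
    ref_min, ref_max = float(ref.min()), float(ref.max())

    rows = []
    for node, data in network.nodes(data=True):
        # a merged node's means live under its member feature ids
        keys = [node, *data.get("members", ())]
        key = next((k for k in keys if k in means.index), None)
        if key is None:
            vals = (0.0, 0.0, 0.0)
        else:
            vals = tuple(float(means.loc[key, g]) for g in group_order)
        if sum(vals) == 0:
            hue = None
        else:
            hue = three_way_hue(vals, cfg)
        alpha = node_alpha(vals, ref_min, ref_max)
        rows.append({"node": node, "hue": hue, "alpha": alpha, "neutral": hue is None})
    out = pd.DataFrame(rows).set_index("node")
    out["hue"] = out["hue"].astype(float)
    return out
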
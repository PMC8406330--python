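"""Peak-height quantification and the coculture-enrichment screen.

The screen looks for metabolites produced (or strongly up-produced) by the
fungal-bacterial coculture rather than by either organism alone.  After
per-sample row-sum normalization, a feature passes when

(a) it is detected in every coculture replicate,
(b) its mean coculture height is at least ``fc_threshold``-fold that of
    both the fungal and bacterial monoculture means (a monoculture mean of
    zero counts as "not detectable" and satisfies the fold criterion), and
(c) a one-tailed pooled-variance Student's t-test of coculture > each
    monoculture gives p < ``alpha`` against both.

No multiple-testing correction enters the pass decision; Benjamini-
Hochberg adjusted p-values are reported as extra columns for context.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "FeatureTable",
    "ScreenConfig",
    "GROUP_COCULTURE",
    "GROUP_FUNGAL",
    "GROUP_BACTERIAL",
    "row_sum_normalize",
    "group_means",
    "fold_change",
    "one_tailed_t",
    "enrichment_screen",
]

GROUP_COCULTURE = "coculture"
GROUP_FUNGAL = "fungal_mono"
GROUP_BACTERIAL = "bacterial_mono"


@dataclass
class FeatureTable:
    """Feature-by-sample peak heights plus feature metadata and design.

    Attributes
    ----------
    features : DataFrame
        Indexed by feature_id with columns ``mz``, ``rt``, ``polarity``.
    heights : DataFrame
        Non-negative peak heights, features x samples; index aligned with
        ``features``.
    design : DataFrame
        Indexed by sample_id with columns ``group`` and ``condition``.
    """

    features: pd.DataFrame
    heights: pd.DataFrame
    design: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.features.index.equals(self.heights.index):
            raise ValueError("features and heights must share the same feature index")
        missing = set(self.heights.columns) - set(self.design.index)
        if missing:
            raise ValueError(f"samples missing from design: {sorted(missing)}")
        extra = set(self.design.index) - set(self.heights.columns)
        if extra:
            raise ValueError(f"design references samples absent from table: {sorted(extra)}")
        if (self.heights.values < 0).any():
            bad = np.argwhere(self.heights.values < 0)[0]
            raise ValueError(
                f"negative height at feature {self.heights.index[bad[0]]!r}, "
                f"sample {self.heights.columns[bad[1]]!r}"
            )
        if self.features.index.duplicated().any():
            dup = self.features.index[self.features.index.duplicated()][0]
            raise ValueError(f"duplicate feature id {dup!r}")

    def samples_in_group(self, group: str, condition: str | None = None) -> list[str]:
        d = self.design
        mask = d["group"] == group
        if condition is not None:
            mask &= d["condition"] == condition
        return list(d.index[mask])

    @property
    def conditions(self) -> list[str]:
        return sorted(self.design["condition"].unique())


@dataclass(frozen=True)
class ScreenConfig:
    """Screen thresholds.

    ``fc_threshold`` (default 4) is the minimum coculture/monoculture mean
    ratio; ``alpha`` (default 0.05) the one-tailed significance level;
    ``row_sum_total`` the per-sample normalization constant (default 1e6);
    ``detection_floor`` the minimum normalized height counted as detection
    (default 0, i.e. any positive height).  ``log_scale`` switches the
    t-test to log-transformed heights (not the default).
    """

    fc_threshold: float = 4.0
    alpha: float = 0.05
    row_sum_total: float = 1_000_000.0
    detection_floor: float = 0.0
    log_scale: bool = False

    def __post_init__(self) -> None:
        if self.fc_threshold < 1:
            raise ValueError("fc_threshold must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.row_sum_total <= 0:
            raise ValueError("row_sum_total must be positive")


def row_sum_normalize(table: FeatureTable, total: float = 1_000_000.0) -> FeatureTable:
    """Scale each sample so its heights sum to ``total``.

    Within-sample proportions are unchanged and the operation is
    idempotent.  An all-zero sample cannot be normalized and raises.
    """
    sums = table.heights.sum(axis=0)
    zero = sums[sums <= 0]
    if len(zero):
        raise ValueError(f"cannot normalize all-zero sample(s): {list(zero.index)}")
    heights = table.heights * (total / sums)
    return FeatureTable(table.features, heights, table.design)


def group_means(table: FeatureTable, condition: str | None = None) -> pd.DataFrame:
    """Arithmetic mean of replicate heights per group, per feature.

    Returns a features x groups DataFrame.  Raises if any group has no
    samples (under the given condition, when one is specified).
    """
    design = table.design
    if condition is not None:
        design = design[design["condition"] == condition]
    out = {}
    for grp in sorted(design["group"].unique()):
        cols = list(design.index[design["group"] == grp])
        if not cols:
            raise ValueError(f"group {grp!r} has no samples")
        out[grp] = table.heights[cols].mean(axis=1)
    if not out:
        raise ValueError(f"no samples for condition {condition!r}")
    return pd.DataFrame(out, index=table.heights.index)


NOT_DETECTABLE = float("inf")


def fold_change(num_mean: float, den_mean: float) -> float:
    """Mean ratio with the "not detectable" convention.

    Positive numerator over zero denominator returns ``inf`` — the
    denominator condition never showed the feature, rendered as an em
    dash in reports and counting as passing the fold criterion.  Both
    zero returns ``nan`` (undefined; fails the screen).
    """
    if num_mean < 0 or den_mean < 0:
        raise ValueError("means must be non-negative")
    if den_mean > 0:
        return num_mean / den_mean
    if num_mean > 0:
        return NOT_DETECTABLE
    return float("nan")


def one_tailed_t(coculture: np.ndarray, monoculture: np.ndarray) -> tuple[float, float]:
    """One-tailed pooled-variance Student's t-test of coculture mean >
    monoculture mean.

    Returns ``(t, p)`` with ``df = n1 + n2 - 2`` and p the upper-tail
    probability.  With zero pooled variance the limit convention applies:
    equal means give p = 0.5, a larger coculture mean gives p = 0 (and a
    smaller one p = 1).
    """
    x = np.asarray(coculture, dtype=float)
    y = np.asarray(monoculture, dtype=float)
    n1, n2 = x.size, y.size
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least 2 replicates per group")
    dmean = x.mean() - y.mean()
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / df
    if sp2 == 0.0:
        if dmean == 0.0:
            return 0.0, 0.5
        return (math.inf, 0.0) if dmean > 0 else (-math.inf, 1.0)
    se = math.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    t = dmean / se
    p = float(stats.t.sf(t, df))
    return float(t), p


def _fc_to_str(fc: float) -> str:
    if math.isinf(fc):
        return "—"
    if math.isnan(fc):
        return "nd"
    return f"{fc:.2f}"


def enrichment_screen(
    table: FeatureTable,
    cfg: ScreenConfig | None = None,
    condition: str | None = None,
    normalized: bool = False,
) -> pd.DataFrame:
    """Run the coculture-enrichment screen for one condition.

    The table is row-sum normalized first (skip with ``normalized=True``
    if already done).  Returns one row per feature with group means, fold
    changes versus each monoculture, one-tailed t statistics and
    p-values, BH-adjusted p-values (context only), the per-criterion
    flags and the overall ``passes`` flag.
    """
    cfg = cfg or ScreenConfig()
    if not normalized:
        table = row_sum_normalize(table, cfg.row_sum_total)

    design = table.design
    if condition is None:
        conds = table.conditions
        if len(conds) != 1:
            raise ValueError(f"multiple conditions present {conds}; specify one")
        condition = conds[0]

    groups = {}
    for grp in (GROUP_COCULTURE, GROUP_FUNGAL, GROUP_BACTERIAL):
        cols = table.samples_in_group(grp, condition)
        if not cols:
            raise ValueError(f"missing group {grp!r} for condition {condition!r}")
        groups[grp] = cols

    coc = table.heights[groups[GROUP_COCULTURE]].values
    fun = table.heights[groups[GROUP_FUNGAL]].values
    bac = table.heights[groups[GROUP_BACTERIAL]].values

    def maybe_log(a: np.ndarray) -> np.ndarray:
        return np.log1p(a) if cfg.log_scale else a

    rows = []
    for i, fid in enumerate(table.heights.index):
        c, f, b = coc[i], fun[i], bac[i]
        detected_all = bool(np.all(c > cfg.detection_floor))
        mc, mf, mb = float(c.mean()), float(f.mean()), float(b.mean())
        fc_f = fold_change(mc, mf)
        fc_b = fold_change(mc, mb)
        t_f, p_f = one_tailed_t(maybe_log(c), maybe_log(f))
        t_b, p_b = one_tailed_t(maybe_log(c), maybe_log(b))
        fc_ok_f = math.isinf(fc_f) or (not math.isnan(fc_f) and fc_f >= cfg.fc_threshold)
        fc_ok_b = math.isinf(fc_b) or (not math.isnan(fc_b) and fc_b >= cfg.fc_threshold)
        passes = (
            detected_all and fc_ok_f and fc_ok_b and p_f < cfg.alpha and p_b < cfg.alpha
        )
        rows.append(
            {
                "feature_id": fid,
                "condition": condition,
                "mean_coculture": mc,
                "mean_fungal_mono": mf,
                "mean_bacterial_mono": mb,
                "fc_vs_fungal": fc_f,
                "fc_vs_bacterial": fc_b,
                "fc_vs_fungal_str": _fc_to_str(fc_f),
                "fc_vs_bacterial_str": _fc_to_str(fc_b),
                "not_detectable_fungal": math.isinf(fc_f),
                "not_detectable_bacterial": math.isinf(fc_b),
                "t_vs_fungal": t_f,
                "p_vs_fungal": p_f,
                "t_vs_bacterial": t_b,
                "p_vs_bacterial": p_b,
                "detected_all_coculture": detected_all,
                "passes": passes,
            }
        )
    report = pd.DataFrame(rows).set_index("feature_id")
    report = report.join(table.features[["mz", "rt", "polarity"]])
    for col in ("p_vs_fungal", "p_vs_bacterial"):
        report[col + "_bh"] = multipletests(report[col].values, method="fdr_bh")[1]
    return report
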
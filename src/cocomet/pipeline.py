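"""End-to-end pipeline: filter -> network per polarity -> cross-polarity
merge -> normalize -> enrichment screen -> style -> write outputs."""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd

from .encoding import ColorConfig, style_table
from .io import read_feature_csv, read_mgf, write_graphml
from .merge import MergeConfig, merge_networks
from .network import NetworkConfig, build_network, drop_singletons, library_search
from .quantify import (
    GROUP_BACTERIAL,
    GROUP_COCULTURE,
    GROUP_FUNGAL,
    FeatureTable,
    ScreenConfig,
    enrichment_screen,
    group_means,
    row_sum_normalize,
)
from .spectra import Ms2Spectrum, Polarity, ToleranceConfig, filter_spectrum

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "run_pipeline_from_objects"]

logger = logging.getLogger("cocomet")


@dataclass
class PipelineConfig:
    """Paths plus every stage's parameter block.

    All defaults are the standard GNPS/FBMN parameters: 0.05 Da
    tolerances, ±17 Da precursor removal, top-6 per ±50 Da window,
    cosine > 0.70 with >= 6 matched peaks, mutual top-10, family cap
    100, merge at < 20 ppm and < 0.15 min, row-sum normalization to
    1,000,000, 4-fold enrichment at one-tailed alpha 0.05.
    """

    pos_mgf: str | Path | None = None
    neg_mgf: str | Path | None = None
    feature_csv: str | Path | None = None
    design_csv: str | Path | None = None
    library_mgf: str | Path | None = None
    out_dir: str | Path = "cocomet_out"
    tolerance: ToleranceConfig = field(default_factory=ToleranceConfig)
    network: NetworkConfig = field(default_factory=NetworkConfig)
    merge: MergeConfig = field(default_factory=MergeConfig)
    screen: ScreenConfig = field(default_factory=ScreenConfig)
    color: ColorConfig = field(default_factory=ColorConfig)
    condition: str | None = None
    log_level: str = "INFO"


@dataclass
class PipelineResult:
    """In-memory pipeline outputs (also written to ``out_dir``)."""

    merged_network: nx.Graph
    display_network: nx.Graph
    report: pd.DataFrame
    styles: pd.DataFrame
    means: pd.DataFrame
    paths: dict[str, Path]


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
            logger.info("stage %-18s %.2fs", name, time.perf_counter() - t0)
            return out

        return wrapped

    return deco


def run_pipeline_from_objects(
    pos_spectra: list[Ms2Spectrum],
    neg_spectra: list[Ms2Spectrum],
    table: FeatureTable,
    cfg: PipelineConfig,
    library: list[Ms2Spectrum] | None = None,
) -> PipelineResult:
    """Run all stages on in-memory inputs and write outputs to
    ``cfg.out_dir``.  Fully deterministic: identical inputs produce
    byte-identical report and style CSVs and identical GraphML
    attributes."""
    logger.setLevel(cfg.log_level)
    logger.info(
        "parameters: tol=%s network=%s merge=%s screen=%s",
        cfg.tolerance, cfg.network, cfg.merge, cfg.screen,
    )
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    filt = _stage("filter")(
        lambda spectra: [filter_spectrum(s, cfg.tolerance) for s in spectra]
    )
    pos_f = filt(pos_spectra)
    neg_f = filt(neg_spectra)

    net = _stage("network")(build_network)
    pos_net = net(pos_f, cfg.network, cfg.tolerance)
    neg_net = net(neg_f, cfg.network, cfg.tolerance)

    if len(neg_net) and len(pos_net):
        merged = _stage("merge")(merge_networks)(pos_net, neg_net, cfg.merge)
    elif len(pos_net):
        merged = pos_net.copy()
    else:
        merged = neg_net.copy()

    normalized = _stage("normalize")(row_sum_normalize)(table, cfg.screen.row_sum_total)

    conditions = (
        [cfg.condition] if cfg.condition is not None else normalized.conditions
    )
    screen = _stage("screen")(enrichment_screen)
    reports = [
        screen(normalized, cfg.screen, condition=c, normalized=True) for c in conditions
    ]
    report = pd.concat(reports).sort_values(["condition", "feature_id"]).reset_index()

    # style on the first condition's three group means (the figure shows one substrate)
    means = group_means(normalized, conditions[0])
    means = means[[GROUP_FUNGAL, GROUP_BACTERIAL, GROUP_COCULTURE]]
    display = drop_singletons(merged)
    styles = _stage("style")(style_table)(
        display, means, cfg.color, group_order=(GROUP_FUNGAL, GROUP_BACTERIAL, GROUP_COCULTURE)
    )

    annotations: dict = {}
    if library:
        ann = _stage("library")(
            lambda: {
                s.feature_id: m[0].library_id
                for s in pos_f + neg_f
                if (m := library_search(s, library, cfg.tolerance,
                                        cfg.network.score_threshold, cfg.network.min_matched))
            }
        )()
        for node, data in display.nodes(data=True):
            for member in data.get("members", (node,)):
                if member in ann:
                    annotations[node] = ann[member]
                    break

    paths = {
        "graphml": out_dir / "network.graphml",
        "report": out_dir / "enrichment_report.csv",
        "styles": out_dir / "node_styles.csv",
    }
    write = _stage("write")(
        lambda: (
            write_graphml(display, paths["graphml"], styles=styles, means=means,
                          annotations=annotations),
            report.to_csv(paths["report"], index=False),
            styles.to_csv(paths["styles"]),
        )
    )
    write()
    logger.info(
        "done: %d merged nodes, %d displayed, %d features screened, %d passing",
        len(merged), len(display), len(report), int(report["passes"].sum()),
    )
    return PipelineResult(merged, display, report, styles, means, paths)


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    """File-based entry point: read the MGFs and CSVs named in ``cfg``,
    then delegate to :func:`run_pipeline_from_objects`."""
    if cfg.feature_csv is None or cfg.design_csv is None:
        raise ValueError("feature_csv and design_csv are required")
    read = _stage("read")(
        lambda: (
            read_mgf(cfg.pos_mgf) if cfg.pos_mgf else [],
            read_mgf(cfg.neg_mgf) if cfg.neg_mgf else [],
            read_feature_csv(cfg.feature_csv, cfg.design_csv),
            read_mgf(cfg.library_mgf) if cfg.library_mgf else None,
        )
    )
    pos, neg, table, library = read()
    if not pos and not neg:
        raise ValueError("no spectra: provide pos_mgf and/or neg_mgf")
    return run_pipeline_from_objects(pos, neg, table, cfg, library=library)
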
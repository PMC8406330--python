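"""Synthetic LC-MS/MS data with known ground truth.

The generator emulates the statistical structure of an untargeted
non-polar metabolomics experiment comparing a fungal monoculture, a
bacterial monoculture, and their coculture (four biological replicates
each):

* **Molecular families** — groups of structurally related compounds that
  share a backbone fragment set; members differ by small mass
  modifications (CH2, H2 by default) and a subset of their fragments
  shifts along with the modification, so family members connect under
  the modified cosine's precursor-shift rule.
* **Dual-mode ionization** — a configurable fraction of compounds ionize
  as both [M+H]+ and [M-H]-, producing cross-polarity feature pairs the
  merge stage should reconcile.
* **Quantitative structure** — per-replicate peak heights are group mean
  times multiplicative log-normal noise, with optional detection
  dropout; planted coculture-enriched compounds have their coculture
  mean raised by a known fold change over both monocultures.

Everything is deterministic given the seed: each compound and each
feature row draws from its own integer-indexed random stream, so output
does not depend on generation order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .quantify import (
    GROUP_BACTERIAL,
    GROUP_COCULTURE,
    GROUP_FUNGAL,
    FeatureTable,
)
from .spectra import PROTON_MASS_DA, Ms2Spectrum, Polarity

__all__ = [
    "SimulationConfig",
    "SyntheticCompound",
    "GroundTruth",
    "generate_compounds",
    "generate_spectra",
    "generate_feature_table",
    "generate_dataset",
]

GROUPS = (GROUP_COCULTURE, GROUP_FUNGAL, GROUP_BACTERIAL)


@dataclass(frozen=True)
class SimulationConfig:
    """Generator parameters.

    Defaults emulate the study design: three groups of four biological
    replicates, log-normal replicate noise with sigma 0.2 (~20% CV),
    small families of compounds related by common biochemical mass
    shifts (CH2 = 14.0157 Da, H2 = 2.0157 Da), 3 ppm mass error and
    0.03 min retention-time jitter (high-resolution Orbitrap scale),
    40% of compounds ionizing in both modes, and four planted
    coculture-enriched compounds at 8-fold.
    """

    n_families: int = 5
    compounds_per_family: int = 4
    modification_deltas: tuple[float, ...] = (14.0157, 2.0157)
    fragments_per_backbone: int = 8
    mass_error_ppm: float = 3.0
    rt_jitter_min: float = 0.03
    n_noise_peaks: int = 3
    replicate_cv: float = 0.2
    dropout_prob: float = 0.0
    dual_mode_fraction: float = 0.4
    n_planted_enriched: int = 4
    planted_fc: float = 8.0
    replicates_per_group: int = 4
    base_mass_min: float = 220.0
    family_mass_spacing: float = 70.0
    family_rt_spacing_min: float = 0.8
    seed: int = 17

    def __post_init__(self) -> None:
        if self.n_families < 1 or self.compounds_per_family < 1:
            raise ValueError("need at least one family and one compound per family")
        if self.fragments_per_backbone < 1:
            raise ValueError("fragments_per_backbone must be >= 1")
        if self.replicates_per_group < 1:
            raise ValueError("replicates_per_group must be >= 1")
        if not 0 <= self.dropout_prob < 1:
            raise ValueError("dropout_prob must be in [0, 1)")
        if not 0 <= self.dual_mode_fraction <= 1:
            raise ValueError("dual_mode_fraction must be in [0, 1]")
        if self.planted_fc < 1:
            raise ValueError("planted_fc must be >= 1")
        if self.n_planted_enriched > self.n_families * self.compounds_per_family:
            raise ValueError("more planted compounds than compounds generated")
        max_cum_delta = 0.0
        d = 0.0
        for j in range(self.compounds_per_family - 1):
            d += self.modification_deltas[j % len(self.modification_deltas)]
            max_cum_delta = max(max_cum_delta, d)
        # base masses must stay >= 50 Da apart (5 Da jitter) and members of
        # adjacent families must not collide
        if self.family_mass_spacing < max(55.0, max_cum_delta + 6.0):
            raise ValueError("family_mass_spacing too small: family masses would overlap")


@dataclass(frozen=True)
class SyntheticCompound:
    """One ground-truth compound.

    ``backbone_fragments`` is the family's shared (mz, intensity) list at
    the base mass; ``shifted_mask`` marks which fragments track the
    modification (neutral-loss-like) versus staying fixed
    (charge-retained).  ``true_group_means`` are the noiseless heights
    per group in GROUPS order.
    """

    compound_id: str
    family_id: str
    neutral_mass: float
    rt: float
    backbone_fragments: tuple[tuple[float, float], ...]
    shifted_mask: tuple[bool, ...]
    modification_delta: float
    ionizes_positive: bool
    ionizes_negative: bool
    true_group_means: tuple[float, float, float]
    planted_fc: float


@dataclass
class GroundTruth:
    """Planted structure: enough to score every pipeline stage."""

    family_of: dict[str, str]  # feature_id -> family_id
    cross_polarity_pairs: set[tuple[str, str]]  # (pos feature, neg feature)
    enriched_features: set[str]
    planted_fc: dict[str, float]  # feature_id -> true fold change
    compounds: list[SyntheticCompound] = field(default_factory=list)


def _rng(seed: int, *stream: int) -> np.random.Generator:
    return np.random.default_rng([seed, *stream])


def generate_compounds(cfg: SimulationConfig) -> list[SyntheticCompound]:
    """Generate the ground-truth compound set.

    Family base masses are spaced ``family_mass_spacing`` Da apart (well
    over the 50 Da minimum separation), base retention times
    ``family_rt_spacing_min`` apart; member *j* of a family carries the
    cumulative modification delta of *j* steps through
    ``modification_deltas`` and elutes slightly later.  The planted
    enriched compounds are a seeded random subset; their coculture mean
    is ``planted_fc`` times the (equal) monoculture means.
    """
    n_total = cfg.n_families * cfg.compounds_per_family
    planted_idx = set(
        _rng(cfg.seed, 0).choice(n_total, size=cfg.n_planted_enriched, replace=False).tolist()
    )

    compounds: list[SyntheticCompound] = []
    idx = 0
    for f in range(cfg.n_families):
        frng = _rng(cfg.seed, 1, f)
        base_mass = cfg.base_mass_min + f * cfg.family_mass_spacing + frng.uniform(0, 5)
        base_rt = 1.0 + f * cfg.family_rt_spacing_min + frng.uniform(0, 0.05)
        # evenly spaced fragments with jitter: keeps any ±50 Da window
        # below the top-k cut so the window filter preserves the backbone
        lo, hi = 60.0, base_mass - 60.0
        step = (hi - lo) / cfg.fragments_per_backbone
        frag_mz = lo + step * (np.arange(cfg.fragments_per_backbone) + frng.uniform(0.1, 0.9, cfg.fragments_per_backbone))
        frag_int = frng.uniform(20.0, 100.0, cfg.fragments_per_backbone)
        fragments = tuple(zip(frag_mz.tolist(), frag_int.tolist()))
        shifted = tuple(bool(i % 2) for i in range(cfg.fragments_per_backbone))

        for m in range(cfg.compounds_per_family):
            crng = _rng(cfg.seed, 2, idx)
            delta = 0.0
            for j in range(m):
                delta += cfg.modification_deltas[j % len(cfg.modification_deltas)]
            base_height = float(10 ** crng.uniform(4.0, 6.0))
            fc = cfg.planted_fc if idx in planted_idx else 1.0
            means = (base_height * fc, base_height, base_height)
            compounds.append(
                SyntheticCompound(
                    compound_id=f"cmp{idx:03d}",
                    family_id=f"fam{f:02d}",
                    neutral_mass=base_mass + delta,
                    rt=base_rt + 0.1 * m,
                    backbone_fragments=fragments,
                    shifted_mask=shifted,
                    modification_delta=delta,
                    ionizes_positive=True,
                    ionizes_negative=bool(crng.uniform() < cfg.dual_mode_fraction),
                    true_group_means=means,
                    planted_fc=fc,
                )
            )
            idx += 1
    return compounds


def feature_id(compound: SyntheticCompound, polarity: Polarity) -> str:
    suffix = "pos" if polarity is Polarity.POSITIVE else "neg"
    return f"{compound.compound_id}_{suffix}"


def generate_spectra(
    compounds: list[SyntheticCompound],
    polarity: Polarity | str,
    cfg: SimulationConfig,
) -> list[Ms2Spectrum]:
    """MS/MS spectra for the compounds ionizing in ``polarity``.

    Fragments marked shifted move with the compound's modification delta
    (so family members align under the precursor-shift rule); all m/z
    values, including the precursor, get a ppm-scale mass error and the
    retention time a small jitter.  Low-intensity noise peaks are drawn
    uniformly below the precursor region.  Peaks are returned sorted by
    m/z.
    """
    pol = Polarity(polarity)
    out: list[Ms2Spectrum] = []
    for k, c in enumerate(compounds):
        if pol is Polarity.POSITIVE and not c.ionizes_positive:
            continue
        if pol is Polarity.NEGATIVE and not c.ionizes_negative:
            continue
        srng = _rng(cfg.seed, 3 if pol is Polarity.POSITIVE else 4, k)
        sign = 1.0 if pol is Polarity.POSITIVE else -1.0
        precursor = c.neutral_mass + sign * PROTON_MASS_DA
        precursor *= 1.0 + srng.uniform(-cfg.mass_error_ppm, cfg.mass_error_ppm) * 1e-6

        mzs, intens = [], []
        for (fmz, fint), shifted in zip(c.backbone_fragments, c.shifted_mask):
            mz = fmz + (c.modification_delta if shifted else 0.0)
            mz *= 1.0 + srng.uniform(-cfg.mass_error_ppm, cfg.mass_error_ppm) * 1e-6
            mzs.append(mz)
            intens.append(fint)
        for _ in range(cfg.n_noise_peaks):
            mzs.append(float(srng.uniform(60.0, precursor - 25.0)))
            intens.append(float(srng.uniform(1.0, 8.0)))

        order = np.argsort(mzs)
        mz_arr = np.asarray(mzs)[order]
        int_arr = np.asarray(intens)[order]
        # collapse pathological exact collisions to keep m/z strictly ascending
        keep = np.concatenate(([True], np.diff(mz_arr) > 0))
        rt = max(0.0, c.rt + float(srng.uniform(-cfg.rt_jitter_min, cfg.rt_jitter_min)))
        out.append(
            Ms2Spectrum(
                feature_id=feature_id(c, pol),
                precursor_mz=float(precursor),
                polarity=pol,
                rt=rt,
                mz=mz_arr[keep],
                intensity=int_arr[keep],
            )
        )
    return out


def generate_feature_table(
    compounds: list[SyntheticCompound], cfg: SimulationConfig
) -> tuple[FeatureTable, GroundTruth]:
    """Feature table (one row per ionized compound-polarity pair) plus
    ground truth.

    Replicate heights are ``group mean x LogNormal(0, replicate_cv)``,
    zeroed with probability ``dropout_prob`` (dropout acts before
    normalization, emulating non-detection).  The design covers one
    condition with three groups of ``replicates_per_group`` samples.
    """
    samples = []
    for grp in GROUPS:
        for r in range(cfg.replicates_per_group):
            samples.append((f"{grp}_r{r + 1}", grp))
    design = pd.DataFrame(
        {"group": [g for _, g in samples], "condition": "default"},
        index=pd.Index([s for s, _ in samples], name="sample_id"),
    )

    rows, meta = [], []
    truth = GroundTruth(
        family_of={}, cross_polarity_pairs=set(), enriched_features=set(), planted_fc={},
        compounds=list(compounds),
    )
    fidx = 0
    for c in compounds:
        pols = []
        if c.ionizes_positive:
            pols.append(Polarity.POSITIVE)
        if c.ionizes_negative:
            pols.append(Polarity.NEGATIVE)
        if c.ionizes_positive and c.ionizes_negative:
            truth.cross_polarity_pairs.add(
                (feature_id(c, Polarity.POSITIVE), feature_id(c, Polarity.NEGATIVE))
            )
        for pol in pols:
            fid = feature_id(c, pol)
            frng = _rng(cfg.seed, 5, fidx)
            fidx += 1
            heights = []
            for grp_i, grp in enumerate(GROUPS):
                mean = c.true_group_means[grp_i]
                vals = mean * frng.lognormal(0.0, cfg.replicate_cv, cfg.replicates_per_group)
                if cfg.dropout_prob > 0:
                    vals = np.where(
                        frng.uniform(size=cfg.replicates_per_group) < cfg.dropout_prob, 0.0, vals
                    )
                heights.extend(vals.tolist())
            rows.append(heights)
            sign = 1.0 if pol is Polarity.POSITIVE else -1.0
            meta.append(
                {
                    "feature_id": fid,
                    "mz": c.neutral_mass + sign * PROTON_MASS_DA,
                    "rt": c.rt,
                    "polarity": pol.value,
                }
            )
            truth.family_of[fid] = c.family_id
            truth.planted_fc[fid] = c.planted_fc
            if c.planted_fc > 1:
                truth.enriched_features.add(fid)

    features = pd.DataFrame(meta).set_index("feature_id")
    heights = pd.DataFrame(rows, index=features.index, columns=design.index)
    return FeatureTable(features, heights, design), truth


def generate_dataset(
    cfg: SimulationConfig,
) -> tuple[list[Ms2Spectrum], list[Ms2Spectrum], FeatureTable, GroundTruth]:
    """Convenience wrapper: compounds -> (positive spectra, negative
    spectra, feature table, ground truth)."""
    compounds = generate_compounds(cfg)
    pos = generate_spectra(compounds, Polarity.POSITIVE, cfg)
    neg = generate_spectra(compounds, Polarity.NEGATIVE, cfg)
    table, truth = generate_feature_table(compounds, cfg)
    return pos, neg, table, truth
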
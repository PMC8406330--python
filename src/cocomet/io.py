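"""File formats: MGF spectra, feature/design CSVs, GraphML export.

MGF (Mascot generic format) is the interchange dialect used by GNPS: one
``BEGIN IONS``/``END IONS`` block per feature with ``PEPMASS``, a
retention time (``RTINSECONDS`` or ``RTINMINUTES``), and a charge or ion
mode.  Retention times are converted to minutes on read; everything
internal is minutes.
"""

from __future__ import annotations

from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from pyteomics import mgf as _mgf

from .quantify import FeatureTable
from .spectra import Ms2Spectrum, Polarity

__all__ = [
    "read_mgf",
    "write_mgf",
    "read_feature_csv",
    "write_graphml",
]

_VALID_POLARITIES = {p.value for p in Polarity}


def _entry_polarity(params: dict, index: int) -> Polarity:
    mode = params.get("ionmode") or params.get("ion_mode") or params.get("ion mode")
    if mode is not None:
        mode = str(mode).strip().lower()
        if mode in _VALID_POLARITIES:
            return Polarity(mode)
        raise ValueError(f"MGF entry {index}: unknown ion mode {mode!r}")
    charge = params.get("charge")
    if charge:
        ch = charge[0] if isinstance(charge, (list, tuple)) else charge
        return Polarity.POSITIVE if int(ch) > 0 else Polarity.NEGATIVE
    raise ValueError(f"MGF entry {index}: no IONMODE or CHARGE")


def _entry_rt_minutes(params: dict, index: int) -> float:
    if "rtinminutes" in params:
        return float(params["rtinminutes"])
    if "rtinseconds" in params:
        return float(params["rtinseconds"]) / 60.0
    raise ValueError(f"MGF entry {index}: no RTINSECONDS or RTINMINUTES")


def read_mgf(path: str | Path) -> list[Ms2Spectrum]:
    """Read an MGF file into spectra (RT in minutes).

    Each entry must carry a precursor mass (``PEPMASS``), a retention
    time and a charge or ion mode; a malformed entry raises with its
    0-based entry index.
    """
    spectra: list[Ms2Spectrum] = []
    with _mgf.MGF(str(path), convert_arrays=1) as reader:
        for i, entry in enumerate(reader):
            params = entry.get("params", {})
            pepmass = params.get("pepmass")
            if not pepmass or pepmass[0] is None:
                raise ValueError(f"MGF entry {i}: missing PEPMASS")
            fid = str(params.get("title") or params.get("feature_id") or f"spectrum_{i}")
            mz = np.asarray(entry["m/z array"], dtype=float)
            inten = np.asarray(entry["intensity array"], dtype=float)
            order = np.argsort(mz, kind="stable")
            spectra.append(
                Ms2Spectrum(
                    feature_id=fid,
                    precursor_mz=float(pepmass[0]),
                    polarity=_entry_polarity(params, i),
                    rt=_entry_rt_minutes(params, i),
                    mz=mz[order],
                    intensity=inten[order],
                )
            )
    return spectra


def write_mgf(spectra: list[Ms2Spectrum], path: str | Path) -> None:
    """Write spectra to MGF (RT as RTINSECONDS, charge 1+/1-)."""
    entries = []
    for s in spectra:
        charge = "1+" if s.polarity is Polarity.POSITIVE else "1-"
        entries.append(
            {
                "m/z array": s.mz,
                "intensity array": s.intensity,
                "params": {
                    "title": s.feature_id,
                    "pepmass": (s.precursor_mz, None),
                    "rtinseconds": s.rt * 60.0,
                    "charge": charge,
                    "ionmode": s.polarity.value,
                },
            }
        )
    _mgf.write(entries, str(path), file_mode="w")


def read_feature_csv(path: str | Path, design_path: str | Path) -> FeatureTable:
    """Read a feature table CSV and its design CSV.

    The feature CSV needs columns ``feature_id``, ``mz``, ``rt``,
    ``polarity`` plus one column per sample; the design CSV maps
    ``sample_id`` to ``group`` and ``condition``.  Validation (duplicate
    ids, negative heights, unknown polarities, design/table sample
    mismatches) raises with the offending entry named.
    """
    df = pd.read_csv(path)
    required = ["feature_id", "mz", "rt", "polarity"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"feature CSV missing columns: {missing}")
    bad_pol = set(df["polarity"].unique()) - _VALID_POLARITIES
    if bad_pol:
        raise ValueError(f"unknown polarity strings: {sorted(bad_pol)}")
    design = pd.read_csv(design_path)
    for col in ("sample_id", "group", "condition"):
        if col not in design.columns:
            raise ValueError(f"design CSV missing column {col!r}")
    design = design.set_index("sample_id")

    features = df.set_index("feature_id")[["mz", "rt", "polarity"]]
    sample_cols = [c for c in df.columns if c not in required]
    heights = df.set_index("feature_id")[sample_cols].astype(float)
    return FeatureTable(features, heights, design)


def write_feature_csv(table: FeatureTable, path: str | Path, design_path: str | Path) -> None:
    """Inverse of :func:`read_feature_csv`."""
    out = table.features.join(table.heights).reset_index()
    out = out.rename(columns={out.columns[0]: "feature_id"})
    out.to_csv(path, index=False)
    table.design.reset_index().rename(columns={"index": "sample_id"}).to_csv(
        design_path, index=False
    )


def write_graphml(
    network: nx.Graph,
    path: str | Path,
    styles: pd.DataFrame | None = None,
    means: pd.DataFrame | None = None,
    annotations: dict | None = None,
) -> None:
    """Write the network as GraphML readable by Cytoscape and friends.

    Node attributes already on the graph (m/z, RT, polarity, neutral
    mass, members) are kept; optional per-node ``styles`` (hue/alpha),
    group ``means`` and library ``annotations`` are attached.  A neutral
    (gray) node gets ``hue = -1``.
    """
    g = network.copy()
    for node, data in g.nodes(data=True):
        if "members" in data:
            data["members"] = ";".join(data["members"])
        if styles is not None and node in styles.index:
            hue = styles.loc[node, "hue"]
            data["hue"] = -1.0 if pd.isna(hue) else float(hue)
            data["alpha"] = float(styles.loc[node, "alpha"])
        if means is not None:
            key = next(
                (k for k in [node, *str(node).split("+")] if k in means.index), None
            )
            if key is not None:
                for grp in means.columns:
                    data[f"mean_{grp}"] = float(means.loc[key, grp])
        if annotations and node in annotations:
            data["library_annotation"] = str(annotations[node])
    for _, _, data in g.edges(data=True):
        data["score"] = float(data.get("score", 0.0))
        data["n_matched"] = int(data.get("n_matched", 0))
    nx.write_graphml(g, str(path))
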
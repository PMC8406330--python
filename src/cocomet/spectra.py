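"""MS/MS spectrum representation, spectral cleanup filters, and the
modified cosine similarity.

The two filters reproduce the standard GNPS preprocessing applied to every
fragmentation spectrum before networking:

1. :func:`remove_precursor_region` deletes fragment peaks close to the
   precursor m/z (these carry little structural information and inflate
   similarity between unrelated spectra).
2. :func:`window_filter_top_k` keeps, for every peak, only peaks that rank
   within the top *k* by intensity inside a sliding m/z window centred on
   that peak — a local noise filter.

:func:`modified_cosine` scores two filtered spectra.  Unlike a plain cosine,
fragment peaks may match either directly (same m/z within tolerance) or
offset by the difference between the two precursor masses, so that spectra
of structurally related compounds (e.g. differing by a CH2) still align on
their shared backbone fragments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Sequence

import numpy as np

__all__ = [
    "Polarity",
    "Ms2Spectrum",
    "SimilarityResult",
    "ToleranceConfig",
    "remove_precursor_region",
    "window_filter_top_k",
    "filter_spectrum",
    "modified_cosine",
]

PROTON_MASS_DA = 1.007276466


class Polarity(str, Enum):
    """Ionization mode; positive assumed [M+H]+, negative [M-H]-."""

    POSITIVE = "positive"
    NEGATIVE = "negative"


@dataclass(frozen=True)
class Ms2Spectrum:
    """One feature's representative fragmentation spectrum.

    Parameters
    ----------
    feature_id : str
        Opaque feature identifier.
    precursor_mz : float
        Precursor ion m/z in Da; must be positive.
    polarity : Polarity
        Ionization mode.
    rt : float
        Retention time in minutes; non-negative.
    mz : ndarray
        Fragment m/z values in Da, strictly ascending.
    intensity : ndarray
        Non-negative fragment intensities (arbitrary units), aligned
        with ``mz``.
    """

    feature_id: str
    precursor_mz: float
    polarity: Polarity
    rt: float
    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        mz = np.asarray(self.mz, dtype=float)
        inten = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "mz", mz)
        object.__setattr__(self, "intensity", inten)
        if mz.ndim != 1 or inten.shape != mz.shape:
            raise ValueError("mz and intensity must be 1-D and aligned")
        if self.precursor_mz <= 0:
            raise ValueError(f"precursor_mz must be positive, got {self.precursor_mz}")
        if self.rt < 0:
            raise ValueError(f"rt must be non-negative, got {self.rt}")
        if mz.size:
            if np.any(mz <= 0):
                raise ValueError("fragment m/z values must be positive")
            if np.any(inten < 0):
                raise ValueError("fragment intensities must be non-negative")
            if np.any(np.diff(mz) <= 0):
                raise ValueError("fragment m/z values must be strictly ascending")

    def __len__(self) -> int:
        return int(self.mz.size)

    @property
    def peaks(self) -> list[tuple[float, float]]:
        """Peak list as (mz, intensity) tuples, ascending m/z."""
        return list(zip(self.mz.tolist(), self.intensity.tolist()))

    def with_peaks(self, mz: np.ndarray, intensity: np.ndarray) -> "Ms2Spectrum":
        return replace(self, mz=np.asarray(mz, float), intensity=np.asarray(intensity, float))


@dataclass(frozen=True)
class SimilarityResult:
    """Outcome of a modified-cosine comparison.

    ``score`` lies in [0, 1] (up to float round-off), ``pairs`` holds the
    accepted one-to-one peak index pairs (index into spectrum a, index into
    spectrum b) and ``n_matched == len(pairs)``.
    """

    score: float
    n_matched: int
    pairs: tuple[tuple[int, int], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.n_matched != len(self.pairs):
            raise ValueError("n_matched must equal len(pairs)")


@dataclass(frozen=True)
class ToleranceConfig:
    """Mass tolerances and filter windows, all in Da.

    Defaults are the standard GNPS feature-based molecular networking
    parameters: 0.05 Da precursor and fragment tolerance, precursor-region
    removal of ±17 Da, and top-6 peaks per ±50 Da window.
    """

    fragment_tol_da: float = 0.05
    precursor_tol_da: float = 0.05
    precursor_window_da: float = 17.0
    window_da: float = 50.0
    window_top_k: int = 6

    def __post_init__(self) -> None:
        for name in ("fragment_tol_da", "precursor_tol_da", "precursor_window_da", "window_da"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.window_top_k < 1:
            raise ValueError("window_top_k must be >= 1")


def remove_precursor_region(spectrum: Ms2Spectrum, window: float = 17.0) -> Ms2Spectrum:
    """Remove all fragment peaks within ±``window`` Da of the precursor m/z.

    The boundary is inclusive: a peak exactly ``window`` Da from the
    precursor is removed (the conservative reading of "within").
    """
    if window <= 0:
        raise ValueError("window must be positive")
    keep = np.abs(spectrum.mz - spectrum.precursor_mz) > window
    return spectrum.with_peaks(spectrum.mz[keep], spectrum.intensity[keep])


def window_filter_top_k(spectrum: Ms2Spectrum, window: float = 50.0, k: int = 6) -> Ms2Spectrum:
    """Keep a peak iff it is among the top ``k`` most intense peaks within
    ±``window`` Da of its own m/z (itself included).

    Intensity-rank ties are broken by ascending m/z, so the result is
    deterministic.  The filter is idempotent: removing peaks can only
    improve the rank of the survivors.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    if k < 1:
        raise ValueError("k must be >= 1")
    mz, inten = spectrum.mz, spectrum.intensity
    n = mz.size
    if n <= k:
        return spectrum
    keep = np.zeros(n, dtype=bool)
    lo = np.searchsorted(mz, mz - window, side="left")
    hi = np.searchsorted(mz, mz + window, side="right")
    for i in range(n):
        idx = np.arange(lo[i], hi[i])
        # rank within window: higher intensity first, ties by ascending mz
        order = sorted(idx, key=lambda j: (-inten[j], mz[j]))
        keep[i] = i in order[:k]
    return spectrum.with_peaks(mz[keep], inten[keep])


def filter_spectrum(spectrum: Ms2Spectrum, tol: ToleranceConfig | None = None) -> Ms2Spectrum:
    """Apply the full GNPS preprocessing: precursor-region removal, then
    windowed top-k filtering."""
    tol = tol or ToleranceConfig()
    s = remove_precursor_region(spectrum, tol.precursor_window_da)
    return window_filter_top_k(s, tol.window_da, tol.window_top_k)


def _normalized_intensities(intensity: np.ndarray) -> np.ndarray:
    # sqrt transform then unit L2 norm: identical spectra score exactly 1
    w = np.sqrt(intensity)
    norm = math.sqrt(float(np.dot(w, w)))
    if norm == 0.0:
        return w
    return w / norm


def modified_cosine(
    a: Ms2Spectrum, b: Ms2Spectrum, tol: ToleranceConfig | None = None
) -> SimilarityResult:
    """Modified cosine similarity between two (already filtered) spectra.

    Intensities are square-root transformed and L2-normalised per spectrum.
    A peak pair (i, j) is a candidate when either

    * ``|mz_a[i] - mz_b[j]| <= fragment_tol_da`` (direct match), or
    * ``|mz_a[i] + dprec - mz_b[j]| <= fragment_tol_da`` with
      ``dprec = precursor_b - precursor_a`` (precursor-shifted match).

    A one-to-one pairing is chosen greedily by descending intensity
    product, ties broken by ascending m/z in a then in b; the score is the
    sum of products over accepted pairs.  Symmetric in its arguments.
    """
    tol = tol or ToleranceConfig()
    na, nb = len(a), len(b)
    if na == 0 or nb == 0:
        return SimilarityResult(score=0.0, n_matched=0)

    wa = _normalized_intensities(a.intensity)
    wb = _normalized_intensities(b.intensity)
    dprec = b.precursor_mz - a.precursor_mz
    ftol = tol.fragment_tol_da

    candidates: list[tuple[float, float, float, int, int]] = []
    seen: set[tuple[int, int]] = set()
    for shift in (0.0, dprec):
        for i in range(na):
            target = a.mz[i] + shift
            j0 = int(np.searchsorted(b.mz, target - ftol, side="left"))
            j1 = int(np.searchsorted(b.mz, target + ftol, side="right"))
            for j in range(j0, j1):
                if (i, j) in seen:
                    continue
                seen.add((i, j))
                candidates.append((wa[i] * wb[j], a.mz[i], b.mz[j], i, j))

    # greedy: descending product, ties by ascending mz_a then mz_b
    candidates.sort(key=lambda c: (-c[0], c[1], c[2]))
    used_a: set[int] = set()
    used_b: set[int] = set()
    pairs: list[tuple[int, int]] = []
    score = 0.0
    for prod, _, _, i, j in candidates:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        pairs.append((i, j))
        score += prod
    if not pairs:
        return SimilarityResult(score=0.0, n_matched=0)
    return SimilarityResult(score=float(score), n_matched=len(pairs), pairs=tuple(pairs))


def spectrum_from_peaks(
    feature_id: str,
    precursor_mz: float,
    polarity: Polarity | str,
    rt: float,
    peaks: Sequence[tuple[float, float]],
) -> Ms2Spectrum:
    """Build a spectrum from an unordered (mz, intensity) peak list."""
    pol = Polarity(polarity)
    peaks = sorted(peaks)
    mz = np.array([p[0] for p in peaks], dtype=float)
    inten = np.array([p[1] for p in peaks], dtype=float)
    return Ms2Spectrum(feature_id, precursor_mz, pol, rt, mz, inten)
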
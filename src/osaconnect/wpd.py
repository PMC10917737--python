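"""Wavelet packet band separation of sleep EEG.

A level-5 Daubechies-4 wavelet packet decomposition splits each channel into
2^5 = 32 equal-width leaves of fs/64 Hz each (3.125 Hz at 200 Hz sampling).
Leaves are stored in natural (filter-path) order; because every high-pass
decimation mirrors the spectrum, natural order is NOT ascending frequency
order — a binary-reflected Gray code permutation recovers it, and all
band-to-leaf mapping goes through that permutation.

Each clinical band (delta, theta, alpha, beta, gamma) is the set of leaves
whose center frequency falls inside the band; its features are the absolute
values of the concatenated leaf coefficients, and its band signal is the
inverse transform with all out-of-band leaves zeroed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pywt

__all__ = [
    "WaveletSpec",
    "BandDefinition",
    "DEFAULT_BANDS",
    "PacketTree",
    "BandFeatures",
    "EmptyBandError",
    "wpd_decompose",
    "reconstruct",
    "frequency_order",
    "band_leaf_map",
    "extract_band",
]


class EmptyBandError(ValueError):
    """A band definition captures no wavelet-packet leaf."""


@dataclass(frozen=True)
class WaveletSpec:
    """Wavelet family, decomposition depth and boundary handling."""

    family: str = "db4"
    level: int = 5
    boundary_mode: str = "periodization"

    def __post_init__(self) -> None:
        if self.level < 1:
            raise ValueError("level must be >= 1")
        if self.family not in pywt.wavelist(kind="discrete"):
            raise ValueError(f"unknown wavelet family {self.family!r}")
        if self.boundary_mode not in pywt.Modes.modes:
            raise ValueError(f"unknown boundary mode {self.boundary_mode!r}")

    @property
    def n_leaves(self) -> int:
        return 2 ** self.level


@dataclass(frozen=True)
class BandDefinition:
    """A named frequency band [f_low, f_high) in Hz."""

    name: str
    f_low: float
    f_high: float

    def __post_init__(self) -> None:
        if not 0 <= self.f_low < self.f_high:
            raise ValueError(f"invalid band {self.name}: [{self.f_low}, {self.f_high})")

    def contains(self, freq: float) -> bool:
        return self.f_low <= freq < self.f_high


#: conventional clinical sleep-EEG band edges; gamma capped at the 35 Hz
#: band-pass corner
DEFAULT_BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("delta", 0.5, 4.0),
    BandDefinition("theta", 4.0, 8.0),
    BandDefinition("alpha", 8.0, 13.0),
    BandDefinition("beta", 13.0, 30.0),
    BandDefinition("gamma", 30.0, 35.0),
)

BAND_ORDER = tuple(b.name for b in DEFAULT_BANDS)


def _natural_paths(level: int) -> list[str]:
    """Leaf paths in natural (filter-path) order: 'a'=low-pass, 'd'=high-pass."""
    paths = [""]
    for _ in range(level):
        paths = [p + c for p in paths for c in "ad"]
    return paths


@dataclass
class PacketTree:
    """Leaf coefficients of a full wavelet packet decomposition.

    ``leaves`` are in natural order; use :func:`frequency_order` to address
    them by ascending pass-band.
    """

    spec: WaveletSpec
    leaves: list[np.ndarray] = field(repr=False)
    n_samples: int

    def __post_init__(self) -> None:
        if len(self.leaves) != self.spec.n_leaves:
            raise ValueError(
                f"expected {self.spec.n_leaves} leaves, got {len(self.leaves)}"
            )

    @property
    def n_coefficients(self) -> int:
        return sum(len(lv) for lv in self.leaves)

    def leaf_energies(self) -> np.ndarray:
        """Energy per leaf, natural order."""
        return np.array([float(np.sum(lv**2)) for lv in self.leaves])


def wpd_decompose(x: np.ndarray, spec: WaveletSpec = WaveletSpec()) -> PacketTree:
    """Full wavelet packet decomposition of a 1-D signal down to ``spec.level``."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("signal must be 1-D")
    if len(x) < spec.n_leaves:
        raise ValueError(
            f"signal of {len(x)} samples too short for level {spec.level} "
            f"({spec.n_leaves} leaves)"
        )
    wp = pywt.WaveletPacket(
        data=x, wavelet=spec.family, mode=spec.boundary_mode, maxlevel=spec.level
    )
    leaves = [np.asarray(wp[p].data, dtype=float) for p in _natural_paths(spec.level)]
    return PacketTree(spec=spec, leaves=leaves, n_samples=len(x))


def reconstruct(tree: PacketTree, keep_natural: set[int] | None = None) -> np.ndarray:
    """Inverse transform, optionally keeping only a subset of leaves.

    Parameters
    ----------
    keep_natural : set of natural-order leaf indices, or None for all.

    Returns a signal of ``tree.n_samples`` samples.  The inverse is linear in
    the leaves, so reconstructions from disjoint subsets add up.
    """
    spec = tree.spec
    # seed with zeros of the original length so per-level padding (and the
    # final crop) match the forward transform exactly
    wp = pywt.WaveletPacket(
        data=np.zeros(tree.n_samples),
        wavelet=spec.family,
        mode=spec.boundary_mode,
        maxlevel=spec.level,
    )
    wp.get_level(spec.level)
    for i, path in enumerate(_natural_paths(spec.level)):
        if keep_natural is None or i in keep_natural:
            wp[path].data = tree.leaves[i]
    out = wp.reconstruct(update=False)
    return np.asarray(out, dtype=float)[: tree.n_samples]


def frequency_order(level: int) -> np.ndarray:
    """Natural-order leaf index at each ascending-frequency position.

    Position ``k`` of the returned permutation holds the natural (filter
    path) index of the leaf whose pass-band is approximately
    ``[k, k+1] * fs / 2^(level+1)``.  Each high-pass decimation stage mirrors
    the spectrum of its branch, so the permutation is the binary-reflected
    Gray code ``k ^ (k >> 1)``.
    """
    if level < 1:
        raise ValueError("level must be >= 1")
    k = np.arange(2**level)
    return k ^ (k >> 1)


def leaf_width_hz(fs: float, level: int) -> float:
    """Width in Hz of one wavelet-packet leaf at the given level."""
    return fs / 2.0 / 2**level


def leaf_centers_hz(fs: float, level: int) -> np.ndarray:
    """Center frequencies of the frequency-ordered leaves."""
    w = leaf_width_hz(fs, level)
    return (np.arange(2**level) + 0.5) * w


def band_leaf_map(
    fs: float,
    level: int,
    bands: tuple[BandDefinition, ...] = DEFAULT_BANDS,
) -> dict[str, list[int]]:
    """Assign frequency-ordered leaf indices to bands by center frequency.

    Each leaf belongs to the (single) band containing its center frequency;
    leaves whose center lies in no band are left unassigned.  Overlapping
    band definitions are rejected.
    """
    ordered = sorted(bands, key=lambda b: b.f_low)
    for lo, hi in zip(ordered, ordered[1:]):
        if hi.f_low < lo.f_high:
            raise ValueError(
                f"bands {lo.name} and {hi.name} overlap "
                f"([{lo.f_low}, {lo.f_high}) vs [{hi.f_low}, {hi.f_high}))"
            )
    if max(b.f_high for b in bands) > fs / 2:
        raise ValueError("band extends beyond the Nyquist frequency")
    centers = leaf_centers_hz(fs, level)
    return {
        b.name: [int(k) for k, c in enumerate(centers) if b.contains(c)]
        for b in bands
    }


@dataclass
class BandFeatures:
    """Per-band features of one channel.

    ``abs_coeffs`` — absolute values of the band's leaf coefficients,
    concatenated in ascending-frequency leaf order; the feature vector the
    connectivity analysis correlates.
    ``band_signal`` — the band-limited time series reconstructed from the
    band's leaves alone.
    """

    band: BandDefinition
    abs_coeffs: np.ndarray
    band_signal: np.ndarray
    leaf_indices: list[int]

    def __post_init__(self) -> None:
        if np.any(self.abs_coeffs < 0):
            raise ValueError("abs_coeffs must be non-negative")


def extract_band(
    tree: PacketTree,
    band: BandDefinition,
    fs: float,
    leaf_map: dict[str, list[int]] | None = None,
    bands: tuple[BandDefinition, ...] = DEFAULT_BANDS,
) -> BandFeatures:
    """Absolute-coefficient features and reconstructed signal for one band."""
    if leaf_map is None:
        leaf_map = band_leaf_map(fs, tree.spec.level, bands)
    freq_idx = leaf_map.get(band.name, [])
    if not freq_idx:
        raise EmptyBandError(
            f"band {band.name} [{band.f_low}, {band.f_high}) Hz captures no "
            f"leaf at fs={fs}, level={tree.spec.level}"
        )
    order = frequency_order(tree.spec.level)
    natural = [int(order[k]) for k in freq_idx]
    abs_coeffs = np.concatenate([np.abs(tree.leaves[i]) for i in natural])
    band_signal = reconstruct(tree, keep_natural=set(natural))
    return BandFeatures(
        band=band, abs_coeffs=abs_coeffs, band_signal=band_signal,
        leaf_indices=list(freq_idx),
    )


def band_features_channel(
    x: np.ndarray,
    fs: float,
    spec: WaveletSpec = WaveletSpec(),
    bands: tuple[BandDefinition, ...] = DEFAULT_BANDS,
    with_signals: bool = True,
) -> dict[str, BandFeatures]:
    """Decompose one channel and extract every band's features.

    ``with_signals=False`` skips the inverse transforms (the expensive part)
    and leaves ``band_signal`` empty — sufficient for connectivity, which
    uses only the absolute coefficients.
    """
    tree = wpd_decompose(x, spec)
    leaf_map = band_leaf_map(fs, spec.level, bands)
    order = frequency_order(spec.level)
    out: dict[str, BandFeatures] = {}
    for b in bands:
        freq_idx = leaf_map.get(b.name, [])
        if not freq_idx:
            raise EmptyBandError(
                f"band {b.name} captures no leaf at fs={fs}, level={spec.level}"
            )
        natural = [int(order[k]) for k in freq_idx]
        abs_coeffs = np.concatenate([np.abs(tree.leaves[i]) for i in natural])
        sig = (
            reconstruct(tree, keep_natural=set(natural))
            if with_signals
            else np.empty(0)
        )
        out[b.name] = BandFeatures(
            band=b, abs_coeffs=abs_coeffs, band_signal=sig,
            leaf_indices=list(freq_idx),
        )
    return out
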
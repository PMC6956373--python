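"""Wavelet-packet band features F12-F19.

A level-5 discrete wavelet packet transform (db4, periodization mode, hence
orthogonal and energy preserving) decomposes the 4-45 Hz filtered signal
into dyadic sub-bands.  Five packets covering theta (4-8 Hz), alpha
(8-12 Hz), low beta (14-16 Hz), high beta (16-32 Hz) and gamma (32-40 Hz)
are selected — at different tree levels, since the bands have different
widths — and eight features are computed from them:

F12  total energy of the concatenated packet coefficients
F13  population standard deviation of the concatenated coefficients
F14  sum over packets of the Shannon entropy of each packet's normalized
     squared coefficients (natural log)
F15-F19  band power per packet: the Welch PSD of the packet's band-limited
     reconstruction, integrated over the packet's band.

Packet indexing is frequency-ordered; with natural (Paley) ordering the
band <-> index map is non-monotone, which is the classic wavelet-packet
pitfall.  Each node's band is computed explicitly as
[(fs/2) i / 2^L, (fs/2)(i+1) / 2^L).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt
from scipy.signal import welch

from .errors import ResolutionError, SignalLengthError

WAVELET_FEATURE_NAMES = [f"F{i}" for i in range(12, 20)]

#: the five selected packets, in feature order (F15..F19)
SELECTED_BANDS: list[tuple[float, float]] = [
    (4.0, 8.0),
    (8.0, 12.0),
    (14.0, 16.0),
    (16.0, 32.0),
    (32.0, 40.0),
]

#: named band map exposed for configuration
BAND_MAP: dict[str, tuple[float, float]] = {
    "theta": (4.0, 8.0),
    "alpha": (8.0, 12.0),
    "beta_low": (14.0, 16.0),
    "beta_high": (16.0, 32.0),
    "gamma": (32.0, 40.0),
}

#: Welch estimator settings (2-s Hann segments, 50% overlap, mean average)
WELCH_NPERSEG = 256
WELCH_NOVERLAP = 128


@dataclass
class WPTNode:
    """One wavelet-packet node with its frequency-ordered position."""

    level: int
    freq_index: int
    band: tuple[float, float]
    coefficients: np.ndarray
    path: str


class WPTree:
    """Full wavelet packet tree of a single-channel signal."""

    def __init__(
        self,
        x: np.ndarray,
        fs: float,
        wavelet: str = "db4",
        max_level: int = 5,
        mode: str = "periodization",
    ) -> None:
        x = np.asarray(x, dtype=float)
        if x.ndim != 1:
            raise ValueError("signal must be 1-D")
        if x.size < 2**max_level:
            raise SignalLengthError(
                f"signal of {x.size} samples too short for a level-"
                f"{max_level} packet transform"
            )
        if wavelet not in pywt.wavelist(kind="discrete"):
            raise ValueError(f"unknown wavelet {wavelet!r}")
        self.fs = float(fs)
        self.wavelet = wavelet
        self.mode = mode
        self.max_level = max_level
        self.n_samples = x.size
        self._wp = pywt.WaveletPacket(
            data=x, wavelet=wavelet, mode=mode, maxlevel=max_level
        )

    def nodes_at_level(self, level: int) -> list[WPTNode]:
        """Frequency-ordered nodes of one level, with explicit bands."""
        if not (1 <= level <= self.max_level):
            raise ValueError(f"level {level} outside 1..{self.max_level}")
        width = (self.fs / 2.0) / 2**level
        nodes = self._wp.get_level(level, order="freq")
        return [
            WPTNode(
                level=level,
                freq_index=i,
                band=(i * width, (i + 1) * width),
                coefficients=np.asarray(node.data, dtype=float),
                path=node.path,
            )
            for i, node in enumerate(nodes)
        ]

    def node_for_band(self, lo: float, hi: float) -> WPTNode:
        """The unique node whose band is exactly [lo, hi), if dyadic."""
        nyquist = self.fs / 2.0
        width = hi - lo
        ratio = nyquist / width
        level = np.log2(ratio)
        if abs(level - round(level)) > 1e-9:
            raise ResolutionError(
                f"band [{lo}, {hi}) Hz not representable at fs={self.fs}"
            )
        level = int(round(level))
        if not (1 <= level <= self.max_level):
            raise ResolutionError(
                f"band [{lo}, {hi}) Hz needs level {level}, tree has "
                f"{self.max_level}"
            )
        index = lo / width
        if abs(index - round(index)) > 1e-9:
            raise ResolutionError(
                f"band [{lo}, {hi}) Hz not aligned to the dyadic grid"
            )
        return self.nodes_at_level(level)[int(round(index))]

    def reconstruct_node(self, node: WPTNode) -> np.ndarray:
        """Band-limited time-domain reconstruction from a single packet."""
        wp = pywt.WaveletPacket(
            data=None, wavelet=self.wavelet, mode=self.mode,
            maxlevel=self.max_level,
        )
        wp[node.path] = node.coefficients
        rec = wp.reconstruct(update=False)
        return np.asarray(rec[: self.n_samples], dtype=float)


@dataclass
class BandSelection:
    """The five selected packets, in F15..F19 band order."""

    nodes: list[WPTNode]
    tree: WPTree

    def __post_init__(self) -> None:
        if len(self.nodes) != 5:
            raise ValueError("band selection must hold exactly five packets")


def wpt_decompose(
    x: np.ndarray, fs: float, wavelet: str = "db4", max_level: int = 5
) -> WPTree:
    """Level-`max_level` wavelet packet transform with explicit band maps."""
    return WPTree(x, fs, wavelet=wavelet, max_level=max_level)


def select_band_nodes(tree: WPTree) -> BandSelection:
    """Pick the theta/alpha/low-beta/high-beta/gamma packets.

    The delta band (0-4 Hz) is absent from the bandpass-filtered data and
    is never selected; 12-14 Hz and >40 Hz regions are likewise unused.
    """
    nodes = [tree.node_for_band(lo, hi) for lo, hi in SELECTED_BANDS]
    return BandSelection(nodes=nodes, tree=tree)


def _node_entropy(c: np.ndarray) -> float:
    energy = float(np.sum(c**2))
    if energy == 0.0:
        return 0.0
    p = c**2 / energy
    p = p[p > 0]
    return float(-np.sum(p * np.log(p)))


def band_power(rec: np.ndarray, fs: float, lo: float, hi: float) -> float:
    """Welch-PSD band power of a reconstruction over [lo, hi) Hz."""
    nperseg = min(WELCH_NPERSEG, rec.size)
    f, psd = welch(
        rec, fs=fs, window="hann", nperseg=nperseg,
        noverlap=nperseg // 2, average="mean",
    )
    mask = (f >= lo) & (f < hi)
    if mask.sum() < 2:
        return 0.0
    return float(np.trapezoid(psd[mask], f[mask]))


def wavelet_features(sel: BandSelection) -> np.ndarray:
    """Compute F12..F19 from a band selection."""
    coeffs = [node.coefficients for node in sel.nodes]
    if any(c.size == 0 for c in coeffs):
        raise RuntimeError("empty coefficient vector in band selection")
    concat = np.concatenate(coeffs)
    energy = float(np.sum(concat**2))
    std = float(concat.std())  # population
    entropy_sum = float(sum(_node_entropy(c) for c in coeffs))
    powers = [
        band_power(sel.tree.reconstruct_node(node), sel.tree.fs, *node.band)
        for node in sel.nodes
    ]
    return np.array([energy, std, entropy_sum, *powers])


def wavelet_feature_vector(
    x: np.ndarray, fs: float, wavelet: str = "db4", max_level: int = 5
) -> np.ndarray:
    """Decompose, select bands, and compute F12..F19 in one call."""
    tree = wpt_decompose(x, fs, wavelet=wavelet, max_level=max_level)
    return wavelet_features(select_band_nodes(tree))
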
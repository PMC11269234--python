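"""Wavelet-packet multi-resolution analysis.

A full binary wavelet-packet tree splits both the approximation and the
detail branch at every level, so level ``l`` has 2^l terminal nodes, each
covering an equal frequency band of width fs / 2^(l+1). Terminal nodes
are returned in frequency (sequency) order: band center frequency is
strictly increasing with node index. Level 7 — the default — yields the
128 bands the downstream feature families operate on.

With periodic boundary handling and an orthogonal mother wavelet the
transform is orthonormal, so the summed squared coefficients equal the
signal energy (Parseval). Signals whose length is not a multiple of
2^level are zero-padded up to the next multiple before decomposition;
zero padding adds no energy and keeps the periodized filter bank
orthogonal at every level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pywt

from ictalemo.signal_io import EEGSegment

DEFAULT_WAVELET = "coif1"
DEFAULT_LEVEL = 7
DEFAULT_BOUNDARY = "periodization"


@dataclass
class WPTNodeSet:
    """Terminal nodes of a level-`level` wavelet-packet decomposition.

    ``nodes[f-1]`` holds the coefficients of frequency band ``f`` (1-based)
    in sequency order; ``bands[f-1]`` is its (low, high) range in Hz.
    """

    nodes: list[np.ndarray]
    level: int
    wavelet_name: str
    fs: float
    bands: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.nodes) != 2**self.level:
            raise ValueError(f"expected {2**self.level} nodes at level {self.level}, got {len(self.nodes)}")
        if not self.bands:
            self.bands = [node_band(f, self.level, self.fs) for f in range(1, 2**self.level + 1)]

    def __len__(self) -> int:
        return len(self.nodes)


def node_band(f: int, level: int, fs: float) -> tuple[float, float]:
    """Frequency band (Hz) of terminal node ``f`` (1-based, sequency order).

    The level-``level`` tree partitions [0, fs/2] into 2^level equal bands
    of width fs / 2^(level+1); node f covers ((f-1)*w, f*w).
    """
    if not 1 <= f <= 2**level:
        raise ValueError(f"node index {f} out of range 1..{2**level} for level {level}")
    width = fs / 2 ** (level + 1)
    return ((f - 1) * width, f * width)


def max_feasible_level(n_samples: int, wavelet_name: str = DEFAULT_WAVELET) -> int:
    """Deepest decomposition level supported by a signal of ``n_samples``."""
    return pywt.dwt_max_level(n_samples, pywt.Wavelet(wavelet_name).dec_len)


def decompose(
    seg: EEGSegment,
    level: int = DEFAULT_LEVEL,
    wavelet_name: str = DEFAULT_WAVELET,
    boundary_mode: str = DEFAULT_BOUNDARY,
    order: str = "freq",
) -> WPTNodeSet:
    """Full wavelet-packet decomposition of a segment to ``level``.

    Parameters
    ----------
    seg
        Input segment.
    level
        Tree depth; 2^level terminal nodes. Signals too short for the
        requested level raise a ValueError naming the maximum feasible
        level — there is no silent level reduction.
    wavelet_name
        An orthogonal mother wavelet (default Coiflet of order 1).
    boundary_mode
        Signal extension mode; 'periodization' (default) makes the
        transform orthonormal and energy conservation exact.
    order
        'freq' (sequency, default) or 'natural' (Paley filter-path) node
        ordering.
    """
    if level < 1:
        raise ValueError(f"level must be >= 1, got {level}")
    try:
        wavelet = pywt.Wavelet(wavelet_name)
    except ValueError:
        raise ValueError(f"unknown wavelet {wavelet_name!r}") from None
    if not wavelet.orthogonal:
        raise ValueError(f"wavelet {wavelet_name!r} is not orthogonal")
    if order not in ("freq", "natural"):
        raise ValueError(f"order must be 'freq' or 'natural', got {order!r}")
    feasible = max_feasible_level(len(seg), wavelet_name)
    if level > feasible:
        raise ValueError(
            f"segment of {len(seg)} samples is too short for level {level}; "
            f"maximum feasible level is {feasible}"
        )
    x = seg.samples
    block = 2**level
    if boundary_mode == "periodization" and len(x) % block:
        x = np.pad(x, (0, block - len(x) % block))
    wp = pywt.WaveletPacket(data=x, wavelet=wavelet, mode=boundary_mode, maxlevel=level)
    leaf_nodes = wp.get_level(level, order=order)
    coeffs = [np.asarray(nd.data, dtype=np.float64) for nd in leaf_nodes]
    return WPTNodeSet(nodes=coeffs, level=level, wavelet_name=wavelet_name, fs=seg.fs)


def total_energy(nset: WPTNodeSet) -> float:
    """Sum over all terminal nodes of the summed squared coefficients."""
    return float(sum(np.sum(c**2) for c in nset.nodes))
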
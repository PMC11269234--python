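"""Per-node feature families and assembly of the 512-column feature matrix.

Four families are computed for every terminal wavelet-packet node:

* F1 — standard deviation of the phase-space Euclidean-distance series.
  Each node's coefficient sequence is delay-embedded into 3-dimensional
  phase-space vectors (v(m), v(m+tau), v(m+2*tau)); ictal dynamics trace
  more irregular elliptical orbits, and the spread of the orbit radii
  (distance of each embedded vector from the origin) quantifies that.
* F2 — range (max - min) of the same distance series.
* F3 — largest singular value of the node's phase-space trajectory
  matrix, an algebraic summary of the orbit's principal extent.
* F4 — band energy, the summed squared coefficients; seizure discharges
  concentrate energy into the rhythmic bands.

With the default level-7 decomposition (128 nodes) the horizontal
concatenation [F1 | F2 | F3 | F4], family-major, gives 512 columns.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from ictalemo.signal_io import EEGSegment, Label
from ictalemo import wpt_mra

N_FAMILIES = 4
FAMILY_NAMES = ("F1", "F2", "F3", "F4")


@dataclass
class EmbeddingParams:
    """Time-delay embedding parameters: lag ``tau`` (samples), dimension fixed at 3.

    ``svd_rank_index`` selects which singular value of the trajectory
    matrix becomes the F3 feature (0 = largest).
    """

    tau: int = 1
    dim: int = 3
    svd_rank_index: int = 0

    def __post_init__(self) -> None:
        if self.tau < 1:
            raise ValueError(f"tau must be >= 1, got {self.tau}")
        if self.dim != 3:
            raise ValueError("embedding dimension is fixed at 3")

    def min_length(self) -> int:
        return 2 * self.tau + 2


@dataclass
class FeatureMatrix:
    """p x (4 * n_nodes) feature matrix with per-column provenance.

    ``columns`` holds (family, node) pairs, family in 1..4, node 1-based;
    ``row_labels`` aligns with the segments the rows came from.
    """

    values: np.ndarray
    columns: list[tuple[int, int]]
    row_labels: list[Label]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("feature matrix must be two-dimensional")
        if self.values.shape[1] != len(self.columns):
            raise ValueError("column provenance does not match matrix width")
        if len(self.row_labels) != self.values.shape[0]:
            raise ValueError("row labels do not match matrix height")
        if not np.isfinite(self.values).all():
            raise ValueError("feature matrix contains non-finite entries")

    @property
    def n_segments(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def labels01(self) -> np.ndarray:
        """Labels as a 0/1 integer vector (ictal = 1)."""
        return np.array([1 if lab is Label.ICTAL else 0 for lab in self.row_labels], dtype=np.intp)

    def to_csv(self, path) -> None:
        import pandas as pd
        from ictalemo.signal_io import FeatureCSVSchema

        names = [FeatureCSVSchema.column_token(fam, node) for fam, node in self.columns]
        df = pd.DataFrame(self.values, columns=names)
        df["label"] = [lab.value for lab in self.row_labels]
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "FeatureMatrix":
        import pandas as pd
        from ictalemo.signal_io import FeatureCSVSchema

        df = pd.read_csv(path)
        labels = [Label(v) for v in df.pop("label")]
        columns = [FeatureCSVSchema.parse_token(tok) for tok in df.columns]
        return cls(values=df.to_numpy(dtype=np.float64), columns=columns, row_labels=labels)


def embed_phase_space(v: Sequence[float] | np.ndarray, params: EmbeddingParams = EmbeddingParams()) -> np.ndarray:
    """Delay-embed a scalar series into (M - 2*tau) x 3 phase-space vectors.

    Row m (0-based) is (v[m], v[m+tau], v[m+2*tau]).
    """
    v = np.asarray(v, dtype=np.float64)
    m = v.size - 2 * params.tau
    if m < 2:
        raise ValueError(
            f"series of length {v.size} too short for tau={params.tau}; need at least {params.min_length()}"
        )
    return np.column_stack([v[: m], v[params.tau : params.tau + m], v[2 * params.tau : 2 * params.tau + m]])


def euclidean_distance_series(v: Sequence[float] | np.ndarray, params: EmbeddingParams = EmbeddingParams()) -> np.ndarray:
    """Distance of each embedded phase-space vector from the origin.

    ED(m) = sqrt(v(m)^2 + v(m+tau)^2 + v(m+2*tau)^2); at tau=1 this is
    the consecutive-sample form and the series measures orbit radii.
    """
    return np.linalg.norm(embed_phase_space(v, params), axis=1)


def sd_feature(ed: Sequence[float] | np.ndarray) -> float:
    """Sample standard deviation (divisor Q-1) of the distance series (F1)."""
    ed = np.asarray(ed, dtype=np.float64)
    if ed.size < 2:
        raise ValueError(f"need >= 2 values for a sample standard deviation, got {ed.size}")
    return float(np.std(ed, ddof=1))


def range_feature(ed: Sequence[float] | np.ndarray) -> float:
    """max - min of the distance series (F2); nonnegative."""
    ed = np.asarray(ed, dtype=np.float64)
    if ed.size == 0:
        raise ValueError("empty sequence has no range")
    return float(np.max(ed) - np.min(ed))


def svd_feature(v: Sequence[float] | np.ndarray, params: EmbeddingParams = EmbeddingParams()) -> float:
    """Singular value of the node's phase-space trajectory matrix (F3).

    The (M - 2*tau) x 3 embedding is decomposed and the singular value at
    ``params.svd_rank_index`` (default the largest) is returned.
    """
    a = embed_phase_space(v, params)
    s = np.linalg.svd(a, compute_uv=False)
    return float(s[params.svd_rank_index])


def energy_feature(v: Sequence[float] | np.ndarray) -> float:
    """Summed squared coefficients of the node (F4)."""
    v = np.asarray(v, dtype=np.float64)
    if v.size == 0:
        raise ValueError("empty sequence has no energy")
    return float(np.sum(v**2))


def extract_feature_row(nset: wpt_mra.WPTNodeSet, params: EmbeddingParams = EmbeddingParams()) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """All four families over all nodes, family-major: F1 block, then F2, F3, F4.

    For the level-7 tree this is 4 x 128 = 512 values. Returns the row
    and its (family, node) provenance, node indices 1-based.
    """
    n = len(nset)
    for idx, node in enumerate(nset.nodes, start=1):
        if node.size < params.min_length():
            raise ValueError(
                f"node {idx} has {node.size} coefficients; needs >= {params.min_length()} for tau={params.tau}"
            )
    f1 = np.empty(n)
    f2 = np.empty(n)
    f3 = np.empty(n)
    f4 = np.empty(n)
    for i, node in enumerate(nset.nodes):
        ed = euclidean_distance_series(node, params)
        f1[i] = sd_feature(ed)
        f2[i] = range_feature(ed)
        f3[i] = svd_feature(node, params)
        f4[i] = energy_feature(node)
    row = np.concatenate([f1, f2, f3, f4])
    columns = [(fam, node) for fam in range(1, N_FAMILIES + 1) for node in range(1, n + 1)]
    return row, columns


def build_feature_matrix(
    segments: Sequence[EEGSegment],
    level: int = wpt_mra.DEFAULT_LEVEL,
    wavelet_name: str = wpt_mra.DEFAULT_WAVELET,
    boundary_mode: str = wpt_mra.DEFAULT_BOUNDARY,
    params: EmbeddingParams = EmbeddingParams(),
) -> FeatureMatrix:
    """One feature row per segment, in input order, labels carried through.

    All segments must share one sampling rate (resample beforehand when
    mixing sources). No normalization happens here: feature scaling is
    owned by the classifier and fitted on training data only.
    """
    if not segments:
        raise ValueError("no segments given")
    rates = {s.fs for s in segments}
    if len(rates) != 1:
        raise ValueError(f"segments have mixed sampling rates {sorted(rates)}; resample first")
    rows = []
    columns: list[tuple[int, int]] | None = None
    for seg in segments:
        nset = wpt_mra.decompose(seg, level=level, wavelet_name=wavelet_name, boundary_mode=boundary_mode)
        row, cols = extract_feature_row(nset, params)
        if columns is None:
            columns = cols
        rows.append(row)
    assert columns is not None
    return FeatureMatrix(values=np.vstack(rows), columns=columns, row_labels=[s.label for s in segments])
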
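"""Reading, writing and resampling of EEG segments and feature matrices.

Two on-disk dialects are supported for raw signals:

* one-column ASCII files, one sample per line (the layout used by public
  single-channel EEG repositories that ship each segment as a text file);
* CSV matrices holding one segment per row or per column.

Class labels are never inferred from file content; they are supplied by
the caller (public repositories encode the class in the folder layout).
"""

from __future__ import annotations

import csv
import enum
import math
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import signal as _sps


class Label(str, enum.Enum):
    """Segment class: ictal (seizure), non-ictal (interictal background), or unknown."""

    ICTAL = "ictal"
    NON_ICTAL = "non_ictal"
    UNKNOWN = "unknown"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass
class EEGSegment:
    """A single-channel EEG segment: samples (nominal microvolts) at a fixed rate."""

    samples: np.ndarray
    fs: float
    label: Label = Label.UNKNOWN
    source_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if self.samples.size < 1:
            raise ValueError("segment has no samples")
        if not self.fs > 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        self.label = Label(self.label)

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Segment duration in seconds."""
        return self.samples.size / self.fs


def read_segment_ascii(path: str | Path, fs: float, label: Label | str = Label.UNKNOWN) -> EEGSegment:
    """Read a one-column ASCII sample file into a segment.

    Each non-empty line must parse as one real number. Parse failures
    report the offending (1-based) line number.
    """
    path = Path(path)
    values: list[float] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            text = line.strip()
            if not text:
                continue
            try:
                values.append(float(text))
            except ValueError:
                raise ValueError(f"{path}: line {lineno}: not a number: {text!r}") from None
    if not values:
        raise ValueError(f"{path}: no samples found")
    return EEGSegment(np.asarray(values), fs=fs, label=Label(label), source_id=str(path))


def _parse_csv_table(path: Path) -> tuple[np.ndarray, list[str] | None]:
    """Parse a rectangular numeric CSV; auto-detect a single non-numeric header row."""
    with open(path, newline="") as fh:
        rows = [row for row in csv.reader(fh) if any(cell.strip() for cell in row)]
    if not rows:
        raise ValueError(f"{path}: empty table")

    def _numeric(row: Sequence[str]) -> bool:
        try:
            for cell in row:
                float(cell)
        except ValueError:
            return False
        return True

    header: list[str] | None = None
    if not _numeric(rows[0]):
        header = [c.strip() for c in rows[0]]
        rows = rows[1:]
        if not rows:
            raise ValueError(f"{path}: header but no data rows")
    width = len(rows[0])
    data = np.empty((len(rows), width), dtype=np.float64)
    for i, row in enumerate(rows):
        if len(row) != width:
            raise ValueError(f"{path}: ragged table: row {i + 1} has {len(row)} cells, expected {width}")
        try:
            data[i] = [float(c) for c in row]
        except ValueError:
            raise ValueError(f"{path}: non-numeric cell in data row {i + 1}") from None
    return data, header


def read_segments_csv(
    path: str | Path,
    fs: float,
    orientation: str = "rows",
    labels: Sequence[Label | str] | None = None,
) -> list[EEGSegment]:
    """Read a CSV matrix as a collection of segments.

    ``orientation`` declares whether each row or each column of the table
    is one segment; order is preserved. All segments share ``fs``. An
    optional ``labels`` sequence (aligned with segment order) assigns
    classes; otherwise all segments are ``unknown``.
    """
    if orientation not in ("rows", "columns"):
        raise ValueError(f"orientation must be 'rows' or 'columns', got {orientation!r}")
    path = Path(path)
    data, _ = _parse_csv_table(path)
    if orientation == "columns":
        data = data.T
    if labels is not None and len(labels) != data.shape[0]:
        raise ValueError(f"{len(labels)} labels for {data.shape[0]} segments")
    out = []
    for k in range(data.shape[0]):
        lab = Label(labels[k]) if labels is not None else Label.UNKNOWN
        out.append(EEGSegment(data[k].copy(), fs=fs, label=lab, source_id=f"{path}#{k}"))
    return out


def write_segments_csv(segments: Sequence[EEGSegment], path: str | Path, orientation: str = "rows") -> None:
    """Write equal-length segments to a CSV matrix (inverse of :func:`read_segments_csv`)."""
    if not segments:
        raise ValueError("no segments to write")
    lengths = {len(s) for s in segments}
    if len(lengths) != 1:
        raise ValueError(f"segments have unequal lengths {sorted(lengths)}; cannot form a matrix")
    data = np.vstack([s.samples for s in segments])
    if orientation == "columns":
        data = data.T
    elif orientation != "rows":
        raise ValueError(f"orientation must be 'rows' or 'columns', got {orientation!r}")
    np.savetxt(path, data, delimiter=",", fmt="%.17g")


def write_labels(segments: Sequence[EEGSegment], path: str | Path) -> None:
    """Write a one-column label sidecar aligned with segment order."""
    with open(path, "w") as fh:
        for s in segments:
            fh.write(f"{s.label.value}\n")


def read_labels(path: str | Path) -> list[Label]:
    with open(path) as fh:
        return [Label(line.strip()) for line in fh if line.strip()]


def resample_segment(seg: EEGSegment, target_fs: float) -> EEGSegment:
    """Band-limited resampling of a segment to ``target_fs``.

    Rational-rate conversions use polyphase filtering; irrational ratios
    (e.g. 173.61 Hz -> 200 Hz) fall back to Fourier-domain resampling.
    Resampling at the segment's own rate returns the samples unchanged.
    """
    if not target_fs > 0:
        raise ValueError(f"target_fs must be positive, got {target_fs}")
    if math.isclose(target_fs, seg.fs, rel_tol=1e-12):
        return EEGSegment(seg.samples.copy(), fs=seg.fs, label=seg.label, source_id=seg.source_id)
    n_out = round(len(seg) * target_fs / seg.fs)
    ratio = Fraction(target_fs / seg.fs).limit_denominator(1000)
    if math.isclose(float(ratio), target_fs / seg.fs, rel_tol=1e-9):
        y = _sps.resample_poly(seg.samples, ratio.numerator, ratio.denominator)
        y = y[:n_out] if y.size >= n_out else np.pad(y, (0, n_out - y.size))
    else:
        y = _sps.resample(seg.samples, n_out)
    return EEGSegment(y, fs=target_fs, label=seg.label, source_id=seg.source_id)


@dataclass
class FeatureCSVSchema:
    """Column naming for serialized feature matrices: ``F{family}_node{index:03d}``."""

    label_column: str = "label"

    @staticmethod
    def column_token(family: int, node: int) -> str:
        return f"F{family}_node{node:03d}"

    @staticmethod
    def parse_token(token: str) -> tuple[int, int]:
        if not (token.startswith("F") and "_node" in token):
            raise ValueError(f"not a feature column token: {token!r}")
        fam, node = token[1:].split("_node")
        return int(fam), int(node)
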
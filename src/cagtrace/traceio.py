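"""I/O and peak calling for capillary-electrophoresis fragment data.

Reads and writes GeneMapper-style peak tables (sample id, fragment size in
bp, peak height) and raw electropherogram traces (scan index, fluorescence
signal) as plain CSV, detects peaks in raw traces, and converts peak scan
positions to fragment sizes by piecewise-linear interpolation against a
co-electrophoresed size-standard ladder.

Binary ABIF/.fsa parsing is out of scope; traces enter as two-column CSV
with the ladder peak calls supplied as a separate (scan, size_bp) CSV.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .errors import FormatError, InputError

__all__ = [
    "DEFAULT_DIALECT",
    "GENEMAPPER_DIALECT",
    "Electropherogram",
    "PeakTable",
    "read_peak_table",
    "write_peak_table",
    "read_trace",
    "write_trace",
    "detect_peaks",
    "size_call",
]

logger = logging.getLogger(__name__)

#: Column-name mapping for the package's native peak-table CSV.
DEFAULT_DIALECT = {"sample": "sample_id", "size": "size_bp", "height": "height"}

#: Column-name mapping matching a GeneMapper genotypes export.
GENEMAPPER_DIALECT = {"sample": "Sample File Name", "size": "Size", "height": "Height"}

#: Peaks closer than this on the bp axis are considered duplicates.
DUPLICATE_BP_TOL = 0.1


@dataclass
class Electropherogram:
    """A raw trace plus the ladder channel's peak calls.

    ``scans`` are strictly increasing integer scan indices with one
    fluorescence value each; ``ladder_scans``/``ladder_sizes`` give the scan
    position and known bp size of each size-standard fragment.
    """

    scans: np.ndarray
    signal: np.ndarray
    ladder_scans: np.ndarray = field(default_factory=lambda: np.array([], dtype=np.int64))
    ladder_sizes: np.ndarray = field(default_factory=lambda: np.array([], dtype=float))

    def __post_init__(self) -> None:
        self.scans = np.asarray(self.scans, dtype=np.int64)
        self.signal = np.asarray(self.signal, dtype=float)
        self.ladder_scans = np.asarray(self.ladder_scans, dtype=np.int64)
        self.ladder_sizes = np.asarray(self.ladder_sizes, dtype=float)
        if self.scans.shape != self.signal.shape:
            raise InputError("scans and signal must have equal length")
        if self.scans.size and np.any(np.diff(self.scans) <= 0):
            raise InputError("scan indices must be strictly increasing")
        if self.ladder_scans.shape != self.ladder_sizes.shape:
            raise InputError("ladder_scans and ladder_sizes must have equal length")
        if self.ladder_scans.size and np.any(np.diff(self.ladder_scans) <= 0):
            raise InputError("ladder scan positions must be strictly increasing")


@dataclass
class PeakTable:
    """Sized peaks (bp, height) for one sample, sorted by size."""

    sample_id: str
    sizes_bp: np.ndarray
    heights: np.ndarray

    def __post_init__(self) -> None:
        sizes = np.asarray(self.sizes_bp, dtype=float)
        heights = np.asarray(self.heights, dtype=float)
        if sizes.shape != heights.shape or sizes.ndim != 1:
            raise InputError("sizes_bp and heights must be 1-d arrays of equal length")
        order = np.argsort(sizes, kind="stable")
        sizes, heights = sizes[order], heights[order]
        if np.any(sizes <= 0):
            raise InputError(f"sample {self.sample_id!r}: fragment sizes must be > 0")
        if np.any(heights <= 0):
            raise InputError(f"sample {self.sample_id!r}: peak heights must be > 0")
        if sizes.size > 1 and np.any(np.diff(sizes) < DUPLICATE_BP_TOL):
            raise InputError(
                f"sample {self.sample_id!r}: duplicate peaks within "
                f"{DUPLICATE_BP_TOL} bp"
            )
        self.sizes_bp, self.heights = sizes, heights

    @property
    def n_peaks(self) -> int:
        return int(self.sizes_bp.size)


def read_peak_table(path, dialect: dict | None = None) -> list[PeakTable]:
    """Read a peak-table CSV into one :class:`PeakTable` per sample.

    ``dialect`` maps the logical column roles ``sample``/``size``/``height``
    to the file's column names (see :data:`GENEMAPPER_DIALECT`).  Rows with
    non-positive height are dropped with a logged warning.
    """
    dialect = dict(DEFAULT_DIALECT if dialect is None else dialect)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"peak table {path} is empty") from exc
    for role in ("sample", "size", "height"):
        col = dialect[role]
        if col not in df.columns:
            raise FormatError(
                f"peak table {path} is missing required column {col!r} ({role})"
            )
    if df.empty:
        raise FormatError(f"peak table {path} contains no data rows")
    df = df.rename(columns={dialect[r]: r for r in ("sample", "size", "height")})
    df["size"] = pd.to_numeric(df["size"])
    df["height"] = pd.to_numeric(df["height"])
    bad = df["height"] <= 0
    if bad.any():
        logger.warning("dropping %d rows with non-positive height from %s",
                       int(bad.sum()), path)
        df = df[~bad]
    tables = []
    for sample_id, group in df.groupby("sample", sort=False):
        tables.append(
            PeakTable(str(sample_id), group["size"].to_numpy(), group["height"].to_numpy())
        )
    return tables


def write_peak_table(tables, path, dialect: dict | None = None) -> None:
    """Write peak tables to CSV (values at 6-decimal precision)."""
    dialect = dict(DEFAULT_DIALECT if dialect is None else dialect)
    frames = [
        pd.DataFrame(
            {
                dialect["sample"]: t.sample_id,
                dialect["size"]: t.sizes_bp,
                dialect["height"]: t.heights,
            }
        )
        for t in tables
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.6f")


def read_trace(trace_path, ladder_path=None) -> Electropherogram:
    """Read a (scan, signal) trace CSV, optionally with a ladder CSV."""
    df = pd.read_csv(trace_path)
    for col in ("scan", "signal"):
        if col not in df.columns:
            raise FormatError(f"trace {trace_path} is missing column {col!r}")
    ladder_scans, ladder_sizes = [], []
    if ladder_path is not None:
        lad = pd.read_csv(ladder_path)
        for col in ("scan", "size_bp"):
            if col not in lad.columns:
                raise FormatError(f"ladder {ladder_path} is missing column {col!r}")
        ladder_scans = lad["scan"].to_numpy()
        ladder_sizes = lad["size_bp"].to_numpy()
    return Electropherogram(df["scan"].to_numpy(), df["signal"].to_numpy(),
                            ladder_scans, ladder_sizes)


def write_trace(trace: Electropherogram, trace_path, ladder_path=None) -> None:
    """Write a trace (and optionally its ladder calls) to CSV."""
    pd.DataFrame({"scan": trace.scans, "signal": trace.signal}).to_csv(
        trace_path, index=False, float_format="%.6f"
    )
    if ladder_path is not None:
        pd.DataFrame(
            {"scan": trace.ladder_scans, "size_bp": trace.ladder_sizes}
        ).to_csv(ladder_path, index=False, float_format="%.6f")


def detect_peaks(trace: Electropherogram, min_height: float,
                 min_spacing_scans: int = 1) -> list[tuple[int, float]]:
    """Local maxima of the trace with height and spacing constraints.

    Returns ``(scan, height)`` pairs for maxima with signal >= ``min_height``
    separated by at least ``min_spacing_scans``; when maxima conflict the
    taller peak wins.  A plateau reports its leftmost scan.  Boundary samples
    cannot be maxima (they lack a neighbour on one side).
    """
    if min_height < 0:
        raise InputError(f"min_height must be >= 0, got {min_height}")
    if min_spacing_scans < 1:
        raise InputError(f"min_spacing_scans must be >= 1, got {min_spacing_scans}")
    sig = np.asarray(trace.signal, dtype=float)
    if sig.size < 3:
        raise InputError("trace must contain at least 3 samples")
    _, props = find_peaks(sig, height=min_height, plateau_size=(1, None))
    cand = props["left_edges"]
    heights = sig[cand]
    scans = trace.scans[cand]
    # greedy non-maximum suppression: tallest first, leftmost on ties
    order = np.lexsort((scans, -heights))
    kept: list[int] = []
    for i in order:
        if all(abs(int(scans[i]) - k) >= min_spacing_scans for k in kept):
            kept.append(int(scans[i]))
    kept.sort()
    by_scan = {int(s): float(h) for s, h in zip(scans, heights)}
    return [(s, by_scan[s]) for s in kept]


def size_call(peaks, ladder_scans, ladder_sizes):
    """Convert peak scan positions to fragment sizes against the ladder.

    Piecewise-linear interpolation between ladder points.  Peaks outside the
    ladder span cannot be sized; they are returned separately and logged.
    Returns ``(sized, excluded)`` where ``sized`` is a list of
    ``(size_bp, height)`` and ``excluded`` a list of ``(scan, height)``.
    """
    ladder_scans = np.asarray(ladder_scans, dtype=float)
    ladder_sizes = np.asarray(ladder_sizes, dtype=float)
    if ladder_scans.size < 2:
        raise InputError("size calling requires at least 2 ladder points")
    if ladder_scans.shape != ladder_sizes.shape:
        raise InputError("ladder_scans and ladder_sizes must have equal length")
    if np.any(np.diff(ladder_scans) <= 0) or np.any(np.diff(ladder_sizes) <= 0):
        raise InputError("ladder scans and sizes must be strictly increasing")
    sized, excluded = [], []
    for scan, height in peaks:
        if scan < ladder_scans[0] or scan > ladder_scans[-1]:
            excluded.append((scan, height))
            continue
        size = float(np.interp(scan, ladder_scans, ladder_sizes))
        sized.append((size, float(height)))
    if excluded:
        logger.warning("excluded %d peaks outside the ladder span", len(excluded))
    return sized, excluded
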
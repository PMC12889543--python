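"""Parsing and binning of chromosome sizes, contact pairs and coverage.

Text formats (chrom.sizes, BEDPE, bedGraph) are parsed directly; binary
formats (.hic, .bigWig) go through thin adapters that yield the same record
streams, so the binning core never touches a binary file.

Coordinates follow BED conventions: 0-based, half-open.  Internal bins are
0-indexed half-open intervals [k*bin_size, (k+1)*bin_size).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Iterator, Optional

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Domain types


class ChromSizes:
    """Ordered chromosome-name -> length (bp) mapping (UCSC chrom.sizes)."""

    def __init__(self, entries: Iterable[tuple[str, int]]):
        self.entries: dict[str, int] = {}
        for name, length in entries:
            if name in self.entries:
                raise ValueError(f"duplicate chromosome {name!r}")
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")
            self.entries[name] = int(length)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries.items())

    def __contains__(self, name: str) -> bool:
        return name in self.entries

    def __getitem__(self, name: str) -> int:
        return self.entries[name]

    def __eq__(self, other) -> bool:
        return isinstance(other, ChromSizes) and self.entries == other.entries

    def n_bins(self, name: str, bin_size: int) -> int:
        return int(np.ceil(self.entries[name] / bin_size))


@dataclass(frozen=True)
class ContactRecord:
    """One chromatin contact: two genomic anchors and an interaction weight."""

    chrom1: str
    start1: int
    end1: int
    chrom2: str
    start2: int
    end2: int
    count: float = 1.0

    def __post_init__(self):
        if self.start1 >= self.end1 or self.start2 >= self.end2:
            raise ValueError(f"anchor start must be < end: {self}")
        if self.count < 0:
            raise ValueError(f"negative contact count: {self}")


@dataclass(frozen=True)
class SignalRecord:
    """One coverage interval (bedGraph row)."""

    chrom: str
    start: int
    end: int
    value: float

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"interval start must be < end: {self}")
        if self.value < 0:
            raise ValueError(f"negative signal value: {self}")


@dataclass
class BinnedContactMatrix:
    """Symmetric per-chromosome contact matrix at a fixed bin size."""

    chrom: str
    bin_size: int
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("contact matrix must be square")

    @property
    def n_bins(self) -> int:
        return self.values.shape[0]

    def total(self) -> float:
        return float(self.values.sum())


@dataclass
class EnrichmentSignal:
    """Per-chromosome binned 1D coverage vector (same resolution as contacts)."""

    chrom: str
    bin_size: int
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("signal must be 1-D")

    @property
    def n_bins(self) -> int:
        return self.values.shape[0]


# ---------------------------------------------------------------------------
# Readers


def read_chrom_sizes(path, chroms_to_load="all") -> ChromSizes:
    """Read a two-column UCSC chrom.sizes file, preserving file order.

    Parameters
    ----------
    path : str or Path
    chroms_to_load : "all" or collection of chromosome names to keep.
    """
    entries = []
    keep = None if chroms_to_load == "all" else set(chroms_to_load)
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) < 2:
                raise ValueError(f"{path}: malformed chrom.sizes line {lineno}: {line!r}")
            name = parts[0]
            try:
                length = int(parts[1])
            except ValueError as exc:
                raise ValueError(
                    f"{path}: malformed chrom.sizes line {lineno}: {line!r}"
                ) from exc
            if keep is not None and name not in keep:
                continue
            entries.append((name, length))
    return ChromSizes(entries)


def iter_bedpe(path) -> Iterator[ContactRecord]:
    """Yield contact records from a BEDPE file.

    Columns 1-6 are the two anchors.  Column 8 (score), when present and
    numeric, is used as the count; otherwise each row counts 1.  Header
    lines starting with '#' or 'chrom' are skipped.
    """
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.lower().startswith("chrom"):
                continue
            parts = line.split("\t")
            if len(parts) == 1:
                parts = line.split()
            if len(parts) < 6:
                raise ValueError(f"{path}: BEDPE line {lineno} has <6 columns: {line!r}")
            count = 1.0
            if len(parts) >= 8:
                try:
                    count = float(parts[7])
                except ValueError:
                    count = 1.0
            try:
                yield ContactRecord(
                    parts[0], int(parts[1]), int(parts[2]),
                    parts[3], int(parts[4]), int(parts[5]), count,
                )
            except ValueError as exc:
                raise ValueError(f"{path}: BEDPE line {lineno}: {exc}") from exc


def iter_bedgraph(path) -> Iterator[SignalRecord]:
    """Yield coverage records from a 4-column bedGraph file."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if (not line or line.startswith("#") or line.startswith("track")
                    or line.startswith("browser")):
                continue
            parts = line.split("\t")
            if len(parts) == 1:
                parts = line.split()
            if len(parts) < 4:
                raise ValueError(f"{path}: bedGraph line {lineno} has <4 columns: {line!r}")
            try:
                yield SignalRecord(parts[0], int(parts[1]), int(parts[2]), float(parts[3]))
            except ValueError as exc:
                raise ValueError(f"{path}: bedGraph line {lineno}: {exc}") from exc


def iter_bigwig(path, chrom_sizes: ChromSizes) -> Iterator[SignalRecord]:
    """Adapter: yield SignalRecords from a .bigWig file via pyBigWig."""
    try:
        import pyBigWig
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError(
            "pyBigWig is required to read .bigWig files; install the 'bigwig' extra "
            "or convert the track to bedGraph"
        ) from exc
    bw = pyBigWig.open(str(path))
    try:
        for chrom, _length in chrom_sizes:
            if chrom not in bw.chroms():
                continue
            intervals = bw.intervals(chrom) or ()
            for start, end, value in intervals:
                if value and value > 0:
                    yield SignalRecord(chrom, int(start), int(end), float(value))
    finally:
        bw.close()


def iter_hic(path, chrom_sizes: ChromSizes, bin_size: int) -> Iterator[ContactRecord]:
    """Adapter: yield ContactRecords from a .hic file via hic-straw.

    Each nonzero bin pair becomes one record whose anchors are the bin
    intervals, so midpoint assignment reproduces the bin pair exactly.
    """
    try:
        import hicstraw
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError(
            "hic-straw is required to read .hic files; convert the contacts to BEDPE "
            "or install hic-straw"
        ) from exc
    for chrom, length in chrom_sizes:
        name = chrom[3:] if chrom.startswith("chr") else chrom
        records = hicstraw.straw("observed", "NONE", str(path), name, name, "BP", bin_size)
        for rec in records:
            yield ContactRecord(
                chrom, rec.binX, min(rec.binX + bin_size, length),
                chrom, rec.binY, min(rec.binY + bin_size, length),
                float(rec.counts),
            )


# ---------------------------------------------------------------------------
# Binning


def bin_contacts(records: Iterable[ContactRecord], chrom: str, length_bp: int,
                 bin_size: int, min_value: float = 0.0) -> BinnedContactMatrix:
    """Accumulate contact records into a symmetric binned matrix.

    Each anchor maps to the bin containing its midpoint; counts accumulate
    additively into (i, j) and (j, i).  Inter-chromosomal records and
    records on other chromosomes are dropped (their number is logged).
    After accumulation, entries strictly below ``min_value`` are zeroed —
    the threshold describes a valid interaction at the working resolution,
    so it applies to binned values, not raw rows.
    """
    n = int(np.ceil(length_bp / bin_size))
    A = np.zeros((n, n), dtype=float)
    n_dropped = 0
    for rec in records:
        if rec.chrom1 != rec.chrom2:
            n_dropped += 1
            continue
        if rec.chrom1 != chrom:
            continue
        if rec.end1 > length_bp or rec.end2 > length_bp:
            raise ValueError(
                f"contact anchor beyond chromosome {chrom} length {length_bp}: {rec}"
            )
        i = int(((rec.start1 + rec.end1) // 2) // bin_size)
        j = int(((rec.start2 + rec.end2) // 2) // bin_size)
        A[i, j] += rec.count
        if i != j:
            A[j, i] += rec.count
    if n_dropped:
        log.info("dropped %d inter-chromosomal contacts for %s", n_dropped, chrom)
    if min_value > 0:
        A[A < min_value] = 0.0
    return BinnedContactMatrix(chrom, bin_size, A)


def bin_signal(records: Iterable[SignalRecord], chrom: str, length_bp: int,
               bin_size: int, min_value: float = 0.0,
               multiplier: float = 1.0) -> EnrichmentSignal:
    """Accumulate coverage records into a binned vector.

    Each interval contributes value x (overlapping base pairs) to every bin
    it overlaps; bins are then scaled by ``multiplier`` and entries strictly
    below ``min_value`` zeroed.  Intervals running past the chromosome end
    are clipped with a warning.
    """
    n = int(np.ceil(length_bp / bin_size))
    b = np.zeros(n, dtype=float)
    for rec in records:
        if rec.chrom != chrom:
            continue
        start, end = rec.start, rec.end
        if end > length_bp:
            warnings.warn(
                f"signal interval [{start},{end}) clipped to chromosome "
                f"{chrom} length {length_bp}",
                stacklevel=2,
            )
            end = length_bp
        start = max(start, 0)
        if start >= end:
            continue
        first, last = start // bin_size, (end - 1) // bin_size
        for k in range(first, last + 1):
            lo = max(start, k * bin_size)
            hi = min(end, (k + 1) * bin_size)
            b[k] += rec.value * (hi - lo)
    b *= multiplier
    if min_value > 0:
        b[b < min_value] = 0.0
    return EnrichmentSignal(chrom, bin_size, b)


# ---------------------------------------------------------------------------
# Sample tables


def read_metadata(path) -> pd.DataFrame:
    """Read the sample table: TSV with columns sample_id, contacts_path, signal_path."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    required = {"sample_id", "contacts_path", "signal_path"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: metadata file missing columns {sorted(missing)}")
    if df["sample_id"].duplicated().any():
        raise ValueError(f"{path}: duplicate sample_id in metadata")
    return df


def read_pairs(path) -> pd.DataFrame:
    """Read the comparison list: TSV with columns sample_a, sample_b."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    required = {"sample_a", "sample_b"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: pairs file missing columns {sorted(missing)}")
    return df
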
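"""Sliding windows along the main diagonal of each chromosomal matrix.

Windows are square blocks centred on the diagonal so each one is a
symmetric matrix interpretable as a small graph.  All windows on a
chromosome with at least M bins have identical size M: the last window is
positioned so its lower-right corner coincides with the corner of the
chromosomal matrix instead of being truncated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import BinnedContactMatrix, ChromSizes, EnrichmentSignal

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class Window:
    """Half-open bin interval [start_bin, end_bin) on one chromosome."""

    chrom: str
    start_bin: int
    end_bin: int
    index: int = 0  # ordinal in the genome-wide window list

    @property
    def size(self) -> int:
        return self.end_bin - self.start_bin


def make_windows(n_bins: int, window_bins: int, stride: int,
                 chrom: str = "", index_offset: int = 0) -> list[Window]:
    """Enumerate sliding windows over a chromosome of ``n_bins`` bins.

    The step is ``window_bins // stride`` (adjacent windows overlap by
    1/stride).  Windows start at 0, step, 2*step, ...; when the regular
    sequence would overrun the chromosome, a final window [N-M, N) is
    appended so every window keeps size M.  Chromosomes shorter than the
    window yield a single full-chromosome window.
    """
    if n_bins < 1 or window_bins < 1:
        raise ValueError("n_bins and window_bins must be >= 1")
    if stride < 1:
        raise ValueError("stride must be >= 1")
    if n_bins < window_bins:
        log.info("chromosome %s (%d bins) shorter than window (%d bins); "
                 "one full-chromosome window emitted", chrom, n_bins, window_bins)
        return [Window(chrom, 0, n_bins, index_offset)]
    step = window_bins // stride
    if step == 0:
        raise ValueError("window too small for stride")
    starts = list(range(0, n_bins - window_bins + 1, step))
    if starts[-1] + window_bins < n_bins:
        starts.append(n_bins - window_bins)  # end-snapped last window
    # duplicates can arise when N-M is a multiple of step; keep first
    seen: set[int] = set()
    windows = []
    for s in starts:
        if s in seen:
            continue
        seen.add(s)
        windows.append(Window(chrom, s, s + window_bins, index_offset + len(windows)))
    return windows


def genome_windows(chrom_sizes: ChromSizes, bin_size: int, window_bins: int,
                   stride: int) -> list[Window]:
    """Windows for every chromosome, in ChromSizes order, globally indexed."""
    out: list[Window] = []
    for chrom, _length in chrom_sizes:
        out.extend(
            make_windows(chrom_sizes.n_bins(chrom, bin_size), window_bins,
                         stride, chrom=chrom, index_offset=len(out))
        )
    return out


def extract_window(A: BinnedContactMatrix, b: EnrichmentSignal,
                   w: Window) -> tuple[np.ndarray, np.ndarray]:
    """Copy out the window's square contact block and matching signal slice."""
    if w.chrom != A.chrom or w.chrom != b.chrom:
        raise ValueError(f"window chromosome {w.chrom!r} does not match data")
    if w.end_bin > A.n_bins or w.end_bin > b.n_bins or w.start_bin < 0:
        raise IndexError(f"window [{w.start_bin},{w.end_bin}) outside matrix of "
                         f"{A.n_bins} bins")
    block = A.values[w.start_bin:w.end_bin, w.start_bin:w.end_bin].copy()
    sig = b.values[w.start_bin:w.end_bin].copy()
    return block, sig


def windows_to_bed(windows: list[Window], chrom_sizes: ChromSizes,
                   bin_size: int) -> pd.DataFrame:
    """Window table as BED (chrom, start_bp, end_bp, window_id)."""
    rows = [
        {
            "chrom": w.chrom,
            "start_bp": w.start_bin * bin_size,
            "end_bp": min(w.end_bin * bin_size, chrom_sizes[w.chrom]),
            "window_id": w.index,
        }
        for w in windows
    ]
    return pd.DataFrame(rows, columns=["chrom", "start_bp", "end_bp", "window_id"])
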
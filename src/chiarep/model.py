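"""Model/results objects for pairwise reproducibility scoring.

`Sample` holds one library's binned contacts and coverage.
`ReproducibilityModel` pairs two samples under a `Config`; `fit()` slides
windows along each chromosome, diffuses each sample's signal over its own
chromatin graph, compares the processed signals, and returns a
`ReproducibilityResults` carrying per-window scores, the genome-wide mean
and degenerate-window diagnostics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import io, sgie, windowing
from .config import Config
from .scoring import window_score

log = logging.getLogger(__name__)


@dataclass
class Sample:
    """One library: binned contact matrices and enrichment signals per chromosome."""

    sample_id: str
    chrom_sizes: io.ChromSizes
    contacts: dict[str, io.BinnedContactMatrix] = field(default_factory=dict)
    signals: dict[str, io.EnrichmentSignal] = field(default_factory=dict)
    bin_size: int = 10_000

    @classmethod
    def from_files(cls, sample_id: str, contacts_path: str, signal_path: str,
                   chrom_sizes: io.ChromSizes, config: Config | None = None) -> "Sample":
        """Load and bin a sample from its contact and coverage files.

        Formats are chosen by extension: ``.bedpe`` (or any text pairs
        file) vs ``.hic``; ``.bedGraph``/``.bdg`` vs ``.bigWig``/``.bw``.
        """
        config = config or Config()
        cpath, spath = str(contacts_path), str(signal_path)
        if cpath.lower().endswith(".hic"):
            contact_records = list(io.iter_hic(cpath, chrom_sizes, config.bin_size_bp))
        else:
            contact_records = list(io.iter_bedpe(cpath))
        if spath.lower().endswith((".bw", ".bigwig")):
            signal_records = list(io.iter_bigwig(spath, chrom_sizes))
        else:
            signal_records = list(io.iter_bedgraph(spath))
        return cls.from_records(sample_id, contact_records, signal_records,
                                chrom_sizes, config)

    @classmethod
    def from_records(cls, sample_id, contact_records, signal_records,
                     chrom_sizes: io.ChromSizes, config: Config | None = None) -> "Sample":
        config = config or Config()
        sample = cls(sample_id, chrom_sizes, bin_size=config.bin_size_bp)
        for chrom, length in chrom_sizes:
            sample.contacts[chrom] = io.bin_contacts(
                contact_records, chrom, length, config.bin_size_bp,
                min_value=config.min_hic_value)
            sample.signals[chrom] = io.bin_signal(
                signal_records, chrom, length, config.bin_size_bp,
                min_value=config.min_bedgraph_value, multiplier=config.ba_mult)
        return sample

    @classmethod
    def from_arrays(cls, sample_id: str, matrix: np.ndarray, signal: np.ndarray,
                    chrom: str = "chrS", bin_size: int = 10_000) -> "Sample":
        """Wrap an in-memory (matrix, signal) pair, e.g. a simulated library."""
        n = matrix.shape[0]
        sizes = io.ChromSizes([(chrom, n * bin_size)])
        return cls(
            sample_id, sizes,
            contacts={chrom: io.BinnedContactMatrix(chrom, bin_size, matrix)},
            signals={chrom: io.EnrichmentSignal(chrom, bin_size, signal)},
            bin_size=bin_size,
        )


def _score_one(window, Aa, ba, Ab, bb, config: Config):
    """Score a single window: process both samples, compare."""
    A1, b1 = windowing.extract_window(Aa, ba, window)
    A2, b2 = windowing.extract_window(Ab, bb, window)
    pi1 = sgie.process_window(A1, b1, config)
    pi2 = sgie.process_window(A2, b2, config)
    return window_score(pi1, pi2, config.compare_method)


class ReproducibilityModel:
    """Pairwise reproducibility of two enrichment-based 3C samples.

    Parameters
    ----------
    sample_a, sample_b : Sample
        Samples binned on identical chromosome sizes and bin size.
    config : Config, optional
        Window geometry, diffusion steps and comparison method.

    Examples
    --------
    >>> result = ReproducibilityModel(s1, s2, Config(mu=5)).fit()  # doctest: +SKIP
    >>> result.genome_score  # doctest: +SKIP
    """

    def __init__(self, sample_a: Sample, sample_b: Sample,
                 config: Config | None = None):
        self.config = config or Config()
        if sample_a.chrom_sizes != sample_b.chrom_sizes:
            raise ValueError("samples binned on different chromosome sizes")
        if sample_a.bin_size != sample_b.bin_size:
            raise ValueError("samples binned at different resolutions")
        self.sample_a = sample_a
        self.sample_b = sample_b

    @classmethod
    def from_files(cls, contacts_a, signal_a, contacts_b, signal_b,
                   chrom_sizes_path, config: Config | None = None,
                   ids=("sample_a", "sample_b")) -> "ReproducibilityModel":
        config = config or Config()
        sizes = io.read_chrom_sizes(chrom_sizes_path, config.chroms_to_load)
        sa = Sample.from_files(ids[0], contacts_a, signal_a, sizes, config)
        sb = Sample.from_files(ids[1], contacts_b, signal_b, sizes, config)
        return cls(sa, sb, config)

    @property
    def windows(self) -> list[windowing.Window]:
        return windowing.genome_windows(
            self.sample_a.chrom_sizes, self.config.bin_size_bp,
            self.config.window_bins, self.config.window_stride)

    def fit(self) -> "ReproducibilityResults":
        """Score every window and average into the genome-wide score."""
        cfg = self.config
        windows = self.windows
        jobs = [
            (w, self.sample_a.contacts[w.chrom], self.sample_a.signals[w.chrom],
             self.sample_b.contacts[w.chrom], self.sample_b.signals[w.chrom])
            for w in windows
        ]
        if cfg.num_cores > 1 and len(jobs) > 1:
            from joblib import Parallel, delayed
            scores = Parallel(n_jobs=cfg.num_cores)(
                delayed(_score_one)(w, Aa, ba, Ab, bb, cfg)
                for w, Aa, ba, Ab, bb in jobs)
        else:
            scores = [_score_one(w, Aa, ba, Ab, bb, cfg)
                      for w, Aa, ba, Ab, bb in jobs]
        scores = np.asarray(scores, dtype=float)
        defined = ~np.isnan(scores)
        if not defined.any():
            raise ValueError("no scorable windows")
        rows = pd.DataFrame({
            "sample_a": self.sample_a.sample_id,
            "sample_b": self.sample_b.sample_id,
            "chrom": [w.chrom for w in windows],
            "start_bp": [w.start_bin * cfg.bin_size_bp for w in windows],
            "end_bp": [min(w.end_bin * cfg.bin_size_bp,
                           self.sample_a.chrom_sizes[w.chrom]) for w in windows],
            "window_bins": [w.size for w in windows],
            "score": scores,
            "degenerate": ~defined,
        })
        return ReproducibilityResults(self, rows)


class ReproducibilityResults:
    """Fitted per-window scores and the genome-wide reproducibility score.

    Attributes
    ----------
    window_scores : pandas.DataFrame
        One row per window (chrom, start_bp, end_bp, score, degenerate).
    genome_score : float
        Unweighted mean of the defined window scores — the tool's
        genome-wide reproducibility measure.
    """

    def __init__(self, model: ReproducibilityModel, window_scores: pd.DataFrame):
        self.model = model
        self.window_scores = window_scores

    @property
    def genome_score(self) -> float:
        defined = self.window_scores.loc[~self.window_scores["degenerate"], "score"]
        return float(defined.mean())

    @property
    def n_windows_scored(self) -> int:
        return int((~self.window_scores["degenerate"]).sum())

    @property
    def n_windows_skipped(self) -> int:
        return int(self.window_scores["degenerate"].sum())

    def summary(self) -> str:
        cfg = self.model.config
        defined = self.window_scores.loc[~self.window_scores["degenerate"], "score"]
        lines = [
            "Pairwise reproducibility",
            "=" * 52,
            f"samples:            {self.model.sample_a.sample_id} vs "
            f"{self.model.sample_b.sample_id}",
            f"compare method:     {cfg.compare_method}",
            f"bin size:           {cfg.bin_size_bp:,} bp",
            f"window size:        {cfg.window_size_bp:,} bp (stride {cfg.window_stride})",
            f"random-walk steps:  mu = {cfg.mu}",
            f"windows scored:     {self.n_windows_scored}"
            f" (skipped {self.n_windows_skipped} degenerate)",
            f"window score range: [{defined.min():.4f}, {defined.max():.4f}]",
            f"genome score:       {self.genome_score:.4f}",
        ]
        return "\n".join(lines)

    def to_windows_tsv(self, path) -> None:
        self.window_scores.to_csv(path, sep="\t", index=False)


def score_pair(sample_a: Sample, sample_b: Sample,
               config: Config | None = None) -> ReproducibilityResults:
    """Convenience wrapper: fit a ReproducibilityModel for one pair."""
    return ReproducibilityModel(sample_a, sample_b, config).fit()
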
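"""Run configuration shared by binning, windowing, diffusion and scoring."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional


@dataclass
class Config:
    """Parameter surface of the scorer.

    Attributes
    ----------
    window_size_bp : int
        Side length of the square sliding window, in base pairs.
    bin_size_bp : int
        Resolution at which contacts and coverage are binned.
    window_stride : int
        Stride factor; adjacent windows overlap by 1/window_stride of their
        width (step = window_bins // window_stride).
    mu : int
        Number of random-walk steps performed on the chromatin graph.
    compare_method : str
        "spearman" or "jsd" — how two processed signals are compared.
    ba_mult : float
        Multiplier applied to the binned enrichment signal.
    min_hic_value : float
        Binned contact entries strictly below this are zeroed.
    min_bedgraph_value : float
        Binned signal entries strictly below this are zeroed.
    chroms_to_load : str | list
        "all" or an explicit list of chromosome names.
    coverage_weight_mode : str
        "all" adds b_i + b_j to every matrix cell (the default, dense
        reading); "support" only weights cells with a nonzero contact.
    num_cores : int
        Worker processes for per-window scoring; results are identical to
        serial execution.
    rng_seed : int
        Seed for depth adjustment and simulation.
    """

    window_size_bp: int = 5_000_000
    bin_size_bp: int = 10_000
    window_stride: int = 2
    mu: int = 5
    compare_method: str = "spearman"
    ba_mult: float = 1.0
    min_hic_value: float = 1.0
    min_bedgraph_value: float = 1.0
    chroms_to_load: object = "all"
    coverage_weight_mode: str = "all"
    num_cores: int = 1
    output_dir: str = "output"
    do_output_graph: bool = False
    diagnostic_plots: bool = False
    rng_seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.window_size_bp < self.bin_size_bp:
            raise ValueError("window_size_bp must be >= bin_size_bp")
        if int(self.window_stride) != self.window_stride or self.window_stride < 1:
            raise ValueError("window_stride must be an integer >= 1")
        if int(self.mu) != self.mu or self.mu < 0:
            raise ValueError("mu must be an integer >= 0")
        if self.compare_method not in ("spearman", "jsd"):
            raise ValueError("compare_method must be 'spearman' or 'jsd'")
        if self.coverage_weight_mode not in ("all", "support"):
            raise ValueError("coverage_weight_mode must be 'all' or 'support'")

    @property
    def window_bins(self) -> int:
        """Window size in bins (window_size_bp // bin_size_bp)."""
        return max(1, self.window_size_bp // self.bin_size_bp)

    def to_dict(self) -> dict:
        return asdict(self)
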
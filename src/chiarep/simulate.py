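"""Synthetic paired contact-matrix / coverage libraries.

Emulates the two modalities of an enrichment-based 3C experiment on one
chromosome: a contact matrix with power-law distance decay plus anchored
loops, and a coverage track with peaks at the loop anchors (the
enrichment-support structure that coverage weighting exploits).  Replicate
pairs share the expected matrix and differ only by counting noise and
signal jitter; non-replicate pairs relocate a fraction of the loops (and
their anchor peaks) before counts are drawn.

Counts are Poisson, so libraries are integer-valued and feed directly into
the binomial depth-adjustment utilities.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .io import BinnedContactMatrix, EnrichmentSignal


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic library.

    Defaults describe a deep library at 10 kb bins: near-diagonal bin
    pairs see tens of counts (background_rate over a power-law decay with
    exponent 1), loops add ~40 counts at their anchor pair, and anchor
    peaks rise ~50x over the coverage baseline.
    """

    n_bins: int = 300
    bin_size: int = 10_000
    chrom: str = "chrS"
    decay_exponent: float = 1.0
    n_loops: int = 12
    loop_strength: float = 400.0
    anchor_peak_height: float = 1000.0
    signal_baseline: float = 50.0
    baseline_cv: float = 0.5          # log-sd of the smooth background field
    baseline_corr_bins: float = 5.0   # smoothing length of that field, in bins
    background_rate: float = 100.0
    noise_sd: float = 50.0            # replicate-level Gaussian signal jitter
    structural_fraction: float = 0.5  # fraction of loops relocated in non-replicates
    min_loop_span: int = 10           # loop anchors at least this many bins apart
    seed: int = 0
    deterministic: bool = False       # skip Poisson/Gaussian noise, return means

    def __post_init__(self):
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        if not 0.0 <= self.structural_fraction <= 1.0:
            raise ValueError("structural_fraction must be in [0, 1]")
        for name in ("decay_exponent", "n_loops", "loop_strength",
                     "anchor_peak_height", "background_rate", "noise_sd",
                     "signal_baseline"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def _draw_anchors(spec: SyntheticSpec, rng: np.random.Generator,
                  n: int, exclude: set[tuple[int, int]] = frozenset()) -> list[tuple[int, int]]:
    """Random loop anchor pairs (i < j) separated by at least min_loop_span."""
    anchors: list[tuple[int, int]] = []
    taken = set(exclude)
    span = min(spec.min_loop_span, spec.n_bins - 1)
    while len(anchors) < n:
        i = int(rng.integers(0, spec.n_bins - span))
        j = int(rng.integers(i + span, spec.n_bins))
        if (i, j) in taken:
            continue
        taken.add((i, j))
        anchors.append((i, j))
    return anchors


def _background_field(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    """Smooth multiplicative coverage background, shared within a pair.

    Real coverage tracks have a spatially varying background (nonspecific
    binding, chromatin state, mappability) that is highly correlated
    between libraries from the same protocol; a smoothed log-normal field
    with log-sd ``baseline_cv`` emulates that shared structure.
    """
    g = rng.normal(0.0, 1.0, spec.n_bins)
    if spec.baseline_corr_bins > 0:
        g = gaussian_filter1d(g, sigma=spec.baseline_corr_bins, mode="reflect")
        sd = g.std()
        if sd > 0:
            g /= sd
    return np.exp(spec.baseline_cv * g - 0.5 * spec.baseline_cv ** 2)


def expected_library(spec: SyntheticSpec, anchors: list[tuple[int, int]],
                     background: np.ndarray | None = None
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Expected (noise-free) contact matrix and coverage for given anchors."""
    idx = np.arange(spec.n_bins)
    dist = np.abs(idx[:, None] - idx[None, :])
    lam = spec.background_rate * (dist + 1.0) ** (-spec.decay_exponent)
    for i, j in anchors:
        lam[i, j] += spec.loop_strength
        lam[j, i] += spec.loop_strength
    if background is None:
        background = np.ones(spec.n_bins)
    signal = spec.signal_baseline * background
    for i, j in anchors:
        signal[i] += spec.anchor_peak_height
        signal[j] += spec.anchor_peak_height
    return lam, signal


def simulate_library(spec: SyntheticSpec, anchors=None, rng=None,
                     background=None
                     ) -> tuple[BinnedContactMatrix, EnrichmentSignal]:
    """Draw one library from the spec (fully determined by spec.seed)."""
    rng = rng or np.random.default_rng(spec.seed)
    if anchors is None:
        anchors = _draw_anchors(spec, rng, spec.n_loops)
    if background is None:
        background = _background_field(spec, rng)
    lam, mean_signal = expected_library(spec, anchors, background)
    if spec.deterministic:
        A, b = lam.copy(), mean_signal.copy()
    else:
        iu = np.triu_indices(spec.n_bins)
        counts = np.zeros_like(lam)
        counts[iu] = rng.poisson(lam[iu])
        A = counts + np.triu(counts, 1).T
        b = rng.poisson(mean_signal).astype(float)
        if spec.noise_sd > 0:
            b = np.clip(b + rng.normal(0.0, spec.noise_sd, size=b.shape), 0.0, None)
            b = np.rint(b)
    return (BinnedContactMatrix(spec.chrom, spec.bin_size, A),
            EnrichmentSignal(spec.chrom, spec.bin_size, b))


def make_pair(spec: SyntheticSpec, kind: str = "replicate"):
    """Generate a pair of libraries sharing (replicate) or differing in
    (non_replicate) loop/peak placement.

    Replicates share the expected matrix and anchors; each library is an
    independent Poisson draw with independent signal jitter.
    Non-replicates relocate ``structural_fraction`` of the loops (and the
    corresponding anchor peaks) in the second library before drawing.
    """
    if kind not in ("replicate", "non_replicate"):
        raise ValueError("kind must be 'replicate' or 'non_replicate'")
    rng = np.random.default_rng(spec.seed)
    anchors = _draw_anchors(spec, rng, spec.n_loops)
    background = _background_field(spec, rng)
    anchors_b = anchors
    if kind == "non_replicate" and spec.structural_fraction > 0:
        n_move = int(round(spec.structural_fraction * spec.n_loops))
        moved = _draw_anchors(spec, rng, n_move, exclude=set(anchors))
        keep = anchors[: spec.n_loops - n_move]
        anchors_b = keep + moved
    lib_a = simulate_library(spec, anchors=anchors, rng=rng, background=background)
    lib_b = simulate_library(spec, anchors=anchors_b, rng=rng, background=background)
    return lib_a, lib_b


def write_library(A: BinnedContactMatrix, b: EnrichmentSignal, out_dir,
                  prefix: str = "sample") -> dict[str, Path]:
    """Write a library as BEDPE + bedGraph + chrom.sizes for the I/O path.

    Each nonzero upper-triangle matrix entry becomes one BEDPE row with the
    count in column 8; each nonzero signal bin becomes one bedGraph row
    with value = binned_value / bin_size, so re-binning recovers the
    vector exactly.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bs, chrom = A.bin_size, A.chrom
    paths = {
        "chrom_sizes": out / "chrom.sizes",
        "contacts": out / f"{prefix}.bedpe",
        "signal": out / f"{prefix}.bedGraph",
    }
    length = A.n_bins * bs
    paths["chrom_sizes"].write_text(f"{chrom}\t{length}\n")
    with open(paths["contacts"], "w") as fh:
        iu, ju = np.nonzero(np.triu(A.values))
        for i, j in zip(iu, ju):
            fh.write(f"{chrom}\t{i * bs}\t{(i + 1) * bs}\t"
                     f"{chrom}\t{j * bs}\t{(j + 1) * bs}\t"
                     f"loop_{i}_{j}\t{A.values[i, j]:g}\n")
    with open(paths["signal"], "w") as fh:
        for k in np.nonzero(b.values)[0]:
            fh.write(f"{chrom}\t{k * bs}\t{(k + 1) * bs}\t{b.values[k] / bs:g}\n")
    return paths


def pair_specs(spec: SyntheticSpec, n_seeds: int):
    """Replicate/non-replicate spec variants across seeds (harness helper)."""
    return [replace(spec, seed=spec.seed + k) for k in range(n_seeds)]
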
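"""Signal-graph information exchange: blend 1D coverage with 2D structure.

The window's contact block is coverage-weighted (anchor signal added to the
loop weight), blurred with a small mean filter, and column-normalized into a
random-walk transition kernel.  The simplex-normalized enrichment signal is
then diffused over that chromatin graph for mu steps, so the processed
signal reflects both the original coverage and the contact topology.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import convolve2d

from .config import Config

log = logging.getLogger(__name__)

SIMPLEX_ATOL = 1e-9


@dataclass
class ProbabilitySignal:
    """Vector on the probability simplex.

    Flagged degenerate when it does not sum to 1: either the raw signal
    summed to zero (no normalization possible) or walk mass was dropped at
    isolated nodes.  Non-degenerate vectors sum to 1 within 1e-9.
    """

    values: np.ndarray
    degenerate: bool = False

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise ValueError("probability signal has negative entries")
        if not self.degenerate and abs(self.values.sum() - 1.0) > SIMPLEX_ATOL:
            raise ValueError("probability signal does not sum to 1")

    @property
    def n_bins(self) -> int:
        return self.values.shape[0]


@dataclass
class RandomWalkKernel:
    """mu-step transition matrix K = (A D^{-1})^mu over window bins.

    ``degree`` holds the column sums of the weighted adjacency; columns of
    zero degree (isolated nodes) yield zero columns in K.
    """

    K: np.ndarray
    mu: int
    degree: np.ndarray = field(default=None)

    def __post_init__(self):
        self.K = np.asarray(self.K, dtype=float)
        if np.any(self.K < 0):
            raise ValueError("kernel has negative entries")


def coverage_weight(A: np.ndarray, b: np.ndarray, mode: str = "all") -> np.ndarray:
    """Add anchor signal to loop weights: Ã_ij = A_ij + b_i + b_j.

    mode="all" applies the weighting to every cell (dense default);
    mode="support" only weights cells where a contact already exists.
    """
    A = np.asarray(A, dtype=float)
    b = np.asarray(b, dtype=float)
    if A.shape[0] != A.shape[1] or A.shape[0] != b.shape[0]:
        raise ValueError(f"dimension mismatch: A is {A.shape}, b is {b.shape}")
    weight = b[:, None] + b[None, :]
    if mode == "support":
        return A + weight * (A > 0)
    return A + weight


def mean_blur(A: np.ndarray, filter_bins: int = 3) -> np.ndarray:
    """2D mean filter; edge cells average over the in-bounds neighborhood only."""
    if filter_bins % 2 == 0:
        raise ValueError("filter_bins must be odd")
    A = np.asarray(A, dtype=float)
    if A.shape[0] < 2 or filter_bins == 1:
        return A.copy()
    kernel = np.ones((filter_bins, filter_bins))
    num = convolve2d(A, kernel, mode="same", boundary="fill", fillvalue=0.0)
    den = convolve2d(np.ones_like(A), kernel, mode="same", boundary="fill", fillvalue=0.0)
    return num / den


def build_kernel(A: np.ndarray, mu: int) -> RandomWalkKernel:
    """Column-normalize the weighted adjacency and raise to the mu-th power.

    K(mu) = (A D^{-1})^mu with D = diag of column sums; a mu-step Markov
    transition matrix.  Zero-degree columns produce zero columns (their
    count is logged); mu = 0 gives the identity.
    """
    A = np.asarray(A, dtype=float)
    if np.any(A < 0):
        raise ValueError("adjacency has negative entries")
    if int(mu) != mu or mu < 0:
        raise ValueError("mu must be an integer >= 0")
    degree = A.sum(axis=0)
    isolated = degree == 0
    if isolated.any():
        log.info("%d isolated node(s) in window graph", int(isolated.sum()))
    inv = np.where(isolated, 0.0, 1.0 / np.where(isolated, 1.0, degree))
    T = A * inv[None, :]  # A @ D^{-1}: scales column j by 1/degree_j
    K = np.linalg.matrix_power(T, int(mu)) if mu > 0 else np.eye(A.shape[0])
    return RandomWalkKernel(K=K, mu=int(mu), degree=degree)


def normalize_signal(b: np.ndarray) -> ProbabilitySignal:
    """Project the nonnegative signal onto the simplex: pi_i = b_i / sum(b)."""
    b = np.asarray(b, dtype=float)
    if np.any(b < 0):
        raise ValueError("signal has negative entries")
    total = b.sum()
    if total == 0:
        return ProbabilitySignal(np.zeros_like(b), degenerate=True)
    return ProbabilitySignal(b / total)


def random_walk(pi: ProbabilitySignal, K: RandomWalkKernel) -> ProbabilitySignal:
    """Diffuse the signal over the graph: pi* = K(mu) pi.

    The kernel is column-stochastic (column j holds the outgoing
    transition probabilities of node j), so it pushes probability mass
    forward along the walk: mass at node j moves to node i with
    probability proportional to the edge weight A_ij.  Acting on the
    column vector keeps pi* on the simplex whenever no mass is dropped at
    isolated nodes.
    """
    if pi.values.shape[0] != K.K.shape[0]:
        raise ValueError("signal and kernel dimensions do not match")
    out = K.K @ pi.values
    degenerate = pi.degenerate or abs(out.sum() - 1.0) > SIMPLEX_ATOL
    return ProbabilitySignal(out, degenerate=degenerate)


def process_window(A_win: np.ndarray, b_win: np.ndarray,
                   config: Config | None = None) -> ProbabilitySignal:
    """Full exchange for one window: weight, blur, walk.

    Iterates mu single-step products (pi <- T^T pi) rather than forming the
    dense mu-step kernel; mathematically identical and cheaper for large
    windows.
    """
    config = config or Config()
    At = coverage_weight(A_win, b_win, mode=config.coverage_weight_mode)
    At = mean_blur(At)
    pi = normalize_signal(b_win)
    if pi.degenerate or config.mu == 0:
        return pi
    one_step = build_kernel(At, 1)
    values = pi.values
    for _ in range(config.mu):
        values = one_step.K @ values
    return ProbabilitySignal(values,
                             degenerate=abs(values.sum() - 1.0) > SIMPLEX_ATOL)
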
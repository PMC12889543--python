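"""Window-level similarity between two processed enrichment signals.

Two comparison methods: Spearman rank correlation of the processed
signals, or a transformed Jensen-Shannon divergence mapped onto [-1, 1]
via 2(1 - JSD) - 1 with base-2 logarithms (so JSD itself lies in [0, 1]).
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .sgie import ProbabilitySignal


def spearman_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """Spearman rank correlation with average ranks for ties.

    Returns NaN for constant vectors (undefined correlation; the window
    is treated as degenerate upstream).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("inputs must be equal-length vectors of size >= 2")
    if np.all(a == a[0]) or np.all(b == b[0]):
        return float("nan")
    rho = stats.spearmanr(a, b).statistic
    return float(rho)


def kl_divergence(a: np.ndarray, b: np.ndarray) -> float:
    """KL divergence sum_i a_i log2(a_i / b_i), with 0*log(0) = 0."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    mask = a > 0
    return float(np.sum(a[mask] * np.log2(a[mask] / b[mask])))


def jsd_similarity(a, b) -> float:
    """Transformed Jensen-Shannon similarity 2(1 - JSD(a, b)) - 1.

    JSD(a, b) = 0.5 KL(a || q) + 0.5 KL(b || q) with mixture
    q = 0.5 a + 0.5 b and base-2 logarithms, so JSD is in [0, 1]; the
    returned score is in [-1, 1], with 1 for identical distributions and
    -1 for disjoint supports.
    """
    av = a.values if isinstance(a, ProbabilitySignal) else np.asarray(a, dtype=float)
    bv = b.values if isinstance(b, ProbabilitySignal) else np.asarray(b, dtype=float)
    if av.shape != bv.shape:
        raise ValueError("inputs must have equal length")
    for name, v in (("a", av), ("b", bv)):
        if np.any(v < 0) or abs(v.sum() - 1.0) > 1e-6:
            raise ValueError(f"input {name} is not a probability vector")
    q = 0.5 * av + 0.5 * bv
    jsd = 0.5 * kl_divergence(av, q) + 0.5 * kl_divergence(bv, q)
    return float(2.0 * (1.0 - jsd) - 1.0)


def window_score(a: ProbabilitySignal, b: ProbabilitySignal,
                 method: str = "spearman") -> float:
    """Score one window; NaN marks a degenerate (unscorable) window."""
    if a.degenerate or b.degenerate:
        return float("nan")
    if method == "spearman":
        return spearman_similarity(a.values, b.values)
    if method == "jsd":
        return jsd_similarity(a, b)
    raise ValueError(f"unknown compare method {method!r}")
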
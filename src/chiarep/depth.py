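"""Binomial sequencing-depth adjustment for sample pairs.

Round one matches the deeper library to the shallower one in expectation:
entries of the higher-total matrix (or vector) are replaced by
Binomial(count, T_low / T_high) draws; the lower-total input is left
unchanged.  Round two further downsamples both to a fraction p.  Matrices
are sampled on the upper triangle and mirrored so symmetry is exact.
This is an evaluation utility for depth-robustness studies, not a
normalization.
"""

from __future__ import annotations

import warnings

import numpy as np


def _as_int(x: np.ndarray, name: str) -> np.ndarray:
    xi = np.rint(x)
    if not np.allclose(x, xi):
        warnings.warn(f"{name}: non-integer counts rounded before binomial sampling",
                      stacklevel=3)
    return xi.astype(np.int64)


def _binomial_symmetric(A: np.ndarray, p: float, rng: np.random.Generator) -> np.ndarray:
    """Entrywise Binomial(A_ij, p) on the upper triangle, mirrored."""
    n = A.shape[0]
    counts = _as_int(A, "contact matrix")
    iu = np.triu_indices(n)
    drawn = rng.binomial(counts[iu], p)
    out = np.zeros_like(counts)
    out[iu] = drawn
    out = out + np.triu(out, 1).T
    return out.astype(float)


def subsample(values: np.ndarray, p: float, seed=None) -> np.ndarray:
    """Entrywise binomial thinning to fraction p.

    Matrices are sampled on the upper triangle (diagonal once) and
    mirrored; vectors entrywise.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"subsampling fraction must be in [0, 1], got {p}")
    rng = np.random.default_rng(seed)
    values = np.asarray(values, dtype=float)
    if p == 1.0:
        return values.copy()
    if values.ndim == 2:
        return _binomial_symmetric(values, p, rng)
    counts = _as_int(values, "signal vector")
    return rng.binomial(counts, p).astype(float)


def match_depth(x1: np.ndarray, x2: np.ndarray, seed=None) -> tuple[np.ndarray, np.ndarray]:
    """Subsample the deeper input so expected totals match the shallower one.

    Works on symmetric matrices or 1-D vectors.  If the totals are equal
    (or either is zero) both inputs are returned unchanged.
    """
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    t1, t2 = x1.sum(), x2.sum()
    if t1 == 0 or t2 == 0:
        if t1 == 0 and t2 == 0:
            warnings.warn("both inputs have zero total; depth matching skipped",
                          stacklevel=2)
        return x1.copy(), x2.copy()
    if t1 == t2:
        return x1.copy(), x2.copy()
    if t1 > t2:
        return subsample(x1, t2 / t1, seed), x2.copy()
    return x1.copy(), subsample(x2, t1 / t2, seed)


def adjust_pair(A1, b1, A2, b2, p: float = 1.0, seed=None):
    """Two-round adjustment of a full sample pair (contacts and signals).

    Round 1 depth-matches contacts to contacts and signals to signals;
    round 2 thins all four to fraction p.  Seeds for the four streams are
    derived deterministically from ``seed``.
    """
    ss = np.random.SeedSequence(seed)
    seeds = [s.generate_state(1)[0] % (2**31) for s in ss.spawn(6)]
    A1m, A2m = match_depth(A1, A2, seeds[0])
    b1m, b2m = match_depth(b1, b2, seeds[1])
    if p < 1.0:
        A1m = subsample(A1m, p, seeds[2])
        A2m = subsample(A2m, p, seeds[3])
        b1m = subsample(b1m, p, seeds[4])
        b2m = subsample(b2m, p, seeds[5])
    return A1m, b1m, A2m, b2m
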
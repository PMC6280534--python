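"""Exact-test and multiple-testing primitives shared across the pipeline.

The two-sided Fisher test uses the "minimum likelihood" definition: the
p-value is the sum of hypergeometric probabilities of all tables (with the
same margins) that are no more probable than the observed one.  Small tables
are evaluated in exact integer arithmetic; large tables fall back to a
log-gamma formulation.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.special import gammaln

__all__ = ["fisher_exact_2x2", "fisher_exact_2x2_many", "bh_adjust"]

# Relative tolerance used to detect probability ties in the float path.
_TIE_REL = 1.0 + 1e-7

# Tables with grand total up to this size are computed exactly with integers.
_EXACT_N_MAX = 500


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p-value for the table [[a, b], [c, d]].

    Parameters
    ----------
    a, b, c, d:
        Non-negative integer cell counts; at least one margin must be
        non-zero.

    Returns
    -------
    float
        Two-sided p-value obtained by summing hypergeometric probabilities
        less than or equal to that of the observed table.
    """
    cells = (a, b, c, d)
    if any(x < 0 for x in cells):
        raise ValueError(f"negative cell count in table {cells}")
    if not any(int(x) == x for x in cells):
        raise ValueError(f"non-integer cell count in table {cells}")
    a, b, c, d = (int(x) for x in cells)
    n = a + b + c + d
    if n == 0:
        raise ValueError("all margins are zero; Fisher test undefined")
    if n <= _EXACT_N_MAX:
        return _fisher_exact_int(a, b, c, d)
    return float(
        fisher_exact_2x2_many(
            np.array([a]), np.array([b]), np.array([c]), np.array([d])
        )[0]
    )


def _fisher_exact_int(a: int, b: int, c: int, d: int) -> float:
    """Exact integer-arithmetic Fisher p (small tables)."""
    m1 = a + b  # row 1 margin
    m2 = c + d
    n1 = a + c  # column 1 margin
    n = m1 + m2
    k_min = max(0, n1 - m2)
    k_max = min(n1, m1)
    # Unnormalised hypergeometric weights are integers, so ties are exact.
    w_obs = math.comb(m1, a) * math.comb(m2, c)
    total = 0
    for k in range(k_min, k_max + 1):
        w = math.comb(m1, k) * math.comb(m2, n1 - k)
        if w <= w_obs:
            total += w
    return total / math.comb(n, n1)


def fisher_exact_2x2_many(
    a: np.ndarray,
    b: np.ndarray,
    c: np.ndarray,
    d: np.ndarray,
    chunk_elems: int = 5_000_000,
) -> np.ndarray:
    """Vectorised two-sided Fisher exact test over arrays of 2x2 tables.

    Uses a log-gamma evaluation of the hypergeometric pmf over the full
    support of each table, flattened across tables for speed.  Tables are
    processed in chunks bounded by ``chunk_elems`` support points to cap
    memory.
    """
    a = np.asarray(a, dtype=np.int64)
    b = np.asarray(b, dtype=np.int64)
    c = np.asarray(c, dtype=np.int64)
    d = np.asarray(d, dtype=np.int64)
    if a.shape != b.shape or a.shape != c.shape or a.shape != d.shape:
        raise ValueError("cell arrays must share a shape")
    if min(a.min(initial=0), b.min(initial=0), c.min(initial=0), d.min(initial=0)) < 0:
        raise ValueError("negative cell count")

    m1 = a + b
    m2 = c + d
    n1 = a + c
    k_min = np.maximum(0, n1 - m2)
    k_max = np.minimum(n1, m1)
    support = (k_max - k_min + 1).astype(np.int64)

    out = np.ones(a.shape, dtype=np.float64)
    order = np.arange(a.size)
    # Process in chunks of bounded flattened support size.
    cuts = np.searchsorted(np.cumsum(support), np.arange(0, support.sum() + chunk_elems, chunk_elems))
    for lo, hi in zip(cuts[:-1], cuts[1:]):
        idx = order[lo:hi]
        if idx.size == 0:
            continue
        out[idx] = _fisher_chunk(a[idx], m1[idx], m2[idx], n1[idx], k_min[idx], support[idx])
    return out


def _fisher_chunk(a, m1, m2, n1, k_min, support):
    n = m1 + m2
    offsets = np.concatenate(([0], np.cumsum(support)[:-1]))
    total = int(support.sum())
    # Ragged arange: k value for every support point of every table.
    k = np.arange(total) - np.repeat(offsets, support) + np.repeat(k_min, support)
    rm1 = np.repeat(m1, support)
    rm2 = np.repeat(m2, support)
    rn1 = np.repeat(n1, support)
    log_pmf = (
        gammaln(rm1 + 1)
        - gammaln(k + 1)
        - gammaln(rm1 - k + 1)
        + gammaln(rm2 + 1)
        - gammaln(rn1 - k + 1)
        - gammaln(rm2 - rn1 + k + 1)
    )
    rn = np.repeat(n, support)
    log_pmf -= gammaln(rn + 1) - gammaln(rn1 + 1) - gammaln(rn - rn1 + 1)
    pmf = np.exp(log_pmf)
    p_obs = pmf[offsets + (a - k_min)]
    keep = pmf <= np.repeat(p_obs, support) * _TIE_REL
    sums = np.add.reduceat(np.where(keep, pmf, 0.0), offsets)
    return np.minimum(sums, 1.0)


def bh_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=np.float64)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m, dtype=np.float64)
    out[order] = adjusted
    return out
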
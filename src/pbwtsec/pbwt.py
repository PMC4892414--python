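"""Positional Burrows-Wheeler transform and plaintext set-longest-match search.

The PBWT reorders a haplotype panel column by column: sequences in column k
are sorted (stably) by their reverse prefix of length k, i.e. by positions
k, k-1, ..., 1, and the column stores each sequence's (k+1)-th symbol.
Sequences sharing the same recent suffix are thereby contiguous, so the set
of haplotypes matching a query prefix starting at any position t is always a
half-open interval (f, g] over 0..M, and the interval is extended by one
query symbol with two O(1) lookups in a rank/CF table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .panel import HaplotypePanel

__all__ = [
    "PBWTIndex",
    "LookupVector",
    "MatchInterval",
    "build_pbwt",
    "rank",
    "cf",
    "lookup_vector",
    "update_interval",
    "set_longest_match_plain",
]


@dataclass(frozen=True)
class PBWTIndex:
    """PBWT matrix P (M x N, columns 0..N-1) and per-column positional
    prefix arrays A (N x M, entries are 1-based original row numbers).

    Column k of P holds the (k+1)-th symbols of the haplotypes sorted by
    reverse prefix of length k; ties keep original row order, so the index
    is deterministic.
    """

    P: np.ndarray
    prefix_arrays: np.ndarray
    alphabet_size: int

    @property
    def M(self) -> int:
        return int(self.P.shape[0])

    @property
    def N(self) -> int:
        return int(self.P.shape[1])

    def column(self, k: int) -> np.ndarray:
        if not 0 <= k < self.N:
            raise ValueError(f"column index {k} out of range 0..{self.N - 1}")
        return self.P[:, k]


@dataclass(frozen=True)
class LookupVector:
    """The length-(M+1) interval-update table v_c for one column and symbol.

    v_c[0] = CF_c(column) and v_c[i] = CF_c + Rank_c(column, i) for i >= 1,
    so updating an interval endpoint is a single indexed read.
    """

    values: np.ndarray
    symbol: int
    column: int


@dataclass(frozen=True)
class MatchInterval:
    """Left-open right-closed interval (f, g] over 0..M; g - f counts the
    haplotypes matching the query prefix consumed so far."""

    f: int
    g: int

    def __post_init__(self) -> None:
        if not 0 <= self.f <= self.g:
            raise ValueError(f"invalid interval ({self.f}, {self.g}]")

    @property
    def size(self) -> int:
        return self.g - self.f


def build_pbwt(panel: HaplotypePanel) -> PBWTIndex:
    """Build the PBWT of a panel.

    Uses the incremental construction: the ordering for column k+1 is a
    stable counting-sort of the ordering for column k on symbol x[.][k+1],
    which realizes the reverse-prefix sort radix-wise.
    """
    x = panel.sequences
    m, n = x.shape
    P = np.empty((m, n), dtype=x.dtype)
    A = np.empty((n, m), dtype=np.int64)
    order = np.arange(m)
    for k in range(n):
        P[:, k] = x[order, k]
        A[k] = order + 1
        order = order[np.argsort(x[order, k], kind="stable")]
    return PBWTIndex(P=P, prefix_arrays=A, alphabet_size=panel.alphabet_size)


def rank(column: np.ndarray, c: int, t: int) -> int:
    """Occurrences of symbol c among the first t entries of a column."""
    column = np.asarray(column)
    if not 0 <= t <= len(column):
        raise ValueError(f"rank position {t} out of range 0..{len(column)}")
    return int(np.count_nonzero(column[:t] == c))


def cf(column: np.ndarray, c: int, alphabet_size: int | None = None) -> int:
    """Count of symbols strictly smaller than c in the whole column."""
    if c < 0 or (alphabet_size is not None and c >= alphabet_size):
        raise ValueError(f"symbol {c} out of alphabet range")
    return int(np.count_nonzero(np.asarray(column) < c))


def lookup_vector(index: PBWTIndex, k: int, c: int) -> LookupVector:
    """The interval-update table v_c for column k of the PBWT."""
    if not 0 <= c < index.alphabet_size:
        raise ValueError(f"symbol {c} out of alphabet range")
    col = index.column(k)
    base = cf(col, c)
    values = np.empty(len(col) + 1, dtype=np.int64)
    values[0] = base
    np.cumsum(col == c, out=values[1:])
    values[1:] += base
    return LookupVector(values=values, symbol=c, column=k)


def update_interval(iv: MatchInterval, v: LookupVector) -> MatchInterval:
    """Extend a match interval by the symbol of the lookup vector."""
    return MatchInterval(int(v.values[iv.f]), int(v.values[iv.g]))


def set_longest_match_plain(
    index: PBWTIndex,
    query,
    t: int,
    eps: int = 1,
) -> tuple[int, int]:
    """Longest query prefix, starting at genomic position t, matched by at
    least eps panel haplotypes.

    Returns ``(match_length, matching_count)`` where matching_count is the
    number of haplotypes matching that longest prefix (all M of them when
    match_length is 0).  The search starts from the full interval (0, M]
    and reads lookup vectors at columns t-1, t, ...
    """
    query = np.asarray(query)
    ell = len(query)
    if ell < 1:
        raise ValueError("query must be non-empty")
    if not 1 <= t <= index.N:
        raise ValueError(f"start position {t} out of range 1..{index.N}")
    if t + ell - 1 > index.N:
        raise ValueError("query runs past the last panel position")
    if not 1 <= eps <= index.M:
        raise ValueError(f"anonymity level eps must lie in 1..{index.M}")
    iv = MatchInterval(0, index.M)
    for i in range(ell):
        v = lookup_vector(index, t - 1 + i, int(query[i]))
        nxt = update_interval(iv, v)
        if nxt.size < eps:
            return i, iv.size
        iv = nxt
    return ell, iv.size
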
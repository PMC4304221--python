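"""Suffix array, LCP array and companion structures for repeat detection.

The landscape sweep needs, for one string ``s`` of length ``n``:

* the suffix array ``sa`` (here length ``n + 1``: a sentinel smaller than
  every alphabet symbol is appended internally, so the sentinel-only suffix
  always sits at rank 0);
* the LCP array ``lcp`` with ``lcp[r]`` = length of the longest common
  prefix of the suffixes at ranks ``r`` and ``r + 1``;
* the inverse permutation ``inv`` with ``inv[sa[r]] = r``;
* the ``sp`` array (the psi function): ``sp[r]`` is the rank of the suffix
  obtained by deleting the first character of the suffix at rank ``r``;
* a range-minimum structure over ``lcp`` so that "the maximal run of
  rank-adjacent suffixes around ``r`` sharing a prefix of length >= h" is
  answered in O(log n).

All arrays are 0-based internally; the sentinel is stripped from every
user-facing report.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SourceString",
    "SuffixStructures",
    "RankInterval",
    "build_suffix_structures",
    "compute_sp_array",
    "lcp_interval",
]

DNA_ALPHABET = "ACGTN"

#: marker for "this suffix has no successor" (the sentinel-only suffix)
NO_SUCCESSOR = -1


class AlphabetError(ValueError):
    """A symbol outside the configured alphabet was encountered."""


@dataclass(frozen=True)
class SourceString:
    """A normalized input string over a fixed, totally ordered alphabet.

    ``text`` is uppercased on construction; the sentinel is *not* part of
    ``text`` — it is appended internally by :func:`build_suffix_structures`
    and is strictly smaller than every alphabet symbol.
    """

    text: str
    alphabet: str = DNA_ALPHABET

    def __post_init__(self) -> None:
        up = self.text.upper()
        alpha = self.alphabet.upper()
        object.__setattr__(self, "text", up)
        object.__setattr__(self, "alphabet", alpha)
        if len(up) == 0:
            raise ValueError("input string is empty")
        allowed = set(alpha)
        for i, c in enumerate(up):
            if c not in allowed:
                raise AlphabetError(
                    f"symbol {c!r} at position {i + 1} is not in alphabet {alpha!r}"
                )

    @property
    def n(self) -> int:
        return len(self.text)

    def codes(self) -> np.ndarray:
        """Integer codes incl. trailing sentinel code 0; symbols get 1..m in sort order."""
        order = {c: i + 1 for i, c in enumerate(sorted(set(self.alphabet)))}
        out = np.zeros(self.n + 1, dtype=np.int64)
        for i, c in enumerate(self.text):
            out[i] = order[c]
        return out


@dataclass(frozen=True)
class RankInterval:
    """A closed interval [lo, hi] of suffix-array ranks."""

    lo: int
    hi: int

    def __post_init__(self) -> None:
        if self.lo > self.hi:
            raise ValueError(f"invalid rank interval [{self.lo}, {self.hi}]")

    @property
    def width(self) -> int:
        return self.hi - self.lo + 1


class _SparseTableRMQ:
    """O(n log n) / O(1) range-minimum over a fixed integer array."""

    def __init__(self, values: np.ndarray) -> None:
        a = np.asarray(values, dtype=np.int64)
        n = len(a)
        levels = max(1, n.bit_length())
        table = [a]
        span = 1
        while 2 * span <= n:
            prev = table[-1]
            table.append(np.minimum(prev[: n - 2 * span + 1], prev[span : n - span + 1]))
            span *= 2
        self._table = table
        self._n = n

    def query(self, i: int, j: int) -> int:
        """min(values[i..j]) inclusive; i <= j required."""
        if not (0 <= i <= j < self._n):
            raise IndexError(f"RMQ range [{i}, {j}] out of bounds for n={self._n}")
        k = (j - i + 1).bit_length() - 1
        t = self._table[k]
        return int(min(t[i], t[j - (1 << k) + 1]))


@dataclass
class SuffixStructures:
    """Suffix array and companions for one :class:`SourceString`.

    ``sa``/``inv`` have length ``n + 1`` (sentinel suffix included);
    ``lcp`` has length ``n`` (one entry per rank-adjacent pair).
    """

    source: SourceString
    sa: np.ndarray
    lcp: np.ndarray
    inv: np.ndarray
    sp: np.ndarray = field(default=None)  # type: ignore[assignment]
    _rmq: _SparseTableRMQ = field(default=None, repr=False)  # type: ignore[assignment]

    @property
    def n(self) -> int:
        return self.source.n

    def suffix_length(self, rank: int) -> int:
        """Length of the suffix at ``rank``, sentinel excluded."""
        return self.n - int(self.sa[rank])


def _suffix_array_doubling(codes: np.ndarray) -> np.ndarray:
    """Prefix-doubling suffix array over integer codes (last entry = sentinel 0)."""
    n = len(codes)
    rank = np.asarray(codes, dtype=np.int64).copy()
    tmp = np.empty(n, dtype=np.int64)
    k = 1
    while True:
        # sort by (rank[i], rank[i + k]) with rank past the end treated as -1
        second = np.full(n, -1, dtype=np.int64)
        second[: n - k] = rank[k:]
        sa = np.lexsort((second, rank))
        tmp[sa[0]] = 0
        prev = sa[:-1]
        curr = sa[1:]
        newgrp = (rank[curr] != rank[prev]) | (second[curr] != second[prev])
        tmp[curr] = np.cumsum(newgrp)
        rank, tmp = tmp, rank
        if int(rank[sa[-1]]) == n - 1:
            break
        k *= 2
    return sa.astype(np.int64)


def _kasai_lcp(codes: np.ndarray, sa: np.ndarray, inv: np.ndarray) -> np.ndarray:
    """Kasai's O(n) LCP construction; lcp[r] compares ranks r and r+1."""
    n = len(codes)
    lcp = np.zeros(n - 1, dtype=np.int64)
    h = 0
    for i in range(n):
        r = int(inv[i])
        if r == n - 1:
            h = 0
            continue
        j = int(sa[r + 1])
        while i + h < n and j + h < n and codes[i + h] == codes[j + h]:
            h += 1
        lcp[r] = h
        if h > 0:
            h -= 1
    return lcp


def build_suffix_structures(text: SourceString | str, alphabet: str = DNA_ALPHABET) -> SuffixStructures:
    """Build sa/lcp/inv/sp and the RMQ for ``text`` (sentinel appended internally)."""
    src = text if isinstance(text, SourceString) else SourceString(text, alphabet)
    codes = src.codes()
    sa = _suffix_array_doubling(codes)
    inv = np.empty_like(sa)
    inv[sa] = np.arange(len(sa))
    lcp = _kasai_lcp(codes, sa, inv)
    ss = SuffixStructures(source=src, sa=sa, lcp=lcp, inv=inv)
    ss.sp = compute_sp_array(ss)
    ss._rmq = _SparseTableRMQ(lcp) if len(lcp) else None
    return ss


def compute_sp_array(ss: SuffixStructures) -> np.ndarray:
    """sp[r] = inv[sa[r] + 1]; the sentinel-only suffix maps to NO_SUCCESSOR.

    One vectorized scan of the index array — O(n).
    """
    n1 = len(ss.sa)
    sp = np.full(n1, NO_SUCCESSOR, dtype=np.int64)
    has_next = ss.sa + 1 < n1
    sp[has_next] = ss.inv[ss.sa[has_next] + 1]
    return sp


def lcp_interval(ss: SuffixStructures, rank: int, h: int) -> RankInterval | None:
    """Maximal interval of ranks around ``rank`` sharing a prefix of length >= h.

    Every pair of rank-adjacent suffixes inside the returned interval has
    lcp >= h, and the interval cannot be extended. Its width equals the
    number of (overlap-counted) occurrences of the length-``h`` prefix of
    the suffix at ``rank``. Returns ``None`` when that suffix is shorter
    than ``h`` (no length-``h`` prefix exists — the "empty extension" case).

    O(log n): two binary searches over the O(1) range-minimum structure.
    """
    if h < 1:
        raise ValueError("h must be >= 1")
    n1 = len(ss.sa)
    if not 0 <= rank < n1:
        raise IndexError(f"rank {rank} out of range [0, {n1 - 1}]")
    if ss.suffix_length(rank) < h:
        return None
    rmq = ss._rmq
    if rmq is None:  # n == 1: single real suffix
        return RankInterval(rank, rank)

    # largest u >= rank with min(lcp[rank .. u-1]) >= h
    lo, hi = rank, n1 - 1
    while lo < hi:
        mid = (lo + hi + 1) // 2
        if rmq.query(rank, mid - 1) >= h:
            lo = mid
        else:
            hi = mid - 1
    u = lo
    # smallest d <= rank with min(lcp[d .. rank-1]) >= h
    lo, hi = 0, rank
    while lo < hi:
        mid = (lo + hi) // 2
        if rmq.query(mid, rank - 1) >= h:
            hi = mid
        else:
            lo = mid + 1
    d = lo
    return RankInterval(d, u)
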
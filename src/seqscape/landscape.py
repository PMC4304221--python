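"""The maximal sequence landscape: the longest repeat covering each position.

A *mountain* is one occurrence ``(begin, end, freq)`` of a substring that
occurs at least twice in the string; its height is its length. The *cover
set* of position ``i`` holds every mountain of height > 1 and frequency > 1
whose span contains ``i``, and the *summit* of ``i`` is a highest mountain
of that set (height 0 when the set is empty). The maximal sequence
landscape (MSL) records the summit height — the length of the longest
repeated substring covering the position — for every position at once.

Construction is a left-to-right sweep over the text that maintains the
suffix-array interval ``[sa_lo, sa_hi]`` of the current longest repeated
substring ending at the cursor. Appending the next character either
extends it (an *ascent*, a binary search that narrows the interval) or
fails, in which case the leading character is dropped (a *descent*: one
``sp`` lookup to shift the suffix, one O(log n) LCP-interval query to
recover the interval) until the extension repeats again or the string
empties. Every ascent consumes one character and descents only undo
ascents, so the sweep performs at most ``2n`` steps in total.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import numpy as np

from .suffix import (
    DNA_ALPHABET,
    RankInterval,
    SourceString,
    SuffixStructures,
    build_suffix_structures,
    lcp_interval,
)

__all__ = [
    "Mountain",
    "MslIndex",
    "SweepState",
    "build_msl",
    "brute_force_msl",
    "summit_at",
]

#: refuse the cubic oracle above this length
ORACLE_BOUND = 2000


@dataclass(frozen=True)
class Mountain:
    """One occurrence of a repeated substring. Coordinates are 0-based inclusive."""

    begin: int
    end: int
    freq: int

    @property
    def height(self) -> int:
        return self.end - self.begin + 1

    def __post_init__(self) -> None:
        if self.begin > self.end:
            raise ValueError("mountain begin must not exceed end")
        if self.height < 2 or self.freq < 2:
            raise ValueError("a mountain needs height >= 2 and frequency >= 2")


@dataclass
class SweepState:
    """Instrumentation for the sweep; exposes the ascent/descent step counts."""

    sa_lo: int = 0
    sa_hi: int = 0
    match_begin: int = 0
    pos: int = 0
    ascents: int = 0
    descents: int = 0

    @property
    def steps(self) -> int:
        return self.ascents + self.descents


@dataclass
class MslIndex:
    """Per-position summit heights (0 where no repeat covers the position).

    ``summits[i]`` is a representative highest mountain covering ``i`` —
    among equally high candidates, the one with the smallest begin — or
    ``None`` where ``heights[i] == 0``. Heights are never 1: single
    characters are excluded from cover sets by definition.
    """

    source: SourceString
    heights: np.ndarray
    summits: list[Mountain | None]
    state: SweepState = field(default_factory=SweepState)

    @property
    def n(self) -> int:
        return self.source.n


def summit_at(msl: MslIndex, i: int) -> Mountain | None:
    """The stored summit covering 0-based position ``i``, or None (height 0)."""
    if not 0 <= i < msl.n:
        raise IndexError(f"position {i} out of range [0, {msl.n - 1}]")
    return msl.summits[i]


def _extend_interval(
    ss: SuffixStructures, lo: int, hi: int, offset: int, code: int
) -> tuple[int, int] | None:
    """Narrow [lo, hi] to the suffixes whose symbol at ``offset`` equals ``code``.

    All suffixes in [lo, hi] share a prefix of length ``offset``, so their
    codes at ``offset`` are non-decreasing with rank; two binary searches
    find the run. Returns None when empty.
    """
    codes, sa = ss._codes, ss.sa

    # leftmost rank with symbol >= code
    a, b = lo, hi + 1
    while a < b:
        mid = (a + b) // 2
        if codes[sa[mid] + offset] >= code:
            b = mid
        else:
            a = mid + 1
    left = a
    if left > hi or codes[sa[left] + offset] != code:
        return None
    # rightmost rank with symbol == code
    a, b = left, hi
    while a < b:
        mid = (a + b + 1) // 2
        if codes[sa[mid] + offset] == code:
            a = mid
        else:
            b = mid - 1
    return left, a


def build_msl(text: SourceString | str, alphabet: str = DNA_ALPHABET,
              ss: SuffixStructures | None = None,
              trace: list | None = None) -> MslIndex:
    """Build the maximal sequence landscape of ``text`` in O(n log n).

    For every position ``i``, ``heights[i]`` is the maximum length of a
    substring that covers ``i``, has length >= 2 and occurs >= 2 times in
    the text (overlapping occurrences counted), or 0 when no such substring
    exists. The sweep is instrumented: ``result.state`` reports the ascent
    and descent counts, whose sum never exceeds ``2n``.
    """
    src = text if isinstance(text, SourceString) else SourceString(text, alphabet)
    if ss is None:
        ss = build_suffix_structures(src)
    codes = src.codes()
    ss._codes = codes  # cached for the binary searches
    n = src.n
    full = (0, n)  # all n + 1 suffixes

    state = SweepState()
    # longest repeated substring ending at each position, with its frequency
    ends = np.zeros(n, dtype=np.int64)
    freqs = np.zeros(n, dtype=np.int64)

    lo, hi = full
    length = 0  # current stem: text[i - length .. i - 1]
    for i in range(n):
        c = int(codes[i])
        while True:
            ext = _extend_interval(ss, lo, hi, length, c)
            if ext is not None and ext[1] - ext[0] + 1 >= 2:
                lo, hi = ext
                length += 1
                state.ascents += 1
                break
            if length == 0:
                lo, hi = full
                break
            # drop the leading character: sp shift + LCP-interval recovery
            state.descents += 1
            length -= 1
            if length == 0:
                lo, hi = full
            else:
                sp = int(ss.sp[lo])
                iv = lcp_interval(ss, sp, length)
                lo, hi = iv.lo, iv.hi
        ends[i] = length
        freqs[i] = hi - lo + 1 if length > 0 else 0
        state.pos = i
        state.sa_lo, state.sa_hi = lo, hi
        state.match_begin = i - length + 1
        if trace is not None:
            trace.append((i, lo, hi, length))

    # heights/summits: interval-max over the mountains (b_i, i) swept right-to-left
    heights = np.zeros(n, dtype=np.int64)
    summits: list[Mountain | None] = [None] * n
    heap: list[tuple[int, int, int, int]] = []  # (-height, begin, end, freq)
    mountains: dict[tuple[int, int], Mountain] = {}
    for j in range(n - 1, -1, -1):
        h = int(ends[j])
        if h >= 2:
            heapq.heappush(heap, (-h, j - h + 1, j, int(freqs[j])))
        while heap and heap[0][1] > j:
            heapq.heappop(heap)
        if heap:
            negh, b, e, f = heap[0]
            heights[j] = -negh
            key = (b, e)
            if key not in mountains:
                mountains[key] = Mountain(begin=b, end=e, freq=f)
            summits[j] = mountains[key]

    return MslIndex(source=src, heights=heights, summits=summits, state=state)


def brute_force_msl(text: SourceString | str, alphabet: str = DNA_ALPHABET,
                    bound: int = ORACLE_BOUND) -> MslIndex:
    """Exhaustive-counting oracle for :func:`build_msl` (test use only).

    Walks substring lengths upward, hashing every window of the current
    length; positions covered by a window occurring >= 2 times are stamped
    with that length (longer lengths overwrite, so the final stamp is the
    maximum). Stops at the first length with no repeat. Ties at the final
    height keep the occurrence with the smallest begin, which the
    ascending-begin stamping order gives for free. Refuses inputs longer
    than ``bound``.
    """
    src = text if isinstance(text, SourceString) else SourceString(text, alphabet)
    n = src.n
    if n > bound:
        raise ValueError(f"oracle refuses n={n} > bound={bound}")
    s = src.text
    heights = np.zeros(n, dtype=np.int64)
    summits: list[Mountain | None] = [None] * n
    for length in range(2, n):
        occ: dict[str, list[int]] = {}
        for b in range(n - length + 1):
            occ.setdefault(s[b : b + length], []).append(b)
        begins = sorted(
            (b, len(positions))
            for positions in occ.values()
            if len(positions) >= 2
            for b in positions
        )
        if not begins:
            break
        watermark = -1  # cells <= watermark already stamped at this length
        for b, freq in begins:
            lo = max(b, watermark + 1)
            hi = b + length - 1
            if lo > hi:
                continue
            m = Mountain(b, hi, freq)
            for i in range(lo, hi + 1):
                heights[i] = length
                summits[i] = m
            watermark = hi
    return MslIndex(source=src, heights=heights, summits=summits)
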
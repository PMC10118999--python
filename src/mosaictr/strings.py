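"""Suffix-structure primitives for repeat-unit discovery.

A tandem repeat (TR) is a stretch of DNA made of consecutive copies of a short
*unit*; a mosaic TR strings together runs of several distinct units, e.g.
``(AAAG)i (AG)j (AAAG)k``.  Any rotation of a unit generates the same repeat,
so to pick a canonical representative we restrict candidate units to
*non-self-overlapping* (borderless) substrings: strings in which no proper
suffix equals a prefix.  A candidate unit must additionally be *repetitive*,
i.e. occur at least twice in the input.

This module builds the suffix array and LCP array of the input, derives the
``LEN`` array (``LEN[i]`` = length of the longest substring starting at ``i``
that occurs at least twice), computes border arrays of suffixes with the
Morris-Pratt failure function, and combines them to enumerate all repetitive
non-self-overlapping substrings in O(n^2) time.  It also provides the
compression-ratio diagnostic quantifying how small that candidate pool is
relative to all distinct substrings.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AlphabetError",
    "EmptySequenceError",
    "DnaString",
    "SuffixStructures",
    "OverlapArray",
    "CandidateUnit",
    "CompressionStats",
    "border_array",
    "is_non_self_overlapping",
    "build_suffix_structures",
    "overlap_array",
    "enumerate_candidate_units",
    "compression_ratio",
]

DNA_ALPHABET = frozenset("ACGTN")


class AlphabetError(ValueError):
    """Raised when a sequence contains letters outside A/C/G/T/N."""


class EmptySequenceError(ValueError):
    """Raised when an operation requires a nonempty sequence."""


@dataclass(frozen=True)
class DnaString:
    """A DNA sequence over {A, C, G, T, N}.

    All coordinates into ``seq`` are 0-based, half-open ``[b, e)``.
    """

    seq: str

    def __post_init__(self) -> None:
        bad = set(self.seq) - DNA_ALPHABET
        if bad:
            raise AlphabetError(
                f"sequence contains non-DNA letters: {sorted(bad)!r}"
            )

    @property
    def n(self) -> int:
        return len(self.seq)

    def __len__(self) -> int:
        return len(self.seq)


def _suffix_array(seq: str) -> np.ndarray:
    """Suffix array by prefix doubling (O(n log n) vectorised rounds).

    Comparison-based construction is sufficient at the scales this package
    targets (reads of a few kb); only output correctness matters here.
    """
    n = len(seq)
    rank = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).astype(np.int64)
    if n == 1:
        return np.zeros(1, dtype=np.int64)
    k = 1
    order = np.argsort(rank, kind="stable")
    while True:
        second = np.full(n, -1, dtype=np.int64)
        if k < n:
            second[: n - k] = rank[k:]
        order = np.lexsort((second, rank))
        r_ord = rank[order]
        s_ord = second[order]
        diff = np.ones(n, dtype=bool)
        diff[1:] = (r_ord[1:] != r_ord[:-1]) | (s_ord[1:] != s_ord[:-1])
        new_rank = np.empty(n, dtype=np.int64)
        new_rank[order] = np.cumsum(diff) - 1
        rank = new_rank
        if rank[order[-1]] == n - 1:
            break
        k *= 2
    return order


def _lcp_kasai(seq: str, sa: np.ndarray) -> np.ndarray:
    """LCP array by Kasai's algorithm; lcp[i] pairs sa[i] with sa[i+1]."""
    n = len(seq)
    lcp = np.zeros(max(n - 1, 0), dtype=np.int64)
    rank = np.empty(n, dtype=np.int64)
    rank[sa] = np.arange(n)
    h = 0
    for i in range(n):
        r = rank[i]
        if r < n - 1:
            j = int(sa[r + 1])
            while i + h < n and j + h < n and seq[i + h] == seq[j + h]:
                h += 1
            lcp[r] = h
            if h:
                h -= 1
        else:
            h = 0
    return lcp


@dataclass(frozen=True)
class SuffixStructures:
    """Suffix array, LCP array and LEN array of a sequence.

    ``len_arr[i]`` is the length of the longest prefix of the suffix starting
    at ``i`` that occurs at least twice in the sequence.  Because occurrences
    of a repeated prefix are lexicographic neighbours, ``len_arr[sa[i]]`` is
    the larger of the LCPs with the two suffix-array neighbours of ``sa[i]``.
    """

    sa: np.ndarray
    lcp: np.ndarray
    len_arr: np.ndarray


def build_suffix_structures(s: DnaString) -> SuffixStructures:
    """Build suffix array, LCP array and LEN array for ``s``.

    Raises :class:`EmptySequenceError` on an empty sequence.
    """
    if s.n == 0:
        raise EmptySequenceError("cannot build suffix structures of ''")
    seq = s.seq
    n = s.n
    sa = _suffix_array(seq)
    lcp = _lcp_kasai(seq, sa)
    len_arr = np.zeros(n, dtype=np.int64)
    if n > 1:
        len_arr[sa[0]] = lcp[0]
        len_arr[sa[n - 1]] = lcp[n - 2]
        for i in range(1, n - 1):
            len_arr[sa[i]] = max(lcp[i - 1], lcp[i])
    return SuffixStructures(sa=sa, lcp=lcp, len_arr=len_arr)


def border_array(text: str) -> list[int]:
    """Morris-Pratt failure function of ``text``.

    Returns ``f`` of length ``len(text) + 1`` where ``f[k]`` is the length of
    the longest proper border of ``text[:k]`` (longest ``l < k`` with
    ``text[:l] == text[k-l:k]``).  ``f[0] == f[1] == 0``.
    """
    m = len(text)
    f = [0] * (m + 1)
    k = 0
    for q in range(1, m):
        while k and text[q] != text[k]:
            k = f[k]
        if text[q] == text[k]:
            k += 1
        f[q + 1] = k
    return f


def is_non_self_overlapping(text: str) -> bool:
    """True iff no proper suffix of ``text`` equals a prefix (borderless)."""
    return len(text) > 0 and border_array(text)[len(text)] == 0


@dataclass(frozen=True)
class OverlapArray:
    """Border lengths of every prefix of the suffix ``seq[start:]``.

    ``ol[k]`` (``1 <= k <= n - start``) is the longest proper border of
    ``seq[start:start+k]``; ``seq[start:start+k]`` is non-self-overlapping iff
    ``ol[k] == 0``.  ``ol[0]`` is a 0 sentinel so that ``ol`` can be indexed
    by prefix length directly.
    """

    start: int
    ol: list[int]

    def is_nsop(self, length: int) -> bool:
        return self.ol[length] == 0


def overlap_array(s: DnaString, i: int) -> OverlapArray:
    """Border array of the suffix ``s.seq[i:]`` (Morris-Pratt, O(n - i))."""
    if not 0 <= i < s.n:
        raise IndexError(f"suffix start {i} out of range for length {s.n}")
    return OverlapArray(start=i, ol=border_array(s.seq[i:]))


@dataclass(frozen=True)
class CandidateUnit:
    """A repetitive, non-self-overlapping substring proposed as a repeat unit.

    ``span`` is the leftmost occurrence ``(b, e)`` of ``text``.
    """

    text: str
    span: tuple[int, int]

    @property
    def length(self) -> int:
        return len(self.text)


def enumerate_candidate_units(
    s: DnaString, max_len: int = 100
) -> list[CandidateUnit]:
    """Enumerate all repetitive non-self-overlapping substrings of ``s``.

    A substring qualifies when it occurs at least twice (``LEN[i] >= j - i``
    at some occurrence ``i``), has no nonempty proper border, is at most
    ``max_len`` bases long, and contains no N.  Candidates are deduplicated
    by text; each keeps its leftmost occurrence as witness span.  The border
    array of each suffix is only computed out to ``min(LEN[i], max_len)``
    positions, so the whole enumeration is O(n * max_len) after the O(n log n)
    suffix-structure construction.
    """
    if max_len < 1:
        raise ValueError("max_len must be >= 1")
    structures = build_suffix_structures(s)
    len_arr = structures.len_arr
    seq = s.seq
    n = s.n
    seen: dict[str, tuple[int, int]] = {}
    for i in range(n):
        cap = min(int(len_arr[i]), max_len, n - i)
        if cap < 1:
            continue
        f = border_array(seq[i : i + cap])
        for length in range(1, cap + 1):
            if f[length] == 0:
                text = seq[i : i + length]
                if "N" in text:
                    continue
                if text not in seen:
                    seen[text] = (i, i + length)
    units = [CandidateUnit(text=t, span=sp) for t, sp in seen.items()]
    units.sort(key=lambda u: (u.length, u.text))
    return units


@dataclass(frozen=True)
class CompressionStats:
    """Size of the candidate-unit pool relative to all distinct substrings.

    ``w_all`` counts distinct substrings of length at most ``theta``;
    ``w_nsop`` counts those that are both repetitive (occur at least twice)
    and non-self-overlapping, i.e. exactly the unit candidates of length at
    most ``theta``.  ``ratio = w_nsop / w_all`` measures how drastically the
    borderless-and-repetitive restriction shrinks the set of units that unit
    selection has to consider.
    """

    w_all: int
    w_nsop: int
    theta: int
    ratio: float = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "ratio", self.w_nsop / self.w_all)


def compression_ratio(s: DnaString, theta: int = 20) -> CompressionStats:
    """Compute :class:`CompressionStats` for ``s`` with length cap ``theta``.

    Substrings are collected by direct hashing, which is linear in
    ``n * theta`` and adequate at read scale.
    """
    if s.n == 0:
        raise EmptySequenceError("cannot compute compression ratio of ''")
    if theta < 1:
        raise ValueError("theta must be >= 1")
    seq = s.seq
    n = s.n
    counts: Counter[str] = Counter()
    for i in range(n):
        m = min(theta, n - i)
        for length in range(1, m + 1):
            counts[seq[i : i + length]] += 1
    w_all = len(counts)
    w_nsop = sum(
        1
        for text, c in counts.items()
        if c >= 2 and "N" not in text and is_non_self_overlapping(text)
    )
    return CompressionStats(w_all=w_all, w_nsop=w_nsop, theta=theta)
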
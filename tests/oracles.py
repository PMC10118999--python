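"""Brute-force reference implementations used as independent test oracles.

Everything here follows the definitions directly (sorting suffix slices,
counting substring windows, enumerating tilings and unit concatenations)
and is deliberately independent of the package's algorithms.
"""

from __future__ import annotations

from collections import Counter
from functools import lru_cache
from itertools import product

import edlib


def brute_suffix_array(s: str) -> list[int]:
    return sorted(range(len(s)), key=lambda i: s[i:])


def brute_lcp(a: str, b: str) -> int:
    k = 0
    while k < len(a) and k < len(b) and a[k] == b[k]:
        k += 1
    return k


def substring_counter(s: str, max_len: int | None = None) -> Counter[str]:
    """Occurrence counts (overlapping) of every substring up to max_len."""
    n = len(s)
    cap = n if max_len is None else max_len
    counts: Counter[str] = Counter()
    for i in range(n):
        for length in range(1, min(cap, n - i) + 1):
            counts[s[i : i + length]] += 1
    return counts


def brute_len_arr(s: str) -> list[int]:
    counts = substring_counter(s)
    n = len(s)
    out = []
    for i in range(n):
        best = 0
        for length in range(1, n - i + 1):
            if counts[s[i : i + length]] >= 2:
                best = length
            else:
                break  # occurrence count is monotone in prefix length
        out.append(best)
    return out


def brute_border(t: str) -> int:
    for length in range(len(t) - 1, 0, -1):
        if t[:length] == t[-length:]:
            return length
    return 0


def brute_candidates(s: str, max_len: int) -> set[str]:
    counts = substring_counter(s, max_len)
    return {
        t
        for t, c in counts.items()
        if c >= 2 and "N" not in t and brute_border(t) == 0
    }


def brute_min_tiling_cost(s: str, units: tuple[str, ...]) -> int:
    """Minimum (occurrences + uncovered bases) over all tilings of ``s``."""

    @lru_cache(maxsize=None)
    def rec(j: int) -> int:
        if j == 0:
            return 0
        best = rec(j - 1) + 1  # uncovered letter
        for u in units:
            if j >= len(u) and s[j - len(u) : j] == u:
                best = min(best, rec(j - len(u)) + 1)
        return best

    return rec(len(s))


def brute_extended_penalty(s: str, units: tuple[str, ...]) -> int:
    return sum(len(u) for u in units) + brute_min_tiling_cost(s, units)


def levenshtein(a: str, b: str) -> int:
    if not a:
        return len(b)
    if not b:
        return len(a)
    return edlib.align(a, b, task="distance", mode="NW")["editDistance"]


def brute_concat_distance(
    s: str, units: tuple[str, ...], max_copies: int
) -> int:
    """Minimum edit distance of ``s`` to any concatenation of unit copies.

    The first copy may be replaced by any of its suffixes and the last by
    any of its prefixes (partial flanking copies).
    """
    best = None
    for m in range(1, max_copies + 1):
        for seq in product(units, repeat=m):
            first, last = seq[0], seq[-1]
            middle = "".join(seq[1:-1]) if m >= 2 else None
            for st in range(len(first)):
                head = first[st:]
                if m == 1:
                    # one copy: any substring u[st:en]
                    for en in range(st + 1, len(first) + 1):
                        d = levenshtein(s, first[st:en])
                        if best is None or d < best:
                            best = d
                else:
                    for en in range(1, len(last) + 1):
                        d = levenshtein(s, head + middle + last[:en])
                        if best is None or d < best:
                            best = d
    return best
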
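"""Parsimony-driven selection of repeat units.

Given a TR sequence ``S`` and a unit set ``U``, an *exact decomposition*
tiles ``S`` with segments that each either literally equal a unit of ``U`` or
are left uncovered.  Under maximum parsimony — fewer and shorter generating
units, created by fewer replication-slippage events, are preferred — the
quality of a decomposition ``D`` is its *penalty*

    sum over u in U of (|u| + o(u)),

where ``o(u)`` is the number of segments of ``D`` equal to ``u``.  To keep
rare, error-induced strings out of ``U`` the penalty is extended by the total
length of uncovered segments (*extended penalty*):

    sum over u in U of (|u| + o(u))  +  sum over uncovered segments of |s|.

Minimising the extended penalty jointly over ``U`` and ``D`` is conjectured
intractable (the fixed-``U`` decision version is NP-complete), so units are
selected greedily: starting from the empty set, each round adds the candidate
unit whose inclusion most decreases the extended penalty of the optimal
tiling, stopping when no candidate gives a strict decrease.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterator, Optional, Sequence

from .strings import CandidateUnit, DnaString

__all__ = [
    "UnitSet",
    "ExactDecomposition",
    "PenaltyReport",
    "penalty_of",
    "best_exact_decomposition",
    "greedy_select_units",
]

#: Segment label marking bases not covered by any unit occurrence.
UNCOVERED = None


@dataclass(frozen=True)
class UnitSet:
    """An ordered set of distinct unit strings (order = selection order)."""

    units: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.units)) != len(self.units):
            raise ValueError("units must be distinct")
        if any(not u for u in self.units):
            raise ValueError("units must be nonempty strings")

    @classmethod
    def of(cls, *units: str) -> "UnitSet":
        return cls(tuple(units))

    def __iter__(self) -> Iterator[str]:
        return iter(self.units)

    def __len__(self) -> int:
        return len(self.units)

    def __contains__(self, u: object) -> bool:
        return u in self.units


@dataclass(frozen=True)
class ExactDecomposition:
    """A tiling of ``[0, n)`` into unit occurrences and uncovered segments.

    ``segments`` is an ordered list of ``(b, e, label)`` with ``label`` a unit
    string (the segment equals it literally) or ``UNCOVERED``.  Segments are
    contiguous: ``b_1 = 0``, ``e_i = b_{i+1}``, ``e_k = n``.
    """

    n: int
    segments: tuple[tuple[int, int, Optional[str]], ...]

    def __post_init__(self) -> None:
        pos = 0
        for b, e, _ in self.segments:
            if b != pos or e <= b:
                raise ValueError("segments must tile [0, n) contiguously")
            pos = e
        if pos != self.n:
            raise ValueError("segments must end at n")

    @classmethod
    def from_tiling(
        cls, s: DnaString, pieces: Sequence[str | tuple[str, None]]
    ) -> "ExactDecomposition":
        """Build a decomposition from consecutive piece texts.

        Each piece is either a unit string (covered segment equal to it) or a
        ``(text, UNCOVERED)`` pair.  The concatenation must equal ``s.seq``.
        """
        segments = []
        pos = 0
        for piece in pieces:
            if isinstance(piece, tuple):
                text, label = piece
            else:
                text, label = piece, piece
            if s.seq[pos : pos + len(text)] != text:
                raise ValueError(
                    f"piece {text!r} does not match sequence at {pos}"
                )
            segments.append((pos, pos + len(text), label))
            pos += len(text)
        if pos != s.n:
            raise ValueError("pieces do not tile the whole sequence")
        return cls(n=s.n, segments=tuple(segments))

    def occurrences(self) -> Counter[str]:
        """Number of segments labelled with each unit, o(u)."""
        return Counter(
            label for _, _, label in self.segments if label is not UNCOVERED
        )

    @property
    def covered_length(self) -> int:
        return sum(
            e - b for b, e, label in self.segments if label is not UNCOVERED
        )

    @property
    def uncovered_length(self) -> int:
        return self.n - self.covered_length


@dataclass(frozen=True)
class PenaltyReport:
    """Penalty, extended penalty and coverage of a decomposition."""

    penalty: int
    extended_penalty: int
    coverage: int


def penalty_of(d: ExactDecomposition, u_set: UnitSet) -> PenaltyReport:
    """Score ``d`` under ``u_set``.

    Every ``u`` in ``u_set`` contributes ``|u| + o(u)`` (length counts even
    when ``o(u) = 0``); the extended penalty adds the uncovered length.
    Raises ``ValueError`` if a covered segment's label is outside ``u_set``.
    """
    occ = d.occurrences()
    stray = set(occ) - set(u_set.units)
    if stray:
        raise ValueError(f"decomposition uses units outside the set: {stray}")
    penalty = sum(len(u) + occ.get(u, 0) for u in u_set)
    extended = penalty + d.uncovered_length
    return PenaltyReport(
        penalty=penalty,
        extended_penalty=extended,
        coverage=d.covered_length,
    )


def _occurrence_ends(seq: str, unit: str) -> list[bool]:
    """ends[j] is True iff seq[j-|u|:j] == unit (an occurrence ends at j)."""
    n = len(seq)
    ends = [False] * (n + 1)
    start = seq.find(unit)
    while start != -1:
        ends[start + len(unit)] = True
        start = seq.find(unit, start + 1)
    return ends


def _best_tiling(
    seq: str,
    units: Sequence[str],
    ends_cache: dict[str, list[bool]],
) -> ExactDecomposition:
    """Optimal tiling of ``seq`` by ``units`` plus uncovered letters.

    Minimises the variable part of the extended penalty — one point per unit
    occurrence plus one per uncovered base — by DP over end positions,
    breaking cost ties in favour of larger covered length (fewer uncovered
    bases), so the reported coverage is the maximum among optimal tilings.
    """
    n = len(seq)
    for u in units:
        if u not in ends_cache:
            ends_cache[u] = _occurrence_ends(seq, u)
    # Longest-first examination makes the traceback deterministic.
    order = sorted(units, key=lambda u: (-len(u), units.index(u)))
    INF = (n + 2, n + 2)
    cost: list[tuple[int, int]] = [INF] * (n + 1)
    cost[0] = (0, 0)
    back: list[Optional[str]] = [None] * (n + 1)
    for j in range(1, n + 1):
        c, unc = cost[j - 1]
        best = (c + 1, unc + 1)
        choice: Optional[str] = UNCOVERED
        for u in order:
            if ends_cache[u][j]:
                c2, unc2 = cost[j - len(u)]
                cand = (c2 + 1, unc2)
                if cand < best:
                    best = cand
                    choice = u
        cost[j] = best
        back[j] = choice
    segments: list[tuple[int, int, Optional[str]]] = []
    j = n
    while j > 0:
        u = back[j]
        if u is UNCOVERED:
            b = j - 1
            # merge adjacent uncovered letters
            while b > 0 and back[b] is UNCOVERED:
                b -= 1
            segments.append((b, j, UNCOVERED))
            j = b
        else:
            segments.append((j - len(u), j, u))
            j -= len(u)
    segments.reverse()
    return ExactDecomposition(n=n, segments=tuple(segments))


def best_exact_decomposition(
    s: DnaString, u_set: UnitSet
) -> ExactDecomposition:
    """Tiling of ``s`` by ``u_set`` minimising the extended penalty.

    With an empty unit set the whole string is one uncovered segment.
    """
    if s.n == 0:
        return ExactDecomposition(n=0, segments=())
    return _best_tiling(s.seq, list(u_set.units), {})


def greedy_select_units(
    s: DnaString,
    candidates: Sequence[CandidateUnit],
    max_candidates: Optional[int] = None,
) -> tuple[UnitSet, ExactDecomposition, PenaltyReport]:
    """Greedily grow a unit set that minimises the extended penalty.

    Starting from the empty set (extended penalty ``n``), each round scores
    every unselected candidate ``v`` by the extended penalty of the optimal
    tiling under the augmented set and adds the best one; ties go to larger
    covered length, then shorter unit, then lexicographically smaller text.
    The loop stops when no candidate strictly decreases the extended penalty.
    Units that end up with zero occurrences in the final tiling are dropped.

    ``max_candidates`` optionally prunes the candidate list to the strongest
    ``K`` by potential covered length (occurrence count times unit length)
    before the rounds start; by default all candidates are scored.
    """
    seq = s.seq
    ends_cache: dict[str, list[bool]] = {}
    texts = [c.text for c in candidates]
    if max_candidates is not None and len(texts) > max_candidates:
        def potential(t: str) -> int:
            if t not in ends_cache:
                ends_cache[t] = _occurrence_ends(seq, t)
            return sum(ends_cache[t]) * len(t)

        texts = sorted(texts, key=lambda t: (-potential(t), len(t), t))
        texts = texts[:max_candidates]

    selected: list[str] = []
    best_d = best_exact_decomposition(s, UnitSet(()))
    best_report = penalty_of(best_d, UnitSet(()))
    while True:
        round_best = None  # (key, text, decomposition, report)
        for text in texts:
            if text in selected:
                continue
            trial = UnitSet(tuple(selected + [text]))
            d = _best_tiling(seq, list(trial.units), ends_cache)
            rep = penalty_of(d, trial)
            key = (rep.extended_penalty, -rep.coverage, len(text), text)
            if round_best is None or key < round_best[0]:
                round_best = (key, text, d, rep)
        if (
            round_best is None
            or round_best[3].extended_penalty >= best_report.extended_penalty
        ):
            break
        selected.append(round_best[1])
        best_d = round_best[2]
        best_report = round_best[3]

    # Drop units the optimal tiling never uses; the tiling itself is unchanged.
    occ = best_d.occurrences()
    final = UnitSet(tuple(u for u in selected if occ.get(u, 0) > 0))
    best_report = penalty_of(best_d, final)
    return final, best_d, best_report
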
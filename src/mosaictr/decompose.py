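"""Error-tolerant decomposition against a fixed unit set.

Once the unit set ``U = {u1, ..., uk}`` is chosen, decomposing a noisy TR
sequence is approximate regular-expression matching against ``(u1|...|uk)*``:
find the concatenation of unit copies whose global alignment to ``S`` has
minimum Levenshtein distance (unit-cost substitutions, insertions and
deletions).  A wraparound dynamic program solves this in O(|S| * sum |u|):
each unit contributes a block of states (position within the unit), a shared
wrap state links the end of any unit copy to the start of the next, and the
first and last copies may be partial — the DP can enter a unit mid-way at the
start of ``S`` and leave mid-way at its end at no structural cost, modelling
the canonical TR shape ``s (u)^k p`` with ``s`` a suffix and ``p`` a prefix
of ``u``.

The traceback labels every base of ``S`` with one unit copy, giving ordered
segments ``(b, e, unit, edits)``.  A decomposition is then classified as a
*mosaic tandem repeat* when the bases lying inside tandem runs (at least
``min_tandem_copies`` consecutive copies of one unit) exceed a coverage
threshold fraction of ``|S|``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

from .selection import ExactDecomposition, UnitSet, UNCOVERED
from .strings import DnaString

__all__ = [
    "CopySegment",
    "ApproxDecomposition",
    "MosaicConfig",
    "MosaicCall",
    "approx_decompose",
    "classify_mosaic",
]

_INF = 1 << 30


@dataclass(frozen=True)
class CopySegment:
    """One unit copy of the decomposition.

    ``s.seq[b:e]`` aligns to ``unit[unit_start:unit_end]`` with ``edits``
    Levenshtein edits.  Interior copies have ``unit_start == 0`` and
    ``unit_end == len(unit)``; the first (last) copy may start (end) mid-unit.
    """

    b: int
    e: int
    unit: str
    edits: int
    unit_start: int
    unit_end: int

    @property
    def aligned_text(self) -> str:
        """The portion of the unit this segment aligns to."""
        return self.unit[self.unit_start : self.unit_end]


@dataclass(frozen=True)
class ApproxDecomposition:
    """Ordered unit copies covering ``[0, n)`` with total edit count."""

    n: int
    segments: tuple[CopySegment, ...]
    total_edits: int

    def runs(self) -> list[tuple[str, int]]:
        """Run-length encoding: consecutive same-unit copies merged."""
        out: list[tuple[str, int]] = []
        for seg in self.segments:
            if out and out[-1][0] == seg.unit:
                out[-1] = (seg.unit, out[-1][1] + 1)
            else:
                out.append((seg.unit, 1))
        return out

    def run_spans(self) -> list[tuple[str, int, int, int]]:
        """Run-length encoding with coordinates: ``(unit, copies, b, e)``."""
        out: list[tuple[str, int, int, int]] = []
        for seg in self.segments:
            if out and out[-1][0] == seg.unit and out[-1][3] == seg.b:
                unit, copies, b, _ = out[-1]
                out[-1] = (unit, copies + 1, b, seg.e)
            else:
                out.append((seg.unit, 1, seg.b, seg.e))
        return out

    def reference_text(self) -> str:
        """Concatenation of the aligned unit-copy texts (the DP's instance
        of the regular language); its Levenshtein distance to the input
        equals ``total_edits``."""
        return "".join(seg.aligned_text for seg in self.segments)


def approx_decompose(s: DnaString, u_set: UnitSet) -> ApproxDecomposition:
    """Optimal error-tolerant decomposition of ``s`` by ``u_set``.

    Raises ``ValueError`` on an empty unit set.
    """
    if len(u_set) == 0:
        raise ValueError("approximate decomposition needs a nonempty unit set")
    seq = s.seq
    n = s.n
    units = list(u_set.units)
    lens = [len(u) for u in units]

    # C[j][ui][p] = min edits aligning seq[:j] to a copy concatenation whose
    # last, possibly unfinished copy of units[ui] has consumed p unit chars.
    # M[j] = min edits with seq[:j] aligned to whole copies (wrap state).
    col0 = [[0] * (L + 1) for L in lens]
    C = [col0]
    M = [0]
    for j in range(1, n + 1):
        ch = seq[j - 1]
        prevcol = C[j - 1]
        m_prev = M[j - 1]
        col = []
        for ui, u in enumerate(units):
            L = lens[ui]
            prow = prevcol[ui]
            row = [_INF] * (L + 1)
            for p in range(1, L + 1):
                diag = (m_prev if p == 1 else prow[p - 1]) + (
                    0 if ch == u[p - 1] else 1
                )
                ins = prow[p] + 1
                v = diag if diag < ins else ins
                if p > 1 and row[p - 1] + 1 < v:
                    v = row[p - 1] + 1
                row[p] = v
            col.append(row)
        m_j = min(col[ui][lens[ui]] for ui in range(len(units)))
        # Head deletions of a fresh copy starting at this column: chains from
        # the wrap state cost one per skipped unit char and consume no input.
        for ui in range(len(units)):
            row = col[ui]
            prev = m_j
            for p in range(1, lens[ui] + 1):
                if prev + 1 < row[p]:
                    row[p] = prev + 1
                prev = row[p]
        C.append(col)
        M.append(m_j)

    total, ui, p = _final_state(C[n], units, lens)
    segments = _traceback(seq, units, lens, C, M, ui, p)
    return ApproxDecomposition(n=n, segments=tuple(segments), total_edits=total)


def _final_state(
    last_col: list[list[int]], units: list[str], lens: list[int]
) -> tuple[int, int, int]:
    """Best end state; prefer a completed copy, then earlier unit, then the
    longest partial copy (free partial exit)."""
    best = min(
        last_col[ui][p] for ui in range(len(units)) for p in range(1, lens[ui] + 1)
    )
    for ui in range(len(units)):
        if last_col[ui][lens[ui]] == best:
            return best, ui, lens[ui]
    for ui in range(len(units)):
        for p in range(lens[ui], 0, -1):
            if last_col[ui][p] == best:
                return best, ui, p
    raise AssertionError("unreachable")


def _wrap_predecessor(
    col: list[list[int]], lens: list[int], value: int, prefer_ui: int
) -> tuple[int, int]:
    """Pick the unit whose completed copy realises the wrap state ``value``;
    prefer continuing the same unit, then earlier-selected units."""
    if col[prefer_ui][lens[prefer_ui]] == value:
        return prefer_ui, lens[prefer_ui]
    for ui in range(len(lens)):
        if col[ui][lens[ui]] == value:
            return ui, lens[ui]
    raise AssertionError("wrap state without a realising unit")


def _traceback(
    seq: str,
    units: list[str],
    lens: list[int],
    C: list[list[list[int]]],
    M: list[int],
    ui: int,
    p: int,
) -> list[CopySegment]:
    """Reconstruct copy segments from the DP tables.

    Moves are re-derived by value equality, preferring diagonal continuation
    over insertion over deletion so that error-free input yields the plain
    run-length truth.
    """
    j = len(seq)
    segments: list[CopySegment] = []
    cur_end = j
    cur_unit_end = p
    edits = 0

    def close(b: int, unit_start: int) -> None:
        segments.append(
            CopySegment(
                b=b,
                e=cur_end,
                unit=units[ui],
                edits=edits,
                unit_start=unit_start,
                unit_end=cur_unit_end,
            )
        )

    while True:
        v = C[j][ui][p]
        if j == 0:
            close(0, p)  # free partial entry mid-unit at the sequence start
            break
        u = units[ui]
        ch = seq[j - 1]
        sub = 0 if ch == u[p - 1] else 1
        diag_src = M[j - 1] if p == 1 else C[j - 1][ui][p - 1]
        if diag_src + sub == v:
            edits += sub
            if p == 1:
                close(j - 1, 0)
                if j - 1 == 0:
                    break
                ui, p = _wrap_predecessor(C[j - 1], lens, M[j - 1], ui)
                j -= 1
                cur_end, cur_unit_end, edits = j, p, 0
            else:
                j -= 1
                p -= 1
            continue
        if C[j - 1][ui][p] + 1 == v:  # insertion: extra base within the copy
            edits += 1
            j -= 1
            continue
        del_src = M[j] if p == 1 else C[j][ui][p - 1]
        if del_src + 1 == v:  # deletion: unit char absent from the input
            edits += 1
            if p == 1:
                close(j, 0)
                if j == 0:
                    break
                ui, p = _wrap_predecessor(C[j], lens, M[j], ui)
                cur_end, cur_unit_end, edits = j, p, 0
            else:
                p -= 1
            continue
        raise AssertionError("no transition explains DP value")
    segments.reverse()
    return segments


@dataclass(frozen=True)
class MosaicConfig:
    """Thresholds for calling a decomposition a mosaic tandem repeat.

    ``coverage_threshold`` is the fraction of ``|S|`` that must be exceeded
    (strictly) by bases inside tandem runs; ``min_tandem_copies`` is the
    minimum number of consecutive copies of one unit for a run to count as a
    tandem repeat region.
    """

    coverage_threshold: float = 0.8
    min_tandem_copies: int = 2

    def __post_init__(self) -> None:
        if not 0 < self.coverage_threshold <= 1:
            raise ValueError("coverage_threshold must be in (0, 1]")


@dataclass(frozen=True)
class MosaicCall:
    """Outcome of mosaic-TR classification."""

    is_mosaic: bool
    coverage: int
    n: int

    @property
    def fraction(self) -> float:
        return self.coverage / self.n if self.n else 0.0


def classify_mosaic(
    d: Union[ApproxDecomposition, ExactDecomposition],
    u_set: Optional[UnitSet] = None,
    cfg: MosaicConfig = MosaicConfig(),
) -> MosaicCall:
    """Decide whether ``d`` is a mosaic TR of its units.

    Scans the ordered segments for maximal runs of consecutive copies of the
    same unit; runs of at least ``cfg.min_tandem_copies`` copies are tandem
    regions, and their total base length is the coverage.  Isolated single
    copies contribute nothing.  The call is positive when coverage strictly
    exceeds ``n * cfg.coverage_threshold``.  If ``u_set`` is given, segments
    labelled outside it are treated like uncovered ones.
    """
    if isinstance(d, ApproxDecomposition):
        items = [(seg.b, seg.e, seg.unit) for seg in d.segments]
    else:
        items = [
            (b, e, label) for b, e, label in d.segments if label is not UNCOVERED
        ]
    if u_set is not None:
        items = [(b, e, u) for b, e, u in items if u in u_set]

    coverage = 0
    i = 0
    while i < len(items):
        run_unit = items[i][2]
        k = i
        while (
            k + 1 < len(items)
            and items[k + 1][2] == run_unit
            and items[k + 1][0] == items[k][1]  # contiguous in the sequence
        ):
            k += 1
        if k - i + 1 >= cfg.min_tandem_copies:
            coverage += items[k][1] - items[i][0]
        i = k + 1
    return MosaicCall(
        is_mosaic=coverage > d.n * cfg.coverage_threshold,
        coverage=coverage,
        n=d.n,
    )
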
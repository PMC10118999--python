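"""End-to-end decomposition of a single TR sequence.

Chains the three stages: enumerate repetitive non-self-overlapping candidate
units, select a parsimonious unit set greedily under the extended penalty,
and align the sequence against the selected units with the error-tolerant
wraparound DP.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .decompose import (
    ApproxDecomposition,
    MosaicCall,
    MosaicConfig,
    approx_decompose,
    classify_mosaic,
)
from .selection import (
    ExactDecomposition,
    PenaltyReport,
    UnitSet,
    greedy_select_units,
)
from .strings import DnaString, enumerate_candidate_units

__all__ = ["DecompositionResult", "decompose_sequence"]


@dataclass(frozen=True)
class DecompositionResult:
    """Everything the pipeline derives for one sequence."""

    dna: DnaString
    units: UnitSet
    exact: ExactDecomposition
    report: PenaltyReport
    approx: Optional[ApproxDecomposition]
    mosaic: MosaicCall

    def runs(self) -> list[tuple[str, int]]:
        """Run-length encoding of the approximate decomposition."""
        return self.approx.runs() if self.approx is not None else []


def decompose_sequence(
    s: DnaString | str,
    max_unit_len: int = 100,
    mosaic_cfg: MosaicConfig = MosaicConfig(),
    max_candidates: Optional[int] = None,
) -> DecompositionResult:
    """Decompose one TR sequence into runs of repeat units.

    ``max_unit_len`` caps the candidate unit length (default 100 b, the
    scale of minisatellite units).  When the sequence has no repetitive
    non-self-overlapping substring at all, the unit set is empty and no
    approximate decomposition exists (``approx is None``, not a mosaic).
    """
    dna = DnaString(s) if isinstance(s, str) else s
    candidates = enumerate_candidate_units(dna, max_len=max_unit_len)
    units, exact, report = greedy_select_units(
        dna, candidates, max_candidates=max_candidates
    )
    if len(units) == 0:
        approx = None
        mosaic = MosaicCall(is_mosaic=False, coverage=0, n=dna.n)
    else:
        approx = approx_decompose(dna, units)
        mosaic = classify_mosaic(approx, units, mosaic_cfg)
    return DecompositionResult(
        dna=dna,
        units=units,
        exact=exact,
        report=report,
        approx=approx,
        mosaic=mosaic,
    )
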
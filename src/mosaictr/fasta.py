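"""FASTA input and the annotation text format.

Annotations report one record per input sequence: the run-length pattern of
the decomposition (e.g. ``(AAAG)6(AG)11(AAAG)20``), the selected unit set,
the total edit count, the mosaic call, and per-run intervals in 0-based
half-open coordinates.  The format round-trips through
:func:`parse_annotation`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence, TextIO

from Bio import SeqIO

from .strings import AlphabetError, DnaString

__all__ = [
    "FastaRecord",
    "AnnotationRecord",
    "read_fasta",
    "write_fasta",
    "format_annotation",
    "parse_annotation",
    "read_annotations",
]


@dataclass(frozen=True)
class FastaRecord:
    id: str
    dna: DnaString
    description: str = ""


def read_fasta(path) -> list[FastaRecord]:
    """Read FASTA records as validated, uppercased DNA strings.

    Raises :class:`AlphabetError` naming the offending record when a
    sequence contains letters outside A/C/G/T/N.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        try:
            dna = DnaString(str(rec.seq).upper())
        except AlphabetError as err:
            raise AlphabetError(f"record {rec.id!r}: {err}") from err
        records.append(
            FastaRecord(id=rec.id, dna=dna, description=rec.description)
        )
    return records


def write_fasta(records: Iterable[tuple[str, str]], handle: TextIO, width: int = 80) -> None:
    """Write ``(header, sequence)`` pairs as FASTA."""
    for header, seq in records:
        handle.write(f">{header}\n")
        for i in range(0, len(seq), width):
            handle.write(seq[i : i + width] + "\n")


@dataclass(frozen=True)
class AnnotationRecord:
    """Decomposition summary for one sequence.

    ``runs`` holds ``(unit, copies)`` in order; ``run_spans`` the matching
    ``(b, e)`` intervals (0-based, half-open) tiling the annotated region.
    """

    id: str
    runs: tuple[tuple[str, int], ...]
    run_spans: tuple[tuple[int, int], ...]
    total_edits: int
    is_mosaic: bool
    units: tuple[str, ...]

    def pattern(self) -> str:
        return "".join(f"({u}){c}" for u, c in self.runs)


def format_annotation(rec: AnnotationRecord) -> str:
    """Render one annotation record as text lines."""
    lines = [
        f">{rec.id} units={','.join(rec.units) if rec.units else '-'} "
        f"edits={rec.total_edits} mosaic={int(rec.is_mosaic)}",
        rec.pattern() if rec.runs else "-",
    ]
    for (unit, copies), (b, e) in zip(rec.runs, rec.run_spans):
        lines.append(f"{unit}\t{b}\t{e}\t{copies}")
    return "\n".join(lines) + "\n"


def parse_annotation(text: str) -> AnnotationRecord:
    """Inverse of :func:`format_annotation` for a single record."""
    lines = [ln for ln in text.splitlines() if ln.strip()]
    header = lines[0]
    if not header.startswith(">"):
        raise ValueError("annotation must start with a '>' header")
    fields = header[1:].split()
    rec_id = fields[0]
    meta = dict(f.split("=", 1) for f in fields[1:])
    units = tuple(meta["units"].split(",")) if meta["units"] != "-" else ()
    runs = []
    spans = []
    for ln in lines[2:]:
        unit, b, e, copies = ln.split("\t")
        runs.append((unit, int(copies)))
        spans.append((int(b), int(e)))
    return AnnotationRecord(
        id=rec_id,
        runs=tuple(runs),
        run_spans=tuple(spans),
        total_edits=int(meta["edits"]),
        is_mosaic=bool(int(meta["mosaic"])),
        units=units,
    )


def read_annotations(text: str) -> list[AnnotationRecord]:
    """Parse a concatenation of annotation records."""
    blocks: list[list[str]] = []
    for ln in text.splitlines():
        if ln.startswith(">"):
            blocks.append([ln])
        elif blocks and ln.strip():
            blocks[-1].append(ln)
    return [parse_annotation("\n".join(b)) for b in blocks]
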
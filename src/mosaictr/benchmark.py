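"""Synthetic mosaic-TR benchmark: generation, error injection and scoring.

The benchmark emulates long reads over mosaic tandem repeats.  Eight mosaic
patterns of increasing difficulty are used, from two dissimilar units up to
five alternating runs and long minisatellite-like units:

    (a) (AC)i (AG)j              (e) (AAAG)i (AG)j
    (b) (ACC)i (GTT)j            (f) (AAAG)i (AG)j (AAAG)k
    (c) (AAG)i (AG)j             (g) (AAAG)i (AG)j (AGGG)k (AG)l (AAAG)m
    (d) (AAG)i (AGG)j            (h) (AAAAAG)i (AAAGAGAGGGAAAAG)j (AGGGG)k

Copy counts are drawn uniformly from [10, 200].  Sequencing errors —
substitutions, insertions and deletions in equal proportion by default —
hit each base independently at rates of 0/1/3/5/10/15%, giving 8 x 6 = 48
datasets.  A prediction for a read is scored by its run-length encoding:
every run must show the true unit string, in order, with a copy count within
an *allowance* of X% of the true count; a read counts as accurate only when
all runs pass.

With counts of at least 10 copies per run these patterns have a unique
optimal decomposition (duplicated subpatterns such as (AG)2(AGGG)2 repeated
twice, which admit two equally parsimonious readings, cannot arise), so the
truth comparison is unambiguous.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .pipeline import decompose_sequence
from .strings import DnaString, compression_ratio

__all__ = [
    "MosaicPattern",
    "ErrorModel",
    "BenchmarkRecord",
    "BenchmarkDataset",
    "DEFAULT_ERROR_RATES",
    "builtin_patterns",
    "instantiate",
    "inject_errors",
    "evaluate_prediction",
    "generate_dataset",
    "compression_survey",
    "run_benchmark",
]

_PATTERN_UNITS: dict[str, tuple[str, ...]] = {
    "a": ("AC", "AG"),
    "b": ("ACC", "GTT"),
    "c": ("AAG", "AG"),
    "d": ("AAG", "AGG"),
    "e": ("AAAG", "AG"),
    "f": ("AAAG", "AG", "AAAG"),
    "g": ("AAAG", "AG", "AGGG", "AG", "AAAG"),
    "h": ("AAAAAG", "AAAGAGAGGGAAAAG", "AGGGG"),
}

DEFAULT_ERROR_RATES: tuple[float, ...] = (0.0, 0.01, 0.03, 0.05, 0.10, 0.15)

_RUN_RE = re.compile(r"\(([ACGTN]+)\)(\d+)")


@dataclass(frozen=True)
class MosaicPattern:
    """Ground-truth run-length form ``(u1)^c1 ... (um)^cm``."""

    runs: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        if any(c < 1 for _, c in self.runs):
            raise ValueError("copy counts must be >= 1")
        for (u1, _), (u2, _) in zip(self.runs, self.runs[1:]):
            if u1 == u2:
                raise ValueError("adjacent runs must have distinct units")

    def render(self) -> str:
        return "".join(u * c for u, c in self.runs)

    def __str__(self) -> str:
        return "".join(f"({u}){c}" for u, c in self.runs)

    @classmethod
    def parse(cls, text: str) -> "MosaicPattern":
        runs = [(u, int(c)) for u, c in _RUN_RE.findall(text)]
        if "".join(f"({u}){c}" for u, c in runs) != text:
            raise ValueError(f"not a run-length pattern: {text!r}")
        return cls(tuple(runs))


@dataclass(frozen=True)
class ErrorModel:
    """Per-base sequencing-error model.

    Each base is hit independently with probability ``rate``; a hit applies
    a substitution (uniform different base), an insertion (uniform base added
    after the current one) or a deletion, drawn from ``mix``.  The published
    error rates name the three operation types without proportions; equal
    thirds is the neutral default.
    """

    rate: float
    mix: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)

    def __post_init__(self) -> None:
        if not 0 <= self.rate < 1:
            raise ValueError("rate must be in [0, 1)")
        if abs(sum(self.mix) - 1.0) > 1e-9:
            raise ValueError("mix must sum to 1")


def builtin_patterns() -> dict[str, tuple[str, ...]]:
    """The eight benchmark mosaic-pattern templates, keyed 'a'..'h'."""
    return dict(_PATTERN_UNITS)


def instantiate(
    template: Sequence[str],
    rng: np.random.Generator,
    count_low: int = 10,
    count_high: int = 200,
) -> MosaicPattern:
    """Draw copy counts uniformly in ``[count_low, count_high]`` per run."""
    if not 1 <= count_low <= count_high:
        raise ValueError("need 1 <= count_low <= count_high")
    counts = rng.integers(count_low, count_high, size=len(template), endpoint=True)
    return MosaicPattern(tuple(zip(template, (int(c) for c in counts))))


_OTHER_BASES = {b: [x for x in "ACGT" if x != b] for b in "ACGTN"}


def inject_errors(seq: str, model: ErrorModel, rng: np.random.Generator) -> str:
    """Apply the error model to ``seq``; deterministic for a given ``rng``."""
    n = len(seq)
    if n == 0 or model.rate == 0.0:
        return seq
    hits = np.flatnonzero(rng.random(n) < model.rate)
    if hits.size == 0:
        return seq
    ops = rng.choice(3, size=hits.size, p=model.mix)
    out = []
    prev = 0
    bases = "ACGT"
    for pos, op in zip(hits.tolist(), ops.tolist()):
        out.append(seq[prev:pos])
        ch = seq[pos]
        if op == 0:  # substitution
            out.append(_OTHER_BASES[ch][rng.integers(3)])
        elif op == 1:  # insertion after the base
            out.append(ch)
            out.append(bases[rng.integers(4)])
        # op == 2: deletion -> emit nothing
        prev = pos + 1
    out.append(seq[prev:])
    return "".join(out)


def evaluate_prediction(
    truth: MosaicPattern,
    predicted: Sequence[tuple[str, int]],
    allowance: float = 0.0,
) -> bool:
    """Score a predicted run-length encoding against the truth.

    Accurate iff the ordered unit strings match exactly and every run's
    predicted copy count ``c'`` satisfies ``|c' - c| <= allowance * c``.
    Unit strings are compared literally; rotations do not count.
    """
    if allowance < 0:
        raise ValueError("allowance must be >= 0")
    if [u for u, _ in predicted] != [u for u, _ in truth.runs]:
        return False
    return all(
        abs(cp - ct) <= allowance * ct
        for (_, ct), (_, cp) in zip(truth.runs, predicted)
    )


@dataclass(frozen=True)
class BenchmarkRecord:
    """One benchmark read: the truth pattern, its clean rendering, and the
    error-injected sequence actually handed to the decomposer."""

    truth: MosaicPattern
    clean: str
    errored: str


@dataclass(frozen=True)
class BenchmarkDataset:
    pattern_id: str
    error_rate: float
    records: tuple[BenchmarkRecord, ...]

    @property
    def n_records(self) -> int:
        return len(self.records)


def _dataset_rng(seed: int, pattern_id: str, error_rate: float) -> np.random.Generator:
    """Independent, reproducible stream per (seed, pattern, rate) cell."""
    key = (ord(pattern_id), int(round(error_rate * 1000)))
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


def generate_dataset(
    pattern_id: str,
    error_rate: float,
    n_records: int,
    seed: int,
    count_low: int = 10,
    count_high: int = 200,
    mix: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3),
) -> BenchmarkDataset:
    """Generate one (pattern, error-rate) dataset of ``n_records`` reads."""
    template = _PATTERN_UNITS[pattern_id]
    model = ErrorModel(rate=error_rate, mix=mix)
    rng = _dataset_rng(seed, pattern_id, error_rate)
    records = []
    for _ in range(n_records):
        truth = instantiate(template, rng, count_low, count_high)
        clean = truth.render()
        errored = inject_errors(clean, model, rng)
        records.append(BenchmarkRecord(truth=truth, clean=clean, errored=errored))
    return BenchmarkDataset(
        pattern_id=pattern_id, error_rate=error_rate, records=tuple(records)
    )


def compression_survey(
    pattern_ids: Sequence[str] = tuple("abcdefgh"),
    error_rates: Sequence[float] = DEFAULT_ERROR_RATES,
    n_records: int = 100,
    seed: int = 0,
    theta: int = 20,
) -> pd.DataFrame:
    """Mean compression ratio per dataset over the full benchmark grid.

    Returns one row per (pattern, rate) with the per-dataset mean of the
    per-read ratio of candidate units to distinct substrings (length <=
    ``theta``).
    """
    rows = []
    for pid in pattern_ids:
        for rate in error_rates:
            ds = generate_dataset(pid, rate, n_records, seed)
            ratios = [
                compression_ratio(DnaString(rec.errored), theta).ratio
                for rec in ds.records
            ]
            rows.append(
                {
                    "pattern": pid,
                    "error_rate": rate,
                    "n": n_records,
                    "theta": theta,
                    "mean_compression_ratio": float(np.mean(ratios)),
                }
            )
    return pd.DataFrame(rows)


def run_benchmark(
    pattern_ids: Sequence[str] = tuple("abcdefgh"),
    error_rates: Sequence[float] = DEFAULT_ERROR_RATES,
    n_records: int = 100,
    allowances: Sequence[float] = (0.0, 0.02),
    seed: int = 0,
    max_unit_len: int = 100,
    theta: int = 20,
    max_candidates: Optional[int] = None,
) -> pd.DataFrame:
    """Run the full pipeline over the benchmark grid and score it.

    For every (pattern, error rate) dataset each read is decomposed from
    scratch (candidate enumeration, greedy unit selection, wraparound DP),
    its run-length encoding is compared with the generating truth at each
    allowance, and the per-read compression ratio is recorded.  Returns one
    row per (pattern, rate, allowance) with the fraction of accurate reads.
    """
    rows = []
    for pid in pattern_ids:
        for rate in error_rates:
            ds = generate_dataset(pid, rate, n_records, seed)
            ratios = []
            ok = {a: 0 for a in allowances}
            for rec in ds.records:
                result = decompose_sequence(
                    rec.errored,
                    max_unit_len=max_unit_len,
                    max_candidates=max_candidates,
                )
                runs = result.runs()
                for a in allowances:
                    if evaluate_prediction(rec.truth, runs, a):
                        ok[a] += 1
                ratios.append(
                    compression_ratio(DnaString(rec.errored), theta).ratio
                )
            for a in allowances:
                rows.append(
                    {
                        "pattern": pid,
                        "error_rate": rate,
                        "allowance": a,
                        "n": n_records,
                        "accuracy": ok[a] / n_records,
                        "mean_compression_ratio": float(np.mean(ratios)),
                    }
                )
    return pd.DataFrame(rows)
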
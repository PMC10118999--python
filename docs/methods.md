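# Methods

## Problem and model

A tandem repeat (TR) of a unit string *u* has the form `s (u)^k p` with *s* a
suffix and *p* a prefix of *u*; a mosaic TR concatenates runs of several
distinct units. Given one TR-containing DNA sequence *S* (a long read or an
extracted locus; alphabet A/C/G/T, optionally N), the package infers a unit
set *U* and an annotation of *S* as ordered unit copies. Replication
slippage and non-homologous recombination multiply existing units, so a
mosaic TR is expected to be generated by few, short units: unit selection is
driven by maximum parsimony.

## Candidate units

Any rotation of a unit generates the same TR, and every TR has at least one
*non-self-overlapping* (borderless) rotation, so candidates are restricted to
borderless substrings occurring at least twice. The enumeration follows the
two-array construction:

- `LEN[i]` — the longest prefix of the suffix at *i* occurring ≥ 2 times in
  *S* — is the maximum of the LCPs with the two suffix-array neighbours of
  that suffix. The suffix array is built by numpy-vectorised prefix doubling
  (O(n log n)); correctness, not construction style, is the contract, and at
  the kilobase scale this package targets it is faster in practice than an
  interpreted linear-time construction. The LCP array uses Kasai's
  algorithm. Boundary convention: `lcp[i]` relates `sa[i]` to `sa[i+1]`;
  the first and last suffix-array entries take their single neighbour.
- `OL_i[k]` — the longest proper border of `S[i, i+k)` — is the Morris–Pratt
  failure function of the suffix at *i*.

`S[i, j)` is emitted when `LEN[i] ≥ j−i`, `OL_i[j−i] = 0`, and `j−i ≤`
`max_unit_len` (default 100 b, the minisatellite scale). Border arrays are
only evaluated out to `min(LEN[i], max_unit_len)`, so enumeration is
O(n·max_unit_len) rather than Θ(n²) without changing the output set.
Candidates are deduplicated by text (a unit is a string, not a position),
keep their leftmost occurrence as witness, and never contain N (ambiguity
codes cannot be units). No further filtering is applied: exact tandem powers
are already excluded by borderlessness, near-tandem candidates are left to
the penalty to reject.

## Penalty and unit selection

For a unit set *U* and tiling *D* of *S* (segments equal to a unit, or
uncovered), the penalty is `Σ_{u∈U}(|u| + o(u))`; the extended penalty adds
the total uncovered length. Every selected unit pays its length even with
`o(u) = 0`. For fixed *U* the optimal tiling minimises
(occurrences + uncovered bases), found by a prefix DP in O(n·Σ|u|); ties in
cost are broken toward larger covered length, then (in the traceback) toward
longer units, making the reported decomposition deterministic.

Greedy selection starts from *U* = ∅ (extended penalty *n*) and each round
adds the candidate minimising the extended penalty of the optimal tiling;
candidate ties go to larger coverage, then shorter unit, then
lexicographically smaller text. The loop stops on the first round without a
strict decrease (strictness prevents cycling on ties), then drops units with
zero occurrences in the final tiling; dropped units are not reconsidered.
Greedy rounds score candidates with the *exact* tiling DP, not the
error-tolerant DP — all of the method's worked arithmetic is exact-match,
and it keeps each round linear. The greedy result is an upper bound on the
(conjectured intractable) global minimum; the tests assert the bound, not
equality. `max_candidates` can prune each round to the K candidates with the
largest potential covered length (occurrences × length); the default is no
pruning.

## Error-tolerant decomposition

With *U* selected, *S* is decomposed by wraparound dynamic programming
against `(u1|…|uk)*` under unit-cost Levenshtein edits (no affine gaps —
the error model is per-base sequencing noise, not biological indel
structure). States are positions within each unit plus one shared wrap state
linking copy boundaries; per column the wrap state is resolved first, then
head-deletion chains into fresh copies, so deletions at a copy boundary are
handled without iteration. The first copy may be entered mid-unit and the
last exited mid-unit at zero structural cost (partial flanking copies);
interior copies traverse their unit completely. Traceback prefers diagonal
continuation over insertion over deletion, prefers completing a copy at the
sequence end, and on crossing a copy boundary prefers continuing the same
unit, then earlier-selected units — so error-free input reproduces its
generating run-length form exactly, and run-length encodings are stable.
Total edits equal the Levenshtein distance between *S* and the reported
concatenation of aligned copy texts (asserted by re-alignment in tests).

A decomposition is a **mosaic TR** when the bases inside tandem runs — at
least `min_tandem_copies = 2` consecutive, contiguous copies of one unit —
strictly exceed `coverage_threshold × n` (default 0.8). Two copies is the
smallest count that distinguishes a tandem context from a scattered single
copy, and the strict comparison reads "exceeds" literally.

## Synthetic benchmark

`benchmark` regenerates the study conditions: eight mosaic templates
(a) `(AC)i(AG)j`, (b) `(ACC)i(GTT)j`, (c) `(AAG)i(AG)j`, (d) `(AAG)i(AGG)j`,
(e) `(AAAG)i(AG)j`, (f) `(AAAG)i(AG)j(AAAG)k`,
(g) `(AAAG)i(AG)j(AGGG)k(AG)l(AAAG)m`,
(h) `(AAAAAG)i(AAAGAGAGGGAAAAG)j(AGGGG)k`; copy counts uniform in
[10, 200]; per-base error rates 0/1/3/5/10/15% with substitutions,
insertions and deletions in equal thirds (the operation mix is not otherwise
specified; equal thirds is the neutral, configurable default). Substitutions
draw a uniformly different base; insertions add a uniform base after the hit
position. Generation is bit-reproducible from a seed, with an independent
derived stream per (pattern, rate) dataset. With counts ≥ 10 every template
instance has a unique optimal run-length reading (ambiguity needs duplicated
low-copy subpatterns such as `(AG)2(AGGG)2` twice), so scoring against the
hidden truth is well defined.

A prediction is *accurate* at allowance X when its run-length encoding shows
the truth's unit strings in order and every run's copy count is within X% of
the true count (inclusive, unrounded). Unit strings are compared literally;
rotations do not count, and any structural mismatch (including spurious
extra runs) fails the read. Note pattern (h)'s 15-mer unit is itself
self-overlapping (border `AAAG`), so only a rotation of it can ever be
proposed and pattern (h) cannot be reproduced literally — it probes the hard
end of the scale rather than contributing to recovery guarantees.

What the generator does **not** emulate: platform-specific error profiles
(homopolymer-biased indels, quality values), flanking non-repeat sequence,
read-level coverage, or unit-variant structure within runs. Passing the
benchmark therefore demonstrates correct decomposition under idealised
uniform noise, not end-to-end performance on raw instrument reads.

## Compression ratio

`W_all` is the set of distinct substrings of *S* of length ≤ θ (default 20);
the compression ratio is the fraction of them that survive as candidate
units, i.e. are both repetitive and non-self-overlapping. On the benchmark
grid the per-dataset mean ratio is a few percent (median ≈ 4% over the 48
datasets at 100 reads each), quantifying why restricting to borderless
repetitive substrings makes unit selection tractable. Counting borderless
substrings *without* the repetitiveness requirement would give ratios of
20–50% on the same data — boundary-crossing windows of a mosaic TR are
mostly borderless but occur once — and would say nothing about the candidate
pool, so the repetitive-and-borderless numerator is the one reported.
Substrings are collected by direct hashing (O(n·θ)), adequate at read scale.

## Problem sizes and numerical choices

Defaults: `max_unit_len` 100 b, θ 20 b, coverage threshold 0.8, minimum
tandem copies 2, allowances 0% and 2%, copy counts 10–200, 1000 reads per
dataset in the published design. The test suite and the acceptance script
use 100 reads per dataset for the compression survey and 100 clean reads per
two-unit pattern for recovery checks — sizes chosen so the whole suite runs
in about a minute on one core while keeping sampling error well below the
margins being asserted (a 0.95 accuracy bound, a 5% ratio bound with
observed values near 4.2%). Property tests compare against brute-force
oracles: suffix sorting by slice comparison, substring counting by window
hashing, exhaustive tiling enumeration (n ≤ 15), and exhaustive unit-copy
concatenation scored by edlib (n ≤ 30).

## Known limitations

- Greedy selection is a heuristic; on heavily errored inputs it may admit
  tens of error-variant units, fragmenting the run-length output (structural
  accuracy degrades with error rate, as expected for parsimony scoring on
  noisy data).
- Run-length scoring is literal: a correct decomposition expressed in a
  rotated unit frame counts as wrong.
- All-pairs unit similarity, unit *variants* within runs, and alignment of
  reads to a reference are out of scope.
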
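# Methods

## The assay and its read-out

A single defined DSB is induced in a reporter amplicon (in the original
assay, by heat-shock-driven I-SceI), the locus is PCR-amplified with
primers flanking the cut site, and the amplicons are deep-sequenced.
Every usable read spans the full amplicon, so repair outcomes are read
directly off the read-to-reference alignment.  `scarcall` models exactly
this situation: one amplicon per run, merged single-end reads, both read
ends anchored in the primers.

Reads are usable only if both their start and end lie within the primers:
the first `len(primer_fwd)` bases must match the forward primer and the
last `len(primer_rev)` bases the reverse-complemented reverse primer, each
within `max_mismatch` (default 2; `N` never matches).  Reads are oriented
by primer prefix before this check and library adaptors (the 5' primer
tails) are stripped when present with at most one mismatch.  Reads whose
interior is more than 5% `N` are dropped.  Quality scores are carried but
never used — the filter contract is purely positional.  The
`FilterReport` counts (`anchor_pass`, `anchor_fail`, `too_short`)
partition the input exactly; high-N drops are a flagged subset of
`anchor_fail` so the partition stays three-way.

## Alignment model

Each passing read is aligned globally (Needleman–Wunsch with affine gaps,
via Biopython's `PairwiseAligner`) against the amplicon.  A gap of length
L costs `gap_open + L * gap_extend`.  Defaults:

| parameter  | value | rationale |
|------------|------:|-----------|
| match      |   +2  | scale anchor |
| mismatch   |   −8  | > 2× the per-base cost of a deletion+insertion pair, so inserted bases are never paired against deleted bases as mismatch runs |
| gap_open   |  −13  | > 3× (match − gap_extend), so re-anchoring ≤3 coincidentally matching bases inside a compound junction never pays |
| gap_extend |   −1  | long deletions stay single events |

These values were chosen analytically so that a deletion-plus-insertion at
one junction — the TMEJ footprint the assay cares about — is represented
as exactly that, rather than dissolving into hybrids.  Two failure modes
drive the bounds.  (1) *Pairing*: rewriting `del(d) + ins(m)` as
`min(d,m)` aligned columns plus one shorter gap eliminates a gap-open and
converts gap bases into matches/mismatches; with mismatch `x` and open `o`
the rewrite gains `min(d,m)·(x+2) − o + (2−x)·q` for `q` coincidental
matches, so `|x|` must be large relative to `|o|/min(d,m)`.  (2) *Capture*:
splitting a gap to match `k` coincidental bases gains `4k + o`; with
`o = −13`, `k ≤ 3` never pays.  A milder scheme (e.g. mismatch −4, open
−6) empirically shreds virtually every compound junction into substitution
runs, which collapses the delins class entirely.

Ties among co-optimal alignments are resolved deterministically (first
traceback), and all indels are then **left-aligned** — shifted to the
smallest reference start producing the identical edited sequence, with
the shift bounded so a variant never slides across an earlier variant of
the same read.  Left-normalization makes biologically identical events
count identically whatever the traceback did.  Applying the called
variants to the reference reconstructs the read exactly; this round-trip
is fuzz-tested and re-checked in the acceptance script.

Reads whose optimal alignment edits more than 50% of its columns are set
aside as `UNALIGNABLE` and excluded from classification and from the
mutagenic-fraction denominator.

## Classification

Precedence, applied to the left-normalized variants of a read:

1. no variants → `WILDTYPE`;
2. all variants are pure tract-base length changes inside (or at the
   boundary of) an annotated polyA tract → `FILTERED_POLYA`;
3. substitutions only → `SNV`;
4. deletions, no insertion → `DELETION`;
5. insertions, no deletion → `TANDEM_DUPLICATION` if the sole insertion
   duplicates an adjacent reference segment (checked over all equivalent
   placements of the insertion; the reported unit is the leftmost
   placement), `COMPOUND_TD` if a duplicating insertion co-occurs with any
   other variant, else `INSERTION`;
6. at least one deletion and one insertion within 5 bp of each other →
   `DELINS`; del+ins scattered further apart are classified by the variant
   nearest the cut site and flagged `complex`.

Tract slippage mixed with real variants is ignored as noise (it does not
promote classes).  Substitutions within 2 bp of an indel junction are
treated as junction ambiguity and do not promote `DELETION`/`TD` to
compound classes; both margins are configurable.

PolyA tracts are detected as maximal A-runs *and* T-runs of ≥4 bp (a
polyA stretch on the opposite strand reads as polyT).  A duplication whose
unit is pure tract base inside a tract is slippage by rule 2, not a TD.

**Microhomology** of a left-aligned deletion [s, e) is the largest k with
`ref[s:s+k] == ref[e:e+k]`.  This equals the number of distinct placements
of the same deletion minus one (placements of an equivalent deletion are
provably contiguous shifts), which is what the brute-force oracle counts.

**Templated inserts** are sought as an exact occurrence of the insert — or
its reverse complement — within ±25 bp of the junction; failing the full
insert, its longest prefix or suffix (templated inserts are
junction-anchored copies), at minimum 3 bp.  Ties break toward the match
nearest the junction, forward strand first.  Window and threshold follow
the typical scale of theta-polymerase templated inserts; both are
parameters.

## Sample statistics

`mutagenic_fraction` = mutagenic reads / (aligned − polyA-filtered −
unalignable); the all-reads denominator is reported alongside since the
original description leaves the denominator open.  Wilson 95% intervals
(statsmodels) accompany fractions.  `normalized_efficiency` divides a
sample's fraction by an induced control's.  The deletion-type spectrum
bins junction microhomology as 0 / 1 / 2 / 3–5 / 6–10 / >10 over
deletion-bearing mutagenic reads.  Tornado records sort mutagenic events
by total edited size, descending, with a deterministic secondary key.

The dual-reporter repair score is
`((nhej⁺/nhejᴺ)/(ssa⁺/ssaᴺ))_test / (same)_control`; its standard error
uses the delta method (the score is a quotient of four binomial
proportions, so relative variances add).  Replicate-level mean ± SEM
aggregation is provided separately.

## The synthetic-data generator

`simulate_dataset` emits full-length amplicon reads with per-read truth
labels.  The reference (default 300 bp, cut site at 160) starts with the
assay's printed forward primer and ends with the reverse complement of
its printed reverse primer; it carries one deliberate A₈ tract between
the forward primer and the mutation window, and a row of direct-repeat
cassettes around the cut site — unit lengths 1, 2, 3, 5, 8 with spacings
6, 9, 12, 16, 24 — each flanked by guard bases so the designed junction
microhomology is exact (verified at construction against the
placement-enumeration oracle).  Filler sequence never contains an A/T run
reaching the tract-detection threshold, so the only annotated tract is
the deliberate one.

Default class mixture: wildtype 0.40, deletion 0.25, insertion 0.10,
delins 0.10, tandem duplication 0.05, compound TD 0.05, SNV 0.05 —
a composition in which roughly half of break-bearing molecules acquire a
mutagenic footprint, as seen after efficient nuclease induction.  Event
models:

- deletions: half drawn from the cassettes (exact microhomology by
  construction), half random spans (geometric size, mean ≈ 8 bp, max 40)
  within a ±48 bp window around the cut;
- insertions: geometric length 1–12, resampled if the insert would
  duplicate its flank (such a read *is* a tandem duplication) or extend a
  polyA tract;
- tandem duplications: a 2–12 bp unit copied in place; compound TD adds
  one substitution ≥8 bp clear of the duplication junction;
- delins: a 5–18 bp deletion plus a 5–10 bp insert, half of which are
  templated copies (either strand) from ≥2 bp outside the deleted span
  within a 25 bp window;
- polyA reads: ±1–2 A in the tract; SNVs: 1–3 scattered substitutions.

Reads are emitted reverse-complemented with probability 0.5 to exercise
orientation; qualities are constant `I` (the pipeline ignores them).
Substitution-error and polyA-slippage noise channels exist but default to
0 so truth labels describe the repair event exactly.

**Delins uniqueness.**  A compound edit whose insert resembles the
deleted span or its flanks does not *encode* a delins: its optimal
alignment is a simpler event, for any scoring.  The generator therefore
emits only reads that uniquely encode the intended deletion+insertion:
boundary bases are constructed to avoid junction merging and sliding,
analytic screens reject inserts whose window-pairing against the span
would pay for a gap elimination, and a final check confirms that the
read's optimal alignment decomposes into exactly the intended pair.  This
biases simulated delins inserts toward sequence dissimilar from the
deleted span — which is also the only kind of delins any
alignment-based caller (including the original assay's) can report.

Not modelled: PCR chimeras, index hopping, quality profiles, read-length
variation, partial-amplicon reads.  Passing tests therefore demonstrate
correctness of the calling logic under the assay's idealised read
structure, not robustness to library artefacts beyond the polyA and
substitution-noise channels.

## Problem sizes and determinism

Truth-recovery and mixture-recovery checks use 10,000 reads per sample
(binomial SE ≈ 0.5% on a 50% class); oracle fuzzing uses 500 alignment
pairs on ≤60 bp references and 1,000 deletion contexts.  All randomness
flows from explicit integer seeds through `numpy.random.default_rng`;
equal seeds give byte-identical FASTQ output (gzip written with fixed
mtime) and identical summary JSON.

## Known limitations

- Classification is alignment-relative: compound events whose parts are
  individually cheaper to explain as substitutions or smaller indels are
  reported in that simpler form.  The scoring defaults push this boundary
  as far toward preserving junction compounds as affine scoring allows.
- `SNV` reads are not distinguished from sequencing errors; no error
  model is fitted.  With the default zero-noise simulator this is moot;
  on real data the SNV class absorbs both.
- Whether a compound TD's extra mutation must be junction-proximal is
  left open; any co-occurring variant promotes (outside the 2 bp junction
  margin).
- One amplicon per run; no genome-scale or multi-locus support.
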
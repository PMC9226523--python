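"""Global read-to-amplicon alignment and left-normalized variant calls.

Each primer-anchored read is aligned end-to-end against the reference
amplicon under affine gap scoring (both read ends are primer-anchored by
construction, so global alignment is the right model).  The alignment is
decomposed into atomic variants — substitution runs, deletions, insertions
— and every indel is left-aligned, i.e. shifted to the smallest reference
start that yields the identical edited sequence, so that biologically
identical events are counted identically regardless of where the aligner
happened to place the gap.

Default scoring (match +2, mismatch -8, gap open -13, gap extend -1, a gap
of length L costing open + L*extend) keeps a deletion-plus-insertion at the
cut site from being absorbed into runs of mismatches or re-anchored around
coincidental matches.  Reads whose best alignment edits more than half of
its columns are flagged unalignable and excluded from classification.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Literal, Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .amplicon import AmpliconReference

MAX_EDITED_COLUMN_FRACTION = 0.5

OpKind = Literal["match", "mismatch", "deletion", "insertion"]


@dataclass(frozen=True)
class ScoringScheme:
    """Affine-gap alignment parameters; a length-L gap costs open + L*extend.

    Defaults are tuned so compound events at a junction survive as a
    deletion plus an insertion instead of dissolving into cheaper hybrids:
    the mismatch cost exceeds twice the per-base gap cost, so pairing
    inserted bases against deleted bases never pays, and the gap-open cost
    exceeds three times the match-plus-extend gain, so re-anchoring three
    or fewer coincidentally matching bases inside a junction never pays
    either.
    """

    match: float = 2.0
    mismatch: float = -8.0
    gap_open: float = -13.0
    gap_extend: float = -1.0


@dataclass(frozen=True)
class AlignmentOp:
    kind: OpKind
    length: int
    ref_pos: int
    read_pos: int


@dataclass
class PairwiseAlignment:
    """A global alignment as an ordered op list consuming ref and read."""

    ref: str
    read: str
    ops: list[AlignmentOp]
    score: float

    def edited_column_fraction(self) -> float:
        edited = sum(op.length for op in self.ops if op.kind != "match")
        total = sum(op.length for op in self.ops)
        return edited / total if total else 0.0


@dataclass(frozen=True)
class Variant:
    """An atomic difference from the reference, half-open coordinates.

    substitution: ref_end - ref_start == len(alt) >= 1
    deletion:     alt == "" and ref_end > ref_start
    insertion:    ref_end == ref_start and len(alt) >= 1
    """

    kind: Literal["substitution", "deletion", "insertion"]
    ref_start: int
    ref_end: int
    alt: str = ""

    def __post_init__(self) -> None:
        if self.kind == "substitution":
            if self.ref_end - self.ref_start != len(self.alt) or not self.alt:
                raise ValueError(f"malformed substitution {self}")
        elif self.kind == "deletion":
            if self.alt or self.ref_end <= self.ref_start:
                raise ValueError(f"malformed deletion {self}")
        elif self.kind == "insertion":
            if self.ref_end != self.ref_start or not self.alt:
                raise ValueError(f"malformed insertion {self}")
        else:
            raise ValueError(f"unknown variant kind {self.kind!r}")

    @property
    def length(self) -> int:
        """Edited length: bases deleted, inserted or substituted."""
        return (self.ref_end - self.ref_start) if self.kind != "insertion" else len(self.alt)

    def interval(self) -> tuple[int, int]:
        return self.ref_start, self.ref_end


@lru_cache(maxsize=8)
def _aligner(scoring: ScoringScheme) -> Align.PairwiseAligner:
    alphabet = "ACGTN"
    m = np.full((5, 5), scoring.mismatch)
    for i in range(4):  # N never matches, including N-N
        m[i, i] = scoring.match
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.Array(alphabet=alphabet, dims=2, data=m)
    # Biopython charges open on the first gap base, extend on the rest;
    # fold one extend into open so a length-L gap costs open + L*extend.
    aligner.open_gap_score = scoring.gap_open + scoring.gap_extend
    aligner.extend_gap_score = scoring.gap_extend
    return aligner


def align_global(
    read_bases: str, ref: AmpliconReference | str, scoring: ScoringScheme = ScoringScheme()
) -> PairwiseAlignment:
    """Optimal global alignment of a read against the amplicon.

    Deterministic: of the co-optimal alignments the aligner's first
    traceback is taken, and indel placement is canonicalised afterwards by
    :func:`left_align`.
    """
    ref_seq = ref.sequence if isinstance(ref, AmpliconReference) else ref
    if not read_bases:
        raise ValueError("cannot align an empty read")
    if read_bases == ref_seq:  # identity fast path
        ops = [AlignmentOp("match", len(ref_seq), 0, 0)]
        return PairwiseAlignment(ref_seq, read_bases, ops, scoring.match * len(ref_seq))
    aln = _aligner(scoring).align(ref_seq, read_bases)[0]
    ops = _ops_from_coordinates(ref_seq, read_bases, aln.coordinates)
    return PairwiseAlignment(ref_seq, read_bases, ops, float(aln.score))


def _ops_from_coordinates(ref: str, read: str, coords: np.ndarray) -> list[AlignmentOp]:
    """Decompose Biopython alignment coordinates into atomic ops."""
    ops: list[AlignmentOp] = []
    r0, q0 = int(coords[0, 0]), int(coords[1, 0])
    for k in range(1, coords.shape[1]):
        r1, q1 = int(coords[0, k]), int(coords[1, k])
        if r1 > r0 and q1 > q0:
            # aligned block: split into match/mismatch runs
            i, n = 0, r1 - r0
            while i < n:
                same = ref[r0 + i] == read[q0 + i] and ref[r0 + i] != "N"
                j = i
                while j < n and ((ref[r0 + j] == read[q0 + j] and ref[r0 + j] != "N") == same):
                    j += 1
                ops.append(AlignmentOp("match" if same else "mismatch", j - i, r0 + i, q0 + i))
                i = j
        elif r1 > r0:
            ops.append(AlignmentOp("deletion", r1 - r0, r0, q0))
        elif q1 > q0:
            ops.append(AlignmentOp("insertion", q1 - q0, r0, q0))
        r0, q0 = r1, q1
    return ops


def extract_variants(aln: PairwiseAlignment) -> list[Variant]:
    """Turn an op list into atomic variants, sorted by reference start.

    Each maximal mismatch run becomes one substitution; each gap run one
    deletion or insertion.  No merging across ops — junction-adjacent
    deletion/insertion pairs are preserved for delins classification.
    """
    variants: list[Variant] = []
    for op in aln.ops:
        if op.kind == "mismatch":
            variants.append(
                Variant("substitution", op.ref_pos, op.ref_pos + op.length,
                        aln.read[op.read_pos: op.read_pos + op.length])
            )
        elif op.kind == "deletion":
            variants.append(Variant("deletion", op.ref_pos, op.ref_pos + op.length))
        elif op.kind == "insertion":
            variants.append(
                Variant("insertion", op.ref_pos, op.ref_pos,
                        aln.read[op.read_pos: op.read_pos + op.length])
            )
    variants.sort(key=lambda v: (v.ref_start, v.ref_end))
    return variants


def left_align(v: Variant, ref_sequence: str, min_start: int = 0) -> Variant:
    """Shift an indel to its smallest equivalent reference start.

    A deletion may slide left while the base preceding it equals the last
    deleted base; an insertion slides left while the preceding reference
    base equals the insert's last base (rotating the insert).  The edited
    sequence is invariant under these shifts.  Substitutions are returned
    unchanged.  Idempotent.  ``min_start`` bounds the shift so a variant
    never slides across an earlier variant of the same read.
    """
    if v.kind == "substitution":
        return v
    if v.kind == "deletion":
        s, e = v.ref_start, v.ref_end
        while s > min_start and ref_sequence[s - 1] == ref_sequence[e - 1]:
            s -= 1
            e -= 1
        return Variant("deletion", s, e) if s != v.ref_start else v
    # insertion
    s, alt = v.ref_start, v.alt
    while s > min_start and ref_sequence[s - 1] == alt[-1]:
        alt = ref_sequence[s - 1] + alt[:-1]
        s -= 1
    return Variant("insertion", s, s, alt) if s != v.ref_start else v


def call_variants(
    read_bases: str,
    ref: AmpliconReference | str,
    scoring: ScoringScheme = ScoringScheme(),
) -> tuple[list[Variant], PairwiseAlignment]:
    """Align a read and return its left-normalized variants."""
    aln = align_global(read_bases, ref, scoring)
    ref_seq = aln.ref
    variants = []
    bound = 0  # never slide a variant across the one before it
    for v in extract_variants(aln):
        la = left_align(v, ref_seq, min_start=bound)
        variants.append(la)
        bound = max(bound, la.ref_end)
    variants.sort(key=lambda v: (v.ref_start, v.ref_end))
    return variants, aln


def apply_variants(ref_sequence: str, variants: Sequence[Variant]) -> str:
    """Apply sorted, non-overlapping variants to the reference.

    Inverse of variant extraction: applying the variants called from a
    read reconstructs that read exactly.
    """
    out: list[str] = []
    pos = 0
    for v in sorted(variants, key=lambda v: (v.ref_start, v.ref_end)):
        if v.ref_start < pos:
            raise ValueError(f"overlapping variants at {v.ref_start} (cursor {pos})")
        out.append(ref_sequence[pos: v.ref_start])
        if v.kind == "substitution":
            out.append(v.alt)
            pos = v.ref_end
        elif v.kind == "deletion":
            pos = v.ref_end
        else:
            out.append(v.alt)
            pos = v.ref_start
    out.append(ref_sequence[pos:])
    return "".join(out)


def is_unalignable(aln: PairwiseAlignment) -> bool:
    """True when more than half of the alignment's columns are edited."""
    return aln.edited_column_fraction() > MAX_EDITED_COLUMN_FRACTION
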
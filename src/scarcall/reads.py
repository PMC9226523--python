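"""FASTQ input, read orientation and the both-ends-within-primers filter.

Merged amplicon reads arrive on either strand.  Each read is oriented to
the forward strand by matching its prefix against the two primers, any
library adaptors are stripped, and only reads whose start matches the
forward primer AND whose end matches the reverse-complemented reverse
primer (each within a small mismatch budget) are kept.  Quality scores are
carried through but never used for filtering.
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Iterator, Optional

from .amplicon import AmpliconReference, revcomp

DEFAULT_MAX_MISMATCH = 2
MAX_INTERIOR_N_FRACTION = 0.05


@dataclass(frozen=True)
class SequencingRead:
    id: str
    bases: str
    qualities: Optional[str] = None

    def __post_init__(self) -> None:
        if self.qualities is not None and len(self.qualities) != len(self.bases):
            raise ValueError(f"read {self.id}: quality string length mismatch")

    def reverse_complement(self) -> "SequencingRead":
        quals = self.qualities[::-1] if self.qualities is not None else None
        return SequencingRead(self.id, _revcomp_with_n(self.bases), quals)


def _revcomp_with_n(bases: str) -> str:
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    return "".join(comp[b] for b in reversed(bases))


@dataclass
class FilterReport:
    """Accounting of the primer-anchor filter.

    ``n_anchor_pass + n_anchor_fail + n_too_short`` partitions ``n_input``
    exactly.  Reads that match neither primer prefix, and reads whose
    interior N fraction exceeds the cap, are counted as anchor failures
    (the informational ``n_high_n`` is a subset of ``n_anchor_fail``).
    """

    n_input: int = 0
    n_oriented: int = 0
    n_anchor_pass: int = 0
    n_anchor_fail: int = 0
    n_too_short: int = 0
    n_high_n: int = 0

    def validate(self) -> None:
        if self.n_input != self.n_anchor_pass + self.n_anchor_fail + self.n_too_short:
            raise AssertionError(f"filter counts do not partition the input: {self}")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


def hamming_within(a: str, b: str, max_mismatch: int) -> bool:
    """True when equal-length strings differ at <= max_mismatch positions.

    N never matches anything, including another N.
    """
    if len(a) != len(b):
        return False
    mism = 0
    for x, y in zip(a, b):
        if x != y or x == "N":
            mism += 1
            if mism > max_mismatch:
                return False
    return True


def orient_read(
    read: SequencingRead, ref: AmpliconReference, max_mismatch: int = DEFAULT_MAX_MISMATCH
) -> Optional[SequencingRead]:
    """Orient a read to the forward strand, or return None.

    A read whose prefix matches the forward primer is already forward; a
    prefix matching the reverse primer (as synthesised, i.e. the reverse
    strand 5' end) means the read is the reverse strand and is flipped.
    Forward wins if both somehow match.  Idempotent: an oriented read
    starts with the forward primer and is returned unchanged.
    """
    pf, pr = ref.primer_fwd, ref.primer_rev
    if len(read.bases) >= len(pf) and hamming_within(read.bases[: len(pf)], pf, max_mismatch):
        return read
    if len(read.bases) >= len(pr) and hamming_within(read.bases[: len(pr)], pr, max_mismatch):
        return read.reverse_complement()
    return None


def anchor_filter(
    read: SequencingRead, ref: AmpliconReference, max_mismatch: int = DEFAULT_MAX_MISMATCH
) -> bool:
    """Both-ends-within-primers filter on an oriented read.

    Pass iff the first ``len(primer_fwd)`` bases match the forward primer
    and the last ``len(primer_rev)`` bases match the reverse complement of
    the reverse primer, each within ``max_mismatch``.  Reads too short to
    contain both primers fail (callers count them separately).
    """
    pf = ref.primer_fwd
    pr_rc = revcomp(ref.primer_rev)
    if len(read.bases) < len(pf) + len(pr_rc):
        return False
    return hamming_within(read.bases[: len(pf)], pf, max_mismatch) and hamming_within(
        read.bases[-len(pr_rc):], pr_rc, max_mismatch
    )


def _strip_prefix(bases: str, quals: Optional[str], adaptor: str):
    if adaptor and len(bases) > len(adaptor) and hamming_within(bases[: len(adaptor)], adaptor, 1):
        return bases[len(adaptor):], quals[len(adaptor):] if quals else None, True
    return bases, quals, False


def _strip_suffix(bases: str, quals: Optional[str], tail: str):
    if tail and len(bases) > len(tail) and hamming_within(bases[-len(tail):], tail, 1):
        return bases[: -len(tail)], quals[: -len(tail)] if quals else None, True
    return bases, quals, False


def strip_adaptors(read: SequencingRead, adaptor_fwd: str, adaptor_rev: str) -> SequencingRead:
    """Remove a leading ``adaptor_fwd`` and trailing revcomp(``adaptor_rev``).

    Adaptors are the 5' tails of the two PCR primers; on a forward-oriented
    read they appear before the forward primer and (reverse-complemented)
    after the reverse primer.  Each is removed when present exactly or with
    one mismatch; the primers themselves are retained.
    """
    bases, quals = read.bases, read.qualities
    bases, quals, lead = _strip_prefix(bases, quals, adaptor_fwd)
    bases, quals, trail = _strip_suffix(bases, quals, revcomp(adaptor_rev) if adaptor_rev else "")
    if not (lead or trail):
        return read
    return SequencingRead(read.id, bases, quals)


def read_fastq(path) -> Iterator[SequencingRead]:
    """Iterate a FASTQ file (plain or gzipped)."""
    from Bio import SeqIO

    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            quals = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
            yield SequencingRead(rec.id, str(rec.seq).upper(), quals)


def filter_reads(
    reads: Iterable[SequencingRead],
    ref: AmpliconReference,
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
) -> tuple[list[SequencingRead], FilterReport]:
    """Orient, adaptor-strip and anchor-filter a stream of reads.

    Returns the passing (oriented, adaptor-free) reads plus a
    :class:`FilterReport` whose counts partition the input.
    """
    report = FilterReport()
    kept: list[SequencingRead] = []
    min_len = len(ref.primer_fwd) + len(ref.primer_rev)
    for read in reads:
        report.n_input += 1
        # adaptors may precede the primer on either strand; strip both ways
        read = strip_adaptors(read, ref.adaptor_fwd, ref.adaptor_rev)
        read = strip_adaptors(read, ref.adaptor_rev, ref.adaptor_fwd)
        if len(read.bases) < min_len:
            report.n_too_short += 1
            continue
        interior = read.bases[len(ref.primer_fwd): -len(ref.primer_rev)]
        if interior and interior.count("N") / len(interior) > MAX_INTERIOR_N_FRACTION:
            report.n_high_n += 1
            report.n_anchor_fail += 1
            continue
        oriented = orient_read(read, ref, max_mismatch)
        if oriented is None:
            report.n_anchor_fail += 1
            continue
        report.n_oriented += 1
        if anchor_filter(oriented, ref, max_mismatch):
            report.n_anchor_pass += 1
            kept.append(oriented)
        else:
            report.n_anchor_fail += 1
    report.validate()
    return kept, report
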
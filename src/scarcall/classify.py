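"""Repair-event classification and junction signatures.

Every aligned read receives exactly one class:

* WILDTYPE — no variants.
* FILTERED_POLYA — only homopolymer-slippage artifacts (pure-A/T length
  variation inside an annotated polyA tract); excluded from repair counts.
* SNV — substitutions only.
* DELETION — one or more deletions, no insertion.
* INSERTION — insertion(s) that do not duplicate adjacent sequence.
* TANDEM_DUPLICATION — a single insertion that exactly duplicates the
  reference segment adjacent to the insertion point.
* COMPOUND_TD — a tandem duplication accompanied by any additional variant.
* DELINS — a deletion with an insertion at the same junction.

plus two bookkeeping outcomes (UNALIGNABLE for reads rejected by the
aligner's edited-column cap).  Signatures computed per read: junction
microhomology of the deletion (the length of the exact repeat spanning the
junction, equivalently the number of alternative placements of the same
deletion), tandem-duplication intervals, and templated-insert evidence
(an insert copied, on either strand, from sequence near the junction — the
footprint of polymerase-theta-mediated end joining).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

from .amplicon import AmpliconReference, HomopolymerTract, revcomp
from .align import Variant, left_align

#: substitutions within this many bases of an indel junction are treated as
#: part of the junction (alignment ambiguity), not as independent mutations
JUNCTION_MARGIN = 2

#: a deletion and insertion at most this far apart form a delins
DELINS_MAX_GAP = 5

#: templated-insert search defaults: window around the junction, minimum
#: matched length worth reporting
TEMPLATE_WINDOW = 25
TEMPLATE_MIN_LEN = 3


class RepairClass(str, Enum):
    WILDTYPE = "WILDTYPE"
    SNV = "SNV"
    DELETION = "DELETION"
    INSERTION = "INSERTION"
    DELINS = "DELINS"
    TANDEM_DUPLICATION = "TANDEM_DUPLICATION"
    COMPOUND_TD = "COMPOUND_TD"
    FILTERED_POLYA = "FILTERED_POLYA"
    UNALIGNABLE = "UNALIGNABLE"


#: classes that count as mutagenic repair products
MUTAGENIC_CLASSES = frozenset(
    {
        RepairClass.DELETION,
        RepairClass.INSERTION,
        RepairClass.DELINS,
        RepairClass.TANDEM_DUPLICATION,
        RepairClass.COMPOUND_TD,
    }
)


@dataclass(frozen=True)
class TemplateMatch:
    """An insert (or part of it) copied from reference near the junction."""

    start: int
    end: int
    strand: str  # "+" forward, "-" reverse complement
    matched_len: int
    offset_from_junction: int


@dataclass
class ClassifiedRead:
    read_id: str
    repair_class: RepairClass
    variants: list[Variant] = field(default_factory=list)
    del_start: Optional[int] = None
    del_end: Optional[int] = None
    ins_len: int = 0
    mh_len: Optional[int] = None
    template: Optional[TemplateMatch] = None
    distance_to_cut: Optional[int] = None
    complex: bool = False

    @property
    def del_len(self) -> int:
        if self.del_start is None:
            return 0
        return self.del_end - self.del_start

    @property
    def event_size(self) -> int:
        """Total edited length: deleted plus inserted bases."""
        return self.del_len + self.ins_len


def _is_polya_variant(v: Variant, tracts: Sequence[HomopolymerTract]) -> bool:
    """True when ``v`` is pure tract-base length variation in/at a tract."""
    if v.kind == "substitution":
        return False
    for t in tracts:
        if v.kind == "deletion":
            if t.start <= v.ref_start and v.ref_end <= t.end:
                return True
        else:  # insertion
            if t.contains(v.ref_start) and set(v.alt) == {t.base}:
                return True
    return False


def is_polyA_only(variants: Sequence[Variant], tracts: Sequence[HomopolymerTract]) -> bool:
    """True iff the read's variants are all polyA-slippage artifacts.

    Wildtype reads (no variants) are not filtered; a read mixing tract
    slippage with any other variant is not filtered either (the slippage
    is then ignored as noise during classification).
    """
    return bool(variants) and all(_is_polya_variant(v, tracts) for v in variants)


def compute_microhomology(deletion: Variant, ref_sequence: str) -> int:
    """Length of the exact repeat spanning a deletion junction.

    For a left-aligned deletion [s, e) this is the largest k with
    ``ref[e:e+k] == ref[s:s+k]`` — equivalently, the number of distinct
    reference placements of the same deletion minus one.  A junction whose
    flanks share nothing scores 0.
    """
    s, e = deletion.ref_start, deletion.ref_end
    n = len(ref_sequence)
    k = 0
    while e + k < n and ref_sequence[s + k] == ref_sequence[e + k]:
        k += 1
    return k


def _insertion_placements(ins: Variant, ref: str) -> list[Variant]:
    """All placements of an insertion yielding the identical edited string."""
    out = [left_align(ins, ref)]
    # slide right from the leftmost placement
    cur = out[0]
    while cur.ref_start < len(ref) and cur.alt[0] == ref[cur.ref_start]:
        cur = Variant("insertion", cur.ref_start + 1, cur.ref_start + 1,
                      cur.alt[1:] + ref[cur.ref_start])
        out.append(cur)
    return out


def detect_tandem_duplication(
    insertion: Variant, ref_sequence: str
) -> tuple[bool, Optional[tuple[int, int]]]:
    """Does this insertion duplicate an adjacent reference segment?

    True when, in some equivalent placement, the insert equals the
    reference segment immediately left- or right-adjacent to the insertion
    point; the edited sequence then contains that segment twice in tandem.
    Returns the duplicated reference interval.
    """
    L = len(insertion.alt)
    for placement in _insertion_placements(insertion, ref_sequence):
        p, alt = placement.ref_start, placement.alt
        if p - L >= 0 and ref_sequence[p - L: p] == alt:
            return True, (p - L, p)
        if p + L <= len(ref_sequence) and ref_sequence[p: p + L] == alt:
            return True, (p, p + L)
    return False, None


def detect_templated_insert(
    insert_alt: str,
    junction: int,
    ref_sequence: str,
    window: int = TEMPLATE_WINDOW,
    min_len: int = TEMPLATE_MIN_LEN,
) -> Optional[TemplateMatch]:
    """Search for the insert (or its reverse complement) near the junction.

    The full insert is sought first; failing that, its longest prefix or
    suffix (templated inserts are junction-anchored copies).  Matches of
    length >= ``min_len`` within ``junction +/- window`` are reported; ties
    are broken toward the match nearest the junction, forward strand first,
    prefix before suffix.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    lo = max(0, junction - window)
    hi = min(len(ref_sequence), junction + window)
    region = ref_sequence[lo:hi]

    def occurrences(query: str):
        start = region.find(query)
        while start != -1:
            yield lo + start
            start = region.find(query, start + 1)

    for k in range(len(insert_alt), min_len - 1, -1):
        candidates: list[TemplateMatch] = []
        pieces = [insert_alt[:k]] if k == len(insert_alt) else [insert_alt[:k], insert_alt[-k:]]
        for piece in dict.fromkeys(pieces):
            for strand, query in (("+", piece), ("-", revcomp(piece))):
                for start in occurrences(query):
                    mid = start + k / 2
                    candidates.append(
                        TemplateMatch(start, start + k, strand, k, round(mid - junction))
                    )
        if candidates:
            candidates.sort(key=lambda m: (abs(m.offset_from_junction), m.strand == "-", m.start))
            return candidates[0]
    return None


def _distance_to_cut(start: int, end: int, cut: int) -> int:
    """Signed distance from an event interval to the cut site (0 if spanning)."""
    if start <= cut <= end:
        return 0
    return start - cut if start > cut else end - cut


def _nearest(variants: list[Variant], cut: int) -> Variant:
    return min(variants, key=lambda v: (abs(_distance_to_cut(v.ref_start, v.ref_end, cut)), v.ref_start))


def classify_read(
    variants: Sequence[Variant],
    ref: AmpliconReference,
    read_id: str = "",
    junction_margin: int = JUNCTION_MARGIN,
    delins_max_gap: int = DELINS_MAX_GAP,
    template_window: int = TEMPLATE_WINDOW,
    template_min_len: int = TEMPLATE_MIN_LEN,
) -> ClassifiedRead:
    """Assign a repair class and junction signatures to one aligned read.

    Precedence: wildtype, polyA-artifact filter, substitutions-only, then
    indel-driven classes.  PolyA-tract slippage mixed with real variants is
    ignored as noise; substitutions within ``junction_margin`` of an indel
    junction are treated as alignment ambiguity at the junction and do not
    promote a class to its compound form.
    """
    ref_seq = ref.sequence
    variants = sorted(variants, key=lambda v: (v.ref_start, v.ref_end))
    out = ClassifiedRead(read_id=read_id, repair_class=RepairClass.WILDTYPE, variants=list(variants))
    if not variants:
        return out
    if is_polyA_only(variants, ref.tracts):
        out.repair_class = RepairClass.FILTERED_POLYA
        return out

    real = [v for v in variants if not _is_polya_variant(v, ref.tracts)]
    dels = [v for v in real if v.kind == "deletion"]
    inss = [v for v in real if v.kind == "insertion"]
    subs = [v for v in real if v.kind == "substitution"]

    junctions: list[int] = []
    for v in dels + inss:
        junctions.extend(v.interval())
    core_subs = [
        s for s in subs
        if not junctions
        or min(min(abs(s.ref_start - j), abs(s.ref_end - j)) for j in junctions) > junction_margin
    ]

    if not dels and not inss:
        out.repair_class = RepairClass.SNV
        return out

    cut = ref.cut_site
    if dels and not inss:
        out.repair_class = RepairClass.DELETION
        primary = _nearest(dels, cut)
        _fill_deletion(out, primary, ref_seq, cut)
    elif inss and not dels:
        td_hits = [(v, *detect_tandem_duplication(v, ref_seq)) for v in inss]
        any_td = any(hit for _, hit, _ in td_hits)
        if any_td and len(inss) == 1 and not core_subs:
            out.repair_class = RepairClass.TANDEM_DUPLICATION
        elif any_td:
            out.repair_class = RepairClass.COMPOUND_TD
        else:
            out.repair_class = RepairClass.INSERTION
        primary = _nearest(inss, cut)
        out.ins_len = len(primary.alt)
        out.distance_to_cut = _distance_to_cut(primary.ref_start, primary.ref_end, cut)
        if not any(hit for v, hit, _ in td_hits if v is primary):
            out.template = detect_templated_insert(
                primary.alt, primary.ref_start, ref_seq, template_window, template_min_len
            )
    else:
        # deletion(s) and insertion(s): pair the closest del/ins
        pair = min(
            ((d, i) for d in dels for i in inss),
            key=lambda p: _pair_gap(*p),
        )
        if _pair_gap(*pair) <= delins_max_gap:
            d, i = pair
            out.repair_class = RepairClass.DELINS
            _fill_deletion(out, d, ref_seq, cut)
            out.ins_len = len(i.alt)
            out.distance_to_cut = _distance_to_cut(
                min(d.ref_start, i.ref_start), max(d.ref_end, i.ref_end), cut
            )
            out.template = detect_templated_insert(
                i.alt, i.ref_start, ref_seq, template_window, template_min_len
            )
        else:
            # scattered del + ins: class follows the variant nearest the cut
            out.complex = True
            primary = _nearest(dels + inss, cut)
            if primary.kind == "deletion":
                out.repair_class = RepairClass.DELETION
                _fill_deletion(out, primary, ref_seq, cut)
            else:
                hit, _ = detect_tandem_duplication(primary, ref_seq)
                out.repair_class = RepairClass.COMPOUND_TD if hit else RepairClass.INSERTION
                out.ins_len = len(primary.alt)
                out.distance_to_cut = _distance_to_cut(primary.ref_start, primary.ref_end, cut)
    return out


def _pair_gap(d: Variant, i: Variant) -> int:
    """Gap between a deletion span and an insertion point (0 if touching)."""
    if d.ref_start <= i.ref_start <= d.ref_end:
        return 0
    return i.ref_start - d.ref_end if i.ref_start > d.ref_end else d.ref_start - i.ref_start


def _fill_deletion(out: ClassifiedRead, d: Variant, ref_seq: str, cut: int) -> None:
    out.del_start, out.del_end = d.ref_start, d.ref_end
    out.mh_len = compute_microhomology(d, ref_seq)
    out.distance_to_cut = _distance_to_cut(d.ref_start, d.ref_end, cut)


def classification_table(reads: Sequence[ClassifiedRead]):
    """Per-read classification table as a pandas DataFrame."""
    import pandas as pd

    rows = []
    for r in reads:
        t = r.template
        rows.append(
            {
                "read_id": r.read_id,
                "class": r.repair_class.value,
                "del_start": r.del_start,
                "del_end": r.del_end,
                "del_len": r.del_len or None,
                "ins_len": r.ins_len or None,
                "mh_len": r.mh_len,
                "templated": bool(t) if (r.ins_len or t) else None,
                "template_start": t.start if t else None,
                "template_strand": t.strand if t else None,
                "distance_to_cut": r.distance_to_cut,
                "complex": r.complex,
            }
        )
    return pd.DataFrame(rows)
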
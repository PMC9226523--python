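"""Ground-truth synthetic amplicon reads.

Generates a reference amplicon bounded by the assay's PCR primers and a
FASTQ of full-length (merged, amplicon-spanning) reads whose repair-event
composition is known per read.  The generator emulates the structure of
the real deep-sequencing data: wildtype reads, substitutions, deletions
with 0-10 bp junction microhomology, insertions, tandem duplications,
deletion+insertion compounds (optionally with inserts templated from
flanking sequence on either strand), and polyA-tract slippage reads.

Microhomology is engineered constructively: the reference carries direct-
repeat cassettes around the cut site — two exact copies of a short unit
separated by a fixed spacing, with guard bases that stop the repeat from
extending — so a deletion spanning one copy plus the spacer has exactly
the designed junction microhomology.

Rejection rules keep the emitted truth labels faithful under the package's
own event taxonomy: a random insert that happens to duplicate its flank is
resampled (it would *be* a tandem duplication), and delins inserts that
share boundary bases with the deleted span or its flanks are resampled
(the combined edit would reduce to a smaller, different event).  Reads are
emitted on either strand with probability 1/2 to exercise orientation;
quality strings are constant because the pipeline never uses them.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .amplicon import AmpliconReference, find_homopolymer_tracts, revcomp
from .align import Variant, apply_variants, left_align
from .classify import RepairClass, detect_tandem_duplication, _is_polya_variant

#: the assay's PCR primers and library adaptors (5' tails), as synthesised
PRIMER_FWD = "AAAGTTATCTCCAGGCTCGC"
PRIMER_REV = "TTCACCCTCTCCACTGACAG"
ADAPTOR_FWD = "GATGTGTATAAGAGACAG"
ADAPTOR_REV = "CGTGTGCTCTTCCGATCT"

_BASES = np.array(list("ACGT"))

DEFAULT_CLASS_MIX = {
    RepairClass.WILDTYPE: 0.40,
    RepairClass.DELETION: 0.25,
    RepairClass.INSERTION: 0.10,
    RepairClass.DELINS: 0.10,
    RepairClass.TANDEM_DUPLICATION: 0.05,
    RepairClass.COMPOUND_TD: 0.05,
    RepairClass.SNV: 0.05,
}


@dataclass(frozen=True)
class Cassette:
    """An engineered direct repeat: deleting [del_start, del_end) leaves a
    junction with exactly ``mh_len`` bases of microhomology."""

    del_start: int
    del_end: int
    mh_len: int


@dataclass
class SimulationConfig:
    seed: int = 0
    n_reads: int = 1000
    ref_length: int = 300
    cut_site: Optional[int] = None  # default: centered at ref_length//2 + 10
    class_mix: dict = field(default_factory=lambda: dict(DEFAULT_CLASS_MIX))
    deletion_size_dist: dict = field(
        default_factory=lambda: {"kind": "geometric", "p": 0.12, "min": 1, "max": 40}
    )
    insertion_len_dist: dict = field(
        default_factory=lambda: {"kind": "geometric", "p": 0.35, "min": 1, "max": 12}
    )
    #: (mh_len, spacing) direct repeats; spacing is the deletion size
    mh_cassettes: tuple = ((1, 6), (2, 9), (3, 12), (5, 16), (8, 24))
    #: fraction of DELETION reads drawn from the engineered cassettes
    cassette_fraction: float = 0.5
    #: fraction of DELINS inserts copied from a flank near the junction
    templated_fraction: float = 0.5
    template_len_range: tuple = (5, 8)
    template_window: int = 25
    td_len_range: tuple = (2, 12)
    polyA_tract_len: int = 8
    polyA_min_len: int = 4
    #: post-hoc noise channels, off by default (truth labels describe the
    #: repair event, not the noise)
    polyA_slip_rate: float = 0.0
    sub_error_rate: float = 0.0
    revcomp_prob: float = 0.5
    with_adaptors: bool = False

    def __post_init__(self) -> None:
        self.class_mix = {RepairClass(k): float(v) for k, v in self.class_mix.items()}
        total = sum(self.class_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class_mix probabilities sum to {total}, not 1")

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        import yaml

        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


@dataclass
class SimulatedAmplicon:
    ref: AmpliconReference
    cassettes: list[Cassette]
    window: tuple[int, int]  # mutation window [lo, hi)


@dataclass
class TruthRecord:
    read_id: str
    true_class: RepairClass
    variants: list[Variant]
    del_start: Optional[int] = None
    del_end: Optional[int] = None
    ins_seq: str = ""
    mh_len: Optional[int] = None
    template_source: Optional[str] = None  # "strand:start-end"
    emitted_strand: str = "+"


def _placement_mh(ref: str, s: int, e: int) -> int:
    """Junction microhomology of a left-aligned deletion, by enumeration of
    every equivalent placement of the same-size deletion."""
    d = e - s
    edited = ref[:s] + ref[e:]
    count = 0
    s2 = s + 1
    while s2 + d <= len(ref) and ref[:s2] + ref[s2 + d:] == edited:
        count += 1
        s2 += 1
    return count


def _left_align_span(ref: str, s: int, e: int) -> tuple[int, int]:
    while s > 0 and ref[s - 1] == ref[e - 1]:
        s -= 1
        e -= 1
    return s, e


def _random_filler(rng: np.random.Generator, n: int, max_at_run: int = 3) -> str:
    """Random DNA with no A or T run longer than ``max_at_run``."""
    out: list[str] = []
    run_base, run_len = "", 0
    while len(out) < n:
        b = str(_BASES[rng.integers(4)])
        if b in "AT" and b == run_base and run_len >= max_at_run:
            continue
        run_len = run_len + 1 if b == run_base else 1
        run_base = b
        out.append(b)
    return "".join(out)


def _pick(rng: np.random.Generator, exclude: str) -> str:
    choices = [b for b in "ACGT" if b not in exclude]
    return choices[rng.integers(len(choices))]


def _sample_size(rng: np.random.Generator, dist: dict) -> int:
    lo, hi = dist.get("min", 1), dist.get("max", 40)
    if dist["kind"] == "geometric":
        size = lo - 1 + int(rng.geometric(dist["p"]))
    elif dist["kind"] == "uniform":
        size = int(rng.integers(lo, hi + 1))
    else:
        raise ValueError(f"unknown size distribution {dist['kind']!r}")
    return min(max(size, lo), hi)


def make_reference(config: SimulationConfig) -> SimulatedAmplicon:
    """Build a seeded random amplicon with engineered repeat cassettes.

    Layout: forward primer, filler, a polyA tract, filler, the cassette row
    straddling the cut site, filler, revcomp(reverse primer).  Filler never
    contains an A/T run reaching the polyA detection threshold, and guard
    bases around each cassette stop its repeat from extending, so the
    designed microhomology lengths are exact and the only annotated tract
    is the deliberate one.
    """
    rng = np.random.default_rng(config.seed)
    L = config.ref_length
    cut = config.cut_site if config.cut_site is not None else L // 2 + 10
    pf, pr_rc = PRIMER_FWD, revcomp(PRIMER_REV)
    tract_start = len(pf) + 10
    tract_end = tract_start + config.polyA_tract_len

    # cassette row: [unit | spacer-filler | unit | guard+gap] per cassette
    row_parts: list[str] = []
    cassettes: list[Cassette] = []
    row_len = sum(sp + mh + 3 for mh, sp in config.mh_cassettes)
    row_start = cut - row_len // 2
    pos = row_start
    for mh, spacing in config.mh_cassettes:
        if spacing < mh:
            raise ValueError(f"cassette spacing {spacing} shorter than repeat {mh}")
        unit = _pick(rng, "AT") + _random_filler(rng, mh - 2, 2) + _pick(rng, "AT") if mh >= 2 else _pick(rng, "AT")
        spacer = _random_filler(rng, spacing - mh)
        # guards: stop the junction repeat from extending beyond the unit
        guard_r = _pick(rng, (spacer + unit)[0])  # != ref[a+mh]
        gap = _random_filler(rng, 2)
        row_parts.append(unit + spacer + unit + guard_r + gap)
        cassettes.append(Cassette(pos, pos + spacing, mh))
        pos += spacing + mh + 3
    row = "".join(row_parts)

    left_len = row_start - tract_end
    right_len = L - len(pr_rc) - (row_start + row_len)
    if left_len < 3 or right_len < 3:
        raise ValueError("cassettes do not fit between the tract and the reverse primer")
    left_fill = _random_filler(rng, left_len)
    right_fill = _random_filler(rng, right_len)
    mid_fill = _random_filler(rng, tract_start - len(pf))

    # guard the tract and the cassette row boundaries (C/G so no A/T run can
    # extend across a boundary)
    mid_fill = (mid_fill[:-1] + _pick(rng, "AT")) if mid_fill else mid_fill
    left_fill = _pick(rng, "AT") + left_fill[1:-1] + _pick(rng, row[0] + "AT")
    # left guard for the first cassette handled above; also guard each
    # cassette's pre-base inside the row assembly below
    seq = pf + mid_fill + "A" * config.polyA_tract_len + left_fill + row + right_fill + pr_rc
    assert len(seq) == L

    # enforce the left-alignment guard per cassette: ref[a-1] != ref[b-1]
    seq_l = list(seq)
    for c in cassettes:
        if seq_l[c.del_start - 1] == seq_l[c.del_end - 1]:
            seq_l[c.del_start - 1] = _pick(rng, seq_l[c.del_end - 1] + "AT")
    seq = "".join(seq_l)

    ref = AmpliconReference(
        name=f"sim_amplicon_seed{config.seed}",
        sequence=seq,
        cut_site=cut,
        primer_fwd=PRIMER_FWD,
        primer_rev=PRIMER_REV,
        adaptor_fwd=ADAPTOR_FWD,
        adaptor_rev=ADAPTOR_REV,
        tracts=tuple(find_homopolymer_tracts(seq, config.polyA_min_len)),
        polyA_min_len=config.polyA_min_len,
    )
    expected = [t for t in ref.tracts if (t.start, t.end) == (tract_start, tract_end)]
    if len(ref.tracts) != 1 or not expected:
        raise AssertionError("reference construction produced stray homopolymer tracts")
    for c in cassettes:
        s, e = _left_align_span(seq, c.del_start, c.del_end)
        if (s, e) != (c.del_start, c.del_end) or _placement_mh(seq, s, e) != c.mh_len:
            raise AssertionError(f"cassette {c} does not realise its designed microhomology")
    lo = max(len(PRIMER_FWD) + 2, tract_end + 2, cut - 48)
    hi = min(L - len(PRIMER_REV) - 2, cut + 48)
    return SimulatedAmplicon(ref=ref, cassettes=cassettes, window=(lo, hi))


def _random_deletion(sim: SimulatedAmplicon, config, rng) -> Variant:
    ref = sim.ref.sequence
    lo, hi = sim.window
    for _ in range(100):
        d = _sample_size(rng, config.deletion_size_dist)
        if lo + d > hi:
            continue
        s = int(rng.integers(lo, hi - d + 1))
        s, e = _left_align_span(ref, s, s + d)
        v = Variant("deletion", s, e)
        if not _is_polya_variant(v, sim.ref.tracts):
            return v
    raise RuntimeError("could not draw a deletion inside the mutation window")


def _random_insert(rng, length: int) -> str:
    return "".join(_BASES[rng.integers(4, size=length)])


def simulate_event(
    true_class: RepairClass, sim: SimulatedAmplicon, config: SimulationConfig, rng
) -> tuple[str, TruthRecord]:
    """Emit one forward-strand read of the requested class plus its truth.

    The returned record's variants, applied to the reference, reproduce the
    read exactly.
    """
    ref = sim.ref.sequence
    cut = sim.ref.cut_site
    lo, hi = sim.window
    rec = TruthRecord(read_id="", true_class=true_class, variants=[])

    if true_class == RepairClass.WILDTYPE:
        pass

    elif true_class == RepairClass.SNV:
        n_subs = int(rng.choice([1, 2, 3], p=[0.7, 0.2, 0.1]))
        positions = sorted(rng.choice(np.arange(lo, hi), size=n_subs, replace=False).tolist())
        rec.variants = [
            Variant("substitution", p, p + 1, _pick(rng, ref[p])) for p in positions
        ]

    elif true_class == RepairClass.DELETION:
        if sim.cassettes and rng.random() < config.cassette_fraction:
            c = sim.cassettes[rng.integers(len(sim.cassettes))]
            v = Variant("deletion", c.del_start, c.del_end)
            rec.mh_len = c.mh_len
        else:
            v = _random_deletion(sim, config, rng)
            rec.mh_len = _placement_mh(ref, v.ref_start, v.ref_end)
        rec.variants = [v]
        rec.del_start, rec.del_end = v.ref_start, v.ref_end

    elif true_class == RepairClass.INSERTION:
        for _ in range(200):
            m = _sample_size(rng, config.insertion_len_dist)
            p = int(rng.integers(lo, hi))
            alt = _random_insert(rng, m)
            v = left_align(Variant("insertion", p, p, alt), ref)
            if _is_polya_variant(v, sim.ref.tracts):
                continue
            if detect_tandem_duplication(v, ref)[0]:
                continue  # would *be* a TD; resample
            break
        else:
            raise RuntimeError("could not draw a non-duplicating insertion")
        rec.variants = [v]
        rec.ins_seq = v.alt

    elif true_class in (RepairClass.TANDEM_DUPLICATION, RepairClass.COMPOUND_TD):
        for _ in range(200):
            tl = int(rng.integers(config.td_len_range[0], config.td_len_range[1] + 1))
            p = int(rng.integers(lo + tl, hi))
            unit = ref[p - tl: p]
            if len(set(unit)) == 1:
                continue  # single-base unit: slippage-like, not a clean TD
            v = left_align(Variant("insertion", p, p, unit), ref)
            if _is_polya_variant(v, sim.ref.tracts):
                continue
            break
        else:
            raise RuntimeError("could not draw a tandem duplication")
        rec.variants = [v]
        rec.ins_seq = v.alt
        if true_class == RepairClass.COMPOUND_TD:
            # the extra substitution stays well clear of the (left-aligned)
            # duplication junction so it cannot be absorbed as junction noise
            j0, j1 = v.ref_start - tl, v.ref_start + tl
            for _ in range(200):
                q = int(rng.integers(lo, hi))
                if q < j0 - 8 or q > j1 + 8:
                    break
            else:
                raise RuntimeError("could not place the compound substitution")
            sub = Variant("substitution", q, q + 1, _pick(rng, ref[q]))
            rec.variants = sorted(rec.variants + [sub], key=lambda v: v.ref_start)

    elif true_class == RepairClass.DELINS:
        # the deleted part is kept at 5-18 bp and the insert dissimilar
        # from the deleted span, otherwise the optimal alignment of the
        # read collapses the compound into a plain indel with
        # substitutions and the read would not encode a delins at all; a
        # final alignment check rejects the residual ambiguous draws
        for _ in range(500):
            d = min(18, max(5, _sample_size(rng, config.deletion_size_dist)))
            if lo + d > hi:
                continue
            s = int(rng.integers(lo, hi - d + 1))
            s, e = _left_align_span(ref, s, s + d)
            dele = Variant("deletion", s, e)
            if _is_polya_variant(dele, sim.ref.tracts):
                continue
            alt = _draw_delins_insert(ref, s, e, config, rng, rec)
            if alt is None:
                continue
            if not _delins_is_unambiguous(ref, s, e, alt):
                continue
            rec.variants = [dele, Variant("insertion", e, e, alt)]
            rec.del_start, rec.del_end = s, e
            rec.ins_seq = alt
            rec.mh_len = _placement_mh(ref, s, e)
            break
        else:
            raise RuntimeError("could not draw a delins event")

    elif true_class == RepairClass.FILTERED_POLYA:
        tract = sim.ref.tracts[0]
        delta = int(rng.choice([-2, -1, 1, 2]))
        if len(tract) + min(delta, 0) < config.polyA_min_len:
            delta = abs(delta)
        if delta > 0:
            rec.variants = [Variant("insertion", tract.start, tract.start, "A" * delta)]
        else:
            rec.variants = [Variant("deletion", tract.start, tract.start - delta)]

    else:
        raise ValueError(f"cannot simulate class {true_class}")

    bases = apply_variants(ref, rec.variants)
    return bases, rec


def _delins_is_unambiguous(ref: str, s: int, e: int, alt: str) -> bool:
    """Does the edited read uniquely encode deletion [s,e) plus insert?

    The candidate read's optimal global alignment must decompose into
    exactly one deletion with the intended (left-aligned) span and one
    adjacent insertion carrying the intended bases; otherwise the read has
    a simpler interpretation and is not a valid delins ground truth.
    """
    from .align import call_variants

    read = ref[:s] + alt + ref[e:]
    variants, _ = call_variants(read, ref)
    dels = [v for v in variants if v.kind == "deletion"]
    inss = [v for v in variants if v.kind == "insertion"]
    if len(dels) != 1 or len(inss) != 1 or len(variants) != 2:
        return False
    return (dels[0].ref_start, dels[0].ref_end) == (s, e) and inss[0].alt == alt


def _delins_guards(ref: str, s: int, e: int, alt: str, open_saving: float = 13.0) -> bool:
    """Cheap screens against reads whose compound edit has a simpler
    optimal-alignment representation.

    Rejects inserts that (a) merge into or slide along the junction flanks,
    (b) re-anchor a suffix/prefix against the deleted span without opening
    a new gap, or (c) can be paired base-by-base against the span at some
    offset with enough coincidental matches to pay for the eliminated
    gap-open (the gap-elimination channel).  The aligner gives the final
    verdict; these guards only keep rejection sampling efficient.
    """
    span = ref[s:e]
    if len(alt) == len(span):
        return False  # equal lengths invite a substitution-run representation
    flank_l = ref[s - 1] if s > 0 else ""
    flank_r = ref[e] if e < len(ref) else ""
    if alt[0] in (span[0], flank_l, flank_r):
        return False
    if alt[-1] in (span[-1], span[0], flank_l, flank_r):
        return False
    for k in range(1, min(len(alt), len(span)) + 1):
        if alt[-k:] == span[:k] or alt[:k] == span[-k:]:
            return False
    L = min(len(alt), len(span))
    q_allow = int((6 * L - open_saving) // 10)
    short, lng = (alt, span) if len(alt) <= len(span) else (span, alt)
    for off in range(len(lng) - L + 1):
        if sum(a == b for a, b in zip(short, lng[off: off + L])) > q_allow:
            return False
    return True


def _draw_delins_insert(ref, s, e, config, rng, rec) -> Optional[str]:
    """One attempt at a junction insert obeying the ambiguity guards."""
    span = ref[s:e]
    templated = rng.random() < config.templated_fraction
    if templated:
        tl = int(rng.integers(config.template_len_range[0], config.template_len_range[1] + 1))
        w = config.template_window
        left_zone = (max(0, s - w), s - 2 - tl)
        right_zone = (e + 2, min(len(ref), e + w) - tl)
        zones = [z for z in (left_zone, right_zone) if z[1] >= z[0]]
        if not zones:
            return None
        zlo, zhi = zones[rng.integers(len(zones))]
        t = int(rng.integers(zlo, zhi + 1))
        alt = ref[t: t + tl]
        strand = "+"
        if rng.random() < 0.5:
            alt = revcomp(alt)
            strand = "-"
        source = f"{strand}:{t}-{t + tl}"
    else:
        # constructive boundaries: first/last base drawn from the sets the
        # guards allow, interior uniform
        m = int(rng.integers(6, 11))
        flank_l = ref[s - 1] if s > 0 else ""
        flank_r = ref[e] if e < len(ref) else ""
        first_ok = [b for b in "ACGT" if b not in (span[0], flank_l, flank_r)]
        last_ok = [b for b in "ACGT" if b not in (span[-1], span[0], flank_l, flank_r)]
        if not first_ok or not last_ok:
            return None
        alt = (
            first_ok[rng.integers(len(first_ok))]
            + _random_insert(rng, m - 2)
            + last_ok[rng.integers(len(last_ok))]
        )
        source = None
    if not _delins_guards(ref, s, e, alt):
        return None
    rec.template_source = source
    return alt


def _encode_variants(variants: Sequence[Variant]) -> str:
    parts = []
    for v in variants:
        if v.kind == "deletion":
            parts.append(f"del:{v.ref_start}-{v.ref_end}")
        elif v.kind == "insertion":
            parts.append(f"ins:{v.ref_start}:{v.alt}")
        else:
            parts.append(f"sub:{v.ref_start}:{v.alt}")
    return ";".join(parts)


def decode_variants(encoded: str) -> list[Variant]:
    out: list[Variant] = []
    if not encoded:
        return out
    for part in encoded.split(";"):
        kind, rest = part.split(":", 1)
        if kind == "del":
            s, e = rest.split("-")
            out.append(Variant("deletion", int(s), int(e)))
        elif kind == "ins":
            s, alt = rest.split(":")
            out.append(Variant("insertion", int(s), int(s), alt))
        else:
            s, alt = rest.split(":")
            out.append(Variant("substitution", int(s), int(s) + len(alt), alt))
    return out


def _apply_noise(bases: str, config: SimulationConfig, rng) -> str:
    if config.sub_error_rate > 0:
        arr = np.array(list(bases))
        hits = np.nonzero(rng.random(len(arr)) < config.sub_error_rate)[0]
        for i in hits:
            arr[i] = _pick(rng, str(arr[i]))
        bases = "".join(arr)
    return bases


def simulate_dataset(
    config: SimulationConfig,
    fastq_path=None,
    truth_path=None,
    amplicon: Optional[SimulatedAmplicon] = None,
):
    """Generate the full synthetic sample.

    Returns ``(reads, truth_df, sim_amplicon)``; optionally writes the
    FASTQ (gzipped when the path ends in .gz, with a fixed mtime so equal
    seeds give byte-identical files) and the truth table as TSV.  Pass an
    existing ``amplicon`` to emit several samples (e.g. a control and a
    repair-deficient mutant) over the same reference.
    """
    sim = amplicon if amplicon is not None else make_reference(config)
    rng = np.random.default_rng(config.seed + 1)
    classes = list(config.class_mix.keys())
    probs = np.array([config.class_mix[c] for c in classes], dtype=float)
    probs = probs / probs.sum()

    from .reads import SequencingRead

    reads: list[SequencingRead] = []
    truth_rows = []
    draws = rng.choice(len(classes), size=config.n_reads, p=probs)
    for i in range(config.n_reads):
        cls = classes[int(draws[i])]
        bases, rec = simulate_event(cls, sim, config, rng)
        bases = _apply_noise(bases, config, rng)
        if config.polyA_slip_rate > 0 and rng.random() < config.polyA_slip_rate:
            t = sim.ref.tracts[0]
            run_start = bases.find("A" * 4, max(0, t.start - 10))
            if run_start != -1:
                bases = bases[:run_start] + "A" + bases[run_start:]
        rec.read_id = f"read{i:06d}"
        if config.with_adaptors:
            bases = ADAPTOR_FWD + bases + revcomp(ADAPTOR_REV)
        if rng.random() < config.revcomp_prob:
            rec.emitted_strand = "-"
            bases = revcomp(bases)
        reads.append(SequencingRead(rec.read_id, bases, "I" * len(bases)))
        truth_rows.append(
            {
                "read_id": rec.read_id,
                "true_class": rec.true_class.value,
                "del_start": rec.del_start,
                "del_end": rec.del_end,
                "ins_seq": rec.ins_seq,
                "mh_len": rec.mh_len,
                "template_source": rec.template_source,
                "emitted_strand": rec.emitted_strand,
                "variants": _encode_variants(rec.variants),
            }
        )
    truth = pd.DataFrame(truth_rows)

    if fastq_path is not None:
        _write_fastq(reads, fastq_path)
    if truth_path is not None:
        truth.to_csv(truth_path, sep="\t", index=False)
    return reads, truth, sim


def _write_fastq(reads, path) -> None:
    path = Path(path)
    text = "".join(f"@{r.id}\n{r.bases}\n+\n{r.qualities}\n" for r in reads)
    if path.suffix == ".gz":
        with open(path, "wb") as raw:
            with gzip.GzipFile(filename="", mode="wb", fileobj=raw, mtime=0) as fh:
                fh.write(text.encode())
    else:
        path.write_text(text)
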
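import numpy as np
import pytest

from scarcall.align import Variant, apply_variants, call_variants
from scarcall.amplicon import HomopolymerTract, revcomp, find_homopolymer_tracts
from scarcall.classify import (
    RepairClass,
    classify_read,
    compute_microhomology,
    detect_tandem_duplication,
    detect_templated_insert,
    is_polyA_only,
)
from scarcall.reads import SequencingRead, orient_read
from oracles import microhomology_by_enumeration, contains_tandem


def _random_seq(rng, n):
    return "".join(np.array(list("ACGT"))[rng.integers(4, size=n)])


class TestPolyAFilter:
    TRACTS = [HomopolymerTract(10, 16, "A")]

    def test_single_A_deletion_inside_tract(self):
        assert is_polyA_only([Variant("deletion", 12, 13)], self.TRACTS)

    def test_A_insertion_at_tract_boundary(self):
        assert is_polyA_only([Variant("insertion", 10, 10, "AA")], self.TRACTS)

    def test_mixed_with_distant_substitution_not_filtered(self):
        vs = [Variant("deletion", 12, 13), Variant("substitution", 40, 41, "G")]
        assert not is_polyA_only(vs, self.TRACTS)

    def test_wildtype_not_filtered(self):
        assert not is_polyA_only([], self.TRACTS)

    def test_non_tract_base_insertion_not_filtered(self):
        assert not is_polyA_only([Variant("insertion", 12, 12, "G")], self.TRACTS)

    def test_deletion_outside_tract_not_filtered(self):
        assert not is_polyA_only([Variant("deletion", 30, 31)], self.TRACTS)


class TestMicrohomology:
    def test_cat_repeat_junction(self):
        # deleting one CAT from a CATCAT repeat: 3 bp of junction homology
        assert compute_microhomology(Variant("deletion", 3, 6), "GGGCATCATGGG") == 3

    def test_no_shared_flank(self):
        assert compute_microhomology(Variant("deletion", 3, 6), "GGGTACGGG") == 0

    def test_full_tract_deletion(self):
        ref = "CAAAAAG"
        v = Variant("deletion", 1, 6)  # left-aligned full A5 deletion
        assert compute_microhomology(v, ref) == microhomology_by_enumeration(ref, 1, 6)

    def test_agrees_with_placement_enumeration_oracle(self, rng):
        """Fuzzed deletions, including homopolymer and tandem-repeat
        contexts, against brute-force placement enumeration."""
        checked = 0
        while checked < 1000:
            kind = rng.integers(3)
            if kind == 0:
                ref = _random_seq(rng, int(rng.integers(15, 50)))
            elif kind == 1:  # homopolymer-rich
                ref = "".join(
                    str(np.random.default_rng(int(rng.integers(1 << 30))).choice(list("AACGT")))
                    * int(rng.integers(1, 5))
                    for _ in range(12)
                )
            else:  # embedded tandem repeat
                unit = _random_seq(rng, int(rng.integers(2, 5)))
                ref = _random_seq(rng, 8) + unit * 3 + _random_seq(rng, 8)
            if len(ref) < 6:
                continue
            s = int(rng.integers(0, len(ref) - 2))
            e = s + int(rng.integers(1, min(6, len(ref) - s)))
            # implementation requires left-aligned input
            while s > 0 and ref[s - 1] == ref[e - 1]:
                s, e = s - 1, e - 1
            got = compute_microhomology(Variant("deletion", s, e), ref)
            assert got == microhomology_by_enumeration(ref, s, e), (ref, s, e)
            checked += 1


class TestTandemDuplication:
    def test_left_flank_duplication(self):
        # "CTG" inserted after its own copy; the reported unit is the
        # leftmost equivalent placement of the same tandem event
        ref = "AAGCTGCCTT"
        v = Variant("insertion", 6, 6, "CTG")
        ok, interval = detect_tandem_duplication(v, ref)
        assert ok and interval[1] - interval[0] == 3
        assert contains_tandem(apply_variants(ref, [v]), ref[interval[0]: interval[1]])

    def test_non_duplicating_insert(self):
        ok, _ = detect_tandem_duplication(Variant("insertion", 6, 6, "TTT"), "AAGCTGCCTT")
        assert not ok

    def test_single_base_duplication(self):
        ok, interval = detect_tandem_duplication(Variant("insertion", 3, 3, "G"), "ACGTCA")
        assert ok and interval == (2, 3)

    def test_detection_implies_tandem_in_edited_string(self, rng):
        """Whenever a TD is called, the edited sequence literally contains
        the duplicated unit twice in tandem."""
        hits = 0
        for _ in range(400):
            ref = _random_seq(rng, 30)
            p = int(rng.integers(1, 29))
            alt = _random_seq(rng, int(rng.integers(1, 5)))
            v = Variant("insertion", p, p, alt)
            ok, interval = detect_tandem_duplication(v, ref)
            if ok:
                hits += 1
                unit = ref[interval[0]: interval[1]]
                assert contains_tandem(apply_variants(ref, [v]), unit)
        assert hits > 0


class TestTemplatedInsert:
    REF = "GGTACCGGTTAACCGGATCGATTACAGGCATGCGGTTACGGATC"

    def test_forward_copy_near_junction(self):
        insert = self.REF[10:22]  # 12-mer from just left of the junction
        m = detect_templated_insert(insert, 18, self.REF, window=25, min_len=3)
        assert m is not None and m.strand == "+" and m.matched_len == 12

    def test_below_min_len(self):
        assert detect_templated_insert("ACGT", 20, self.REF, window=25, min_len=5) is None

    def test_reverse_complement_copy(self):
        insert = revcomp(self.REF[22:32])
        m = detect_templated_insert(insert, 20, self.REF, window=25, min_len=3)
        assert m is not None and m.strand == "-" and (m.start, m.end) == (22, 32)


class TestClassifyRules:
    def test_rule_table(self, sim_amplicon):
        ref = sim_amplicon.ref
        cut = ref.cut_site
        cases = [
            ([], RepairClass.WILDTYPE),
            ([Variant("substitution", cut, cut + 1, _other(ref.sequence[cut]))], RepairClass.SNV),
            ([Variant("deletion", cut - 8, cut + 7)], RepairClass.DELETION),
            (
                [Variant("deletion", cut - 8, cut + 7),
                 Variant("insertion", cut + 7, cut + 7, "GTT")],
                RepairClass.DELINS,
            ),
        ]
        for variants, expected in cases:
            assert classify_read(variants, ref).repair_class == expected

    def test_polya_only_routed_to_filter(self, sim_amplicon):
        ref = sim_amplicon.ref
        t = ref.tracts[0]
        out = classify_read([Variant("insertion", t.start, t.start, "A")], ref)
        assert out.repair_class == RepairClass.FILTERED_POLYA

    def test_polya_noise_ignored_next_to_real_event(self, sim_amplicon):
        ref = sim_amplicon.ref
        t = ref.tracts[0]
        cut = ref.cut_site
        out = classify_read(
            [Variant("insertion", t.start, t.start, "A"),
             Variant("deletion", cut - 5, cut + 5)],
            ref,
        )
        assert out.repair_class == RepairClass.DELETION

    def test_td_and_compound_td(self, sim_amplicon):
        ref = sim_amplicon.ref
        p = ref.cut_site
        unit = ref.sequence[p - 4: p]
        from scarcall.align import left_align

        td = left_align(Variant("insertion", p, p, unit), ref.sequence)
        assert classify_read([td], ref).repair_class == RepairClass.TANDEM_DUPLICATION
        q = p - 30
        sub = Variant("substitution", q, q + 1, _other(ref.sequence[q]))
        out = classify_read(sorted([td, sub], key=lambda v: v.ref_start), ref)
        assert out.repair_class == RepairClass.COMPOUND_TD

    def test_junction_proximal_substitution_does_not_promote(self, sim_amplicon):
        ref = sim_amplicon.ref
        cut = ref.cut_site
        d = Variant("deletion", cut - 6, cut + 6)
        sub = Variant("substitution", cut + 7, cut + 8, _other(ref.sequence[cut + 7]))
        out = classify_read([d, sub], ref)
        assert out.repair_class == RepairClass.DELETION

    def test_deletion_signature_fields(self, sim_amplicon):
        ref = sim_amplicon.ref
        c = sim_amplicon.cassettes[-1]
        out = classify_read([Variant("deletion", c.del_start, c.del_end)], ref)
        assert out.repair_class == RepairClass.DELETION
        assert out.mh_len == c.mh_len
        assert out.del_len == c.del_end - c.del_start


def _other(base):
    return "ACGT"[("ACGT".index(base) + 1) % 4]


def test_classification_invariant_under_strand(sim_amplicon, rng):
    """A read and its reverse complement, after re-orientation, receive the
    same class."""
    from scarcall.simulate import SimulationConfig, simulate_event, make_reference

    sim = sim_amplicon
    ref = sim.ref
    cfg = SimulationConfig(seed=77)
    gen = np.random.default_rng(99)
    for cls in (RepairClass.DELETION, RepairClass.DELINS, RepairClass.TANDEM_DUPLICATION):
        for _ in range(5):
            bases, _ = simulate_event(cls, sim, cfg, gen)
            for strand_bases in (bases, revcomp(bases)):
                oriented = orient_read(SequencingRead("r", strand_bases), ref)
                variants, _ = call_variants(oriented.bases, ref)
                assert classify_read(variants, ref).repair_class == cls
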
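import math

import pytest
from hypothesis import given, strategies as st

from scarcall.classify import ClassifiedRead, RepairClass
from scarcall.summarize import (
    NormalizationError,
    ReporterCounts,
    deletion_type_distribution,
    make_tornado,
    normalize_to_control,
    repair_score,
    repair_score_se,
    summarize_sample,
)


def _reads(layout):
    """layout: list of (class, n, extra-kwargs)."""
    out = []
    i = 0
    for cls, n, kw in layout:
        for _ in range(n):
            out.append(ClassifiedRead(read_id=f"r{i}", repair_class=cls, **kw))
            i += 1
    return out


DEL = {"del_start": 100, "del_end": 110, "mh_len": 0}


class TestSummarize:
    def test_all_wildtype(self):
        s = summarize_sample(_reads([(RepairClass.WILDTYPE, 100, {})]))
        assert s.mutagenic_fraction == 0.0
        assert s.n_aligned == 100

    def test_half_mutagenic(self):
        s = summarize_sample(
            _reads([(RepairClass.WILDTYPE, 50, {}), (RepairClass.DELETION, 50, DEL)])
        )
        assert s.mutagenic_fraction == 0.5

    def test_polya_excluded_from_denominator(self):
        s = summarize_sample(
            _reads(
                [
                    (RepairClass.WILDTYPE, 40, {}),
                    (RepairClass.DELETION, 40, DEL),
                    (RepairClass.FILTERED_POLYA, 20, {}),
                ]
            )
        )
        assert s.mutagenic_fraction == 0.5
        assert s.mutagenic_fraction_all_reads == 0.4

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            summarize_sample([])

    def test_permutation_invariance(self):
        reads = _reads(
            [(RepairClass.WILDTYPE, 10, {}), (RepairClass.DELETION, 5, DEL),
             (RepairClass.SNV, 3, {})]
        )
        a = summarize_sample(reads)
        b = summarize_sample(list(reversed(reads)))
        assert a.class_counts == b.class_counts
        assert a.mutagenic_fraction == b.mutagenic_fraction
        assert a.mh_histogram == b.mh_histogram


class TestNormalization:
    def test_self_normalization_is_one(self):
        s = summarize_sample(
            _reads([(RepairClass.WILDTYPE, 50, {}), (RepairClass.DELETION, 50, DEL)])
        )
        assert normalize_to_control(s, s) == 1.0

    def test_ratio(self):
        lo = summarize_sample(
            _reads([(RepairClass.WILDTYPE, 90, {}), (RepairClass.DELETION, 10, DEL)])
        )
        hi = summarize_sample(
            _reads([(RepairClass.WILDTYPE, 60, {}), (RepairClass.DELETION, 40, DEL)])
        )
        assert normalize_to_control(lo, hi) == pytest.approx(0.25)

    def test_zero_control_rejected(self):
        wt = summarize_sample(_reads([(RepairClass.WILDTYPE, 10, {})]))
        with pytest.raises(NormalizationError):
            normalize_to_control(wt, wt)


class TestDeletionTypes:
    def test_all_zero_mh(self):
        reads = _reads([(RepairClass.DELETION, 4, DEL)])
        assert deletion_type_distribution(reads) == {"0": 1.0}

    def test_default_binning(self):
        reads = []
        for i, mh in enumerate([0, 0, 2, 7]):
            reads.append(
                ClassifiedRead(
                    read_id=f"r{i}", repair_class=RepairClass.DELETION,
                    del_start=100, del_end=110, mh_len=mh,
                )
            )
        assert deletion_type_distribution(reads) == {"0": 0.5, "2": 0.25, "6-10": 0.25}

    def test_no_deletions_gives_empty_map(self):
        assert deletion_type_distribution(_reads([(RepairClass.SNV, 5, {})])) == {}

    def test_bad_bins_rejected(self):
        with pytest.raises(ValueError):
            deletion_type_distribution([], bins=(("0", 0, 0), ("2+", 2, math.inf)))


class TestRepairScore:
    def test_identity(self):
        c = ReporterCounts(80, 100, 20, 100)
        assert repair_score(c, c) == 1.0

    def test_ratio_of_ratios(self):
        test = ReporterCounts(20, 100, 40, 100)
        control = ReporterCounts(80, 100, 20, 100)
        assert repair_score(test, control) == pytest.approx(0.125)

    def test_zero_ssa_rejected(self):
        test = ReporterCounts(20, 100, 10, 100)
        control = ReporterCounts(80, 100, 0, 100)
        with pytest.raises(NormalizationError):
            repair_score(test, control)

    def test_delta_method_se_positive_and_scales(self):
        small = ReporterCounts(8, 10, 2, 10)
        big = ReporterCounts(800, 1000, 200, 1000)
        se_small = repair_score_se(small, small)
        se_big = repair_score_se(big, big)
        assert se_small > se_big > 0


counts = st.integers(min_value=1, max_value=500)


@given(counts, counts, counts, counts)
def test_repair_score_identity_property(a, b, c, d):
    """Any valid population scored against itself gives exactly 1."""
    rc = ReporterCounts(min(a, b), max(a, b), min(c, d), max(c, d))
    assert repair_score(rc, rc) == 1.0


class TestTornado:
    def test_single_event(self):
        recs = make_tornado(_reads([(RepairClass.DELETION, 1, DEL)]))
        assert len(recs) == 1 and recs[0].rank == 0 and recs[0].event_size == 10

    def test_sorted_by_size_descending(self):
        reads = []
        for i, size in enumerate([3, 12, 7]):
            reads.append(
                ClassifiedRead(
                    read_id=f"r{i}", repair_class=RepairClass.DELETION,
                    del_start=100, del_end=100 + size, mh_len=0,
                )
            )
        recs = make_tornado(reads)
        assert [r.event_size for r in recs] == [12, 7, 3]
        assert [r.rank for r in recs] == [0, 1, 2]

    def test_empty_without_mutagenic_events(self):
        assert make_tornado(_reads([(RepairClass.WILDTYPE, 5, {})])) == []

    def test_ranks_are_permutation_and_reproducible(self):
        reads = _reads(
            [(RepairClass.DELETION, 6, DEL),
             (RepairClass.INSERTION, 3, {"ins_len": 4}),
             (RepairClass.WILDTYPE, 4, {})]
        )
        a = make_tornado(reads)
        b = make_tornado(list(reversed(reads)))
        assert sorted(r.rank for r in a) == list(range(9))
        assert [(r.repair_class, r.event_size) for r in a] == [
            (r.repair_class, r.event_size) for r in b
        ]
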
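"""Interval arithmetic and CNV identity semantics."""

import pytest
from hypothesis import given, settings, strategies as st

from pedcnvseg.core import (
    CNVCall,
    GenomicInterval,
    interval_length,
    intersect_all,
    is_same_cnv,
    overlap_bp,
    same_locus,
)

from oracles import overlap_by_counting


def iv(chrom, start, end):
    return GenomicInterval(chrom, start, end)


class TestIntervalLength:
    @pytest.mark.parametrize(
        "interval,expected",
        [
            (("1", 45408389, 45411073), 2684),
            (("7", 8144894, 8497305), 352411),
            (("3", 100, 100), 0),
        ],
    )
    def test_span_between_outermost_probes(self, interval, expected):
        assert interval_length(iv(*interval)) == expected

    def test_reversed_boundaries_rejected(self):
        with pytest.raises(ValueError):
            iv("1", 200, 100)

    def test_chrom_normalization(self):
        assert iv("chr1", 1, 2) == iv("1", 1, 2)
        assert iv("CHRX", 1, 2).chrom == "X"


class TestOverlap:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            (("1", 100, 200), ("1", 100, 200), 100),
            (("1", 100, 200), ("2", 100, 200), 0),
            (("1", 100, 200), ("1", 150, 250), 50),
            (("1", 100, 200), ("1", 300, 400), 0),
        ],
    )
    def test_examples(self, a, b, expected):
        assert overlap_bp(iv(*a), iv(*b)) == expected

    small = st.tuples(
        st.integers(0, 1000), st.integers(0, 1000)
    ).map(lambda t: iv("1", min(t), max(t)))

    @settings(derandomize=True, max_examples=300)
    @given(a=small, b=small)
    def test_matches_position_counting_oracle(self, a, b):
        assert overlap_bp(a, b) == overlap_by_counting(a, b)
        assert overlap_bp(a, b) == overlap_bp(b, a)


class TestIntersectAll:
    def test_single_interval_is_identity(self):
        assert intersect_all([iv("1", 10, 20)]) == iv("1", 10, 20)

    def test_pairwise(self):
        assert intersect_all([iv("1", 100, 300), iv("1", 200, 400)]) == iv("1", 200, 300)

    def test_disjoint_is_empty(self):
        assert intersect_all([iv("1", 100, 200), iv("1", 300, 400)]) is None

    def test_mixed_chromosomes_rejected(self):
        with pytest.raises(ValueError):
            intersect_all([iv("1", 1, 2), iv("2", 1, 2)])

    @settings(derandomize=True, max_examples=200)
    @given(
        st.lists(
            st.tuples(st.integers(0, 500), st.integers(1, 500)).map(
                lambda t: iv("5", t[0], t[0] + t[1])
            ),
            min_size=1,
            max_size=6,
        )
    )
    def test_never_longer_than_shortest_member(self, intervals):
        result = intersect_all(intervals)
        shortest = min(interval_length(x) for x in intervals)
        if result is not None:
            assert interval_length(result) <= shortest


def call(chrom, start, end, cn=1, sample="s"):
    return CNVCall(sample, iv(chrom, start, end), cn, num_snps=5)


class TestSameCNV:
    def test_reflexive_for_identical_records(self):
        a = call("1", 100, 200, cn=1)
        assert is_same_cnv(a, a)

    def test_type_must_match(self):
        assert not is_same_cnv(call("1", 100, 200, cn=1), call("1", 100, 200, cn=3))

    def test_reciprocal_requires_both_fractions(self):
        # overlap 50 bp: 50% of the first, only 25% of the second
        a, b = call("1", 100, 200), call("1", 150, 350)
        assert not is_same_cnv(a, b)
        assert not is_same_cnv(b, a)
        # 'either' mode accepts the same pair
        assert is_same_cnv(a, b, mode="either")

    def test_boundary_fraction_inclusive(self):
        # overlap exactly half of both lengths
        a, b = call("1", 100, 200), call("1", 150, 250)
        assert is_same_cnv(a, b)

    def test_zero_length_operand_rejected(self):
        with pytest.raises(ValueError):
            same_locus(iv("1", 5, 5), "del", iv("1", 1, 9), "del")

    @settings(derandomize=True, max_examples=200)
    @given(
        a=st.tuples(st.integers(0, 400), st.integers(1, 200)),
        b=st.tuples(st.integers(0, 400), st.integers(1, 200)),
    )
    def test_symmetric(self, a, b):
        x = call("2", a[0], a[0] + a[1])
        y = call("2", b[0], b[0] + b[1])
        assert is_same_cnv(x, y) == is_same_cnv(y, x)


class TestCNVCall:
    def test_diploid_copy_number_unrepresentable(self):
        with pytest.raises(ValueError):
            call("1", 1, 10, cn=2)

    @pytest.mark.parametrize("cn,ctype", [(0, "del"), (1, "del"), (3, "dup"), (4, "dup")])
    def test_type_derived_from_copy_number(self, cn, ctype):
        assert call("1", 1, 10, cn=cn).cnv_type == ctype
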
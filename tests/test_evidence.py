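import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from endofilter.evidence import (
    PositionalBiasResult,
    UncallableVariantError,
    VariantReadEvidence,
    classify_read_allele,
    collect_evidence,
    exact_ks_permutation_pvalue,
    offset_histogram,
    positional_bias,
    query_offset,
    soft_clip_ratio,
)
from endofilter.io import ReadAlignment, VariantCall

from helpers import ks_permutation_oracle, offset_oracle, random_read


def read_of(cigar, ref_start=0, seq=None):
    qlen = sum(n for op, n in cigar if op in "MIS=X")
    return ReadAlignment(seq or "A" * qlen, ref_start, tuple(cigar))


class TestQueryOffset:
    def test_identity_alignment(self):
        assert query_offset(read_of([("M", 100)], 1000), 1010) == 10

    def test_leading_soft_clip_shifts_query(self):
        assert query_offset(read_of([("S", 5), ("M", 95)], 1000), 1000) == 5

    def test_position_inside_deletion_is_none(self):
        assert query_offset(read_of([("M", 50), ("D", 10), ("M", 50)], 0), 55) is None

    def test_outside_span_raises(self):
        read = read_of([("M", 50)], 100)
        with pytest.raises(ValueError):
            query_offset(read, 99)
        with pytest.raises(ValueError):
            query_offset(read, 150)

    def test_matches_expansion_oracle_on_fuzzed_cigars(self, rng):
        for _ in range(2000):
            read = random_read(rng)
            span = read.ref_end - read.ref_start
            if span == 0:
                continue
            pos = read.ref_start + int(rng.integers(0, span))
            assert query_offset(read, pos) == offset_oracle(read, pos)


class TestClassifyAllele:
    snv = VariantCall("chr1", 11, "A", "T", "S")  # pos0 = 10

    def test_snv_alleles(self):
        seq_alt = "C" * 10 + "T" + "C" * 89
        seq_ref = "C" * 10 + "A" + "C" * 89
        seq_other = "C" * 10 + "G" + "C" * 89
        assert classify_read_allele(read_of([("M", 100)], 0, seq_alt), self.snv) == "alt"
        assert classify_read_allele(read_of([("M", 100)], 0, seq_ref), self.snv) == "ref"
        assert classify_read_allele(read_of([("M", 100)], 0, seq_other), self.snv) == "other"

    def test_snv_in_deletion_is_other(self):
        read = read_of([("M", 5), ("D", 10), ("M", 95)], 0)
        assert classify_read_allele(read, self.snv) == "other"

    def test_insertion_detection(self):
        ins = VariantCall("chr1", 11, "A", "AGG", "S")
        with_ins = read_of([("M", 11), ("I", 2), ("M", 87)], 0)
        without = read_of([("M", 100)], 0)
        wrong_len = read_of([("M", 11), ("I", 3), ("M", 86)], 0)
        assert classify_read_allele(with_ins, ins) == "alt"
        assert classify_read_allele(without, ins) == "ref"
        # an adjacent insertion of the wrong length supports neither allele
        assert classify_read_allele(wrong_len, ins) == "other"

    def test_deletion_detection(self):
        dele = VariantCall("chr1", 11, "AGG", "A", "S")
        with_del = read_of([("M", 11), ("D", 2), ("M", 89)], 0)
        without = read_of([("M", 100)], 0)
        assert classify_read_allele(with_del, dele) == "alt"
        assert classify_read_allele(without, dele) == "ref"


class TestCollectEvidence:
    snv = VariantCall("chr1", 11, "A", "T", "S")

    def _alt_read(self, cigar=(("M", 100),)):
        qlen = sum(n for op, n in cigar if op in "MIS=X")
        seq = "C" * 100
        # place T at the query offset of ref pos 10
        read = ReadAlignment(seq[:qlen], 0, tuple(cigar))
        off = query_offset(read, 10)
        s = list(read.query_seq)
        s[off] = "T"
        return ReadAlignment("".join(s), 0, tuple(cigar))

    def test_soft_clip_counting(self):
        reads = [self._alt_read() for _ in range(5)]
        reads += [self._alt_read((("S", 20), ("M", 80))) for _ in range(5)]
        ev = collect_evidence(reads, self.snv)
        assert ev.n_alt == 10 and ev.n_alt_softclipped == 5
        assert soft_clip_ratio(ev) == 0.5

    def test_hard_clip_not_soft(self):
        reads = [self._alt_read((("H", 20), ("M", 100)))]
        ev = collect_evidence(reads, self.snv)
        assert ev.n_alt_softclipped == 0

    def test_no_alt_reads_is_uncallable(self):
        ref_read = ReadAlignment("C" * 10 + "A" + "C" * 89, 0, (("M", 100),))
        with pytest.raises(UncallableVariantError):
            collect_evidence([ref_read], self.snv)

    def test_ratio_extremes(self):
        reads = [self._alt_read() for _ in range(10)]
        assert soft_clip_ratio(collect_evidence(reads, self.snv)) == 0.0
        clipped = [self._alt_read((("S", 20), ("M", 80))) for _ in range(10)]
        assert soft_clip_ratio(collect_evidence(clipped, self.snv)) == 1.0


def evidence_from(alt, ref, read_len=100):
    ev = VariantReadEvidence(VariantCall("chr1", 1, "A", "T", "S"))
    ev.alt_offsets = list(alt)
    ev.alt_read_lens = [read_len] * len(alt)
    ev.ref_offsets = list(ref)
    ev.ref_read_lens = [read_len] * len(ref)
    return ev


class TestPositionalBias:
    def test_identical_samples_no_bias(self):
        r = positional_bias(evidence_from([1, 2, 3], [1, 2, 3]), "raw_offset")
        assert r.ks_D == 0.0 and r.ks_p == 1.0 and r.evaluable

    def test_small_sample_convention(self):
        r = positional_bias(evidence_from([1, 2], [5, 6, 7, 8]))
        assert not r.evaluable and r.ks_p == 1.0

    def test_exact_p_equals_permutation_oracle(self, rng):
        # the spec's worked case: 3 vs 5 disjoint samples, C(8,3)=56 assignments
        r = positional_bias(evidence_from([1, 2, 3], [40, 41, 42, 43, 44]), "raw_offset")
        assert r.ks_p == pytest.approx(
            ks_permutation_oracle([1, 2, 3], [40, 41, 42, 43, 44]), abs=1e-12
        )
        for _ in range(40):
            n1, n2 = int(rng.integers(3, 6)), int(rng.integers(3, 6))
            x = list(rng.integers(0, 5, size=n1))
            y = list(rng.integers(0, 5, size=n2))
            assert exact_ks_permutation_pvalue(x, y) == pytest.approx(
                ks_permutation_oracle(x, y), abs=1e-12
            )

    def test_symmetry_under_sample_swap(self, rng):
        x = list(rng.integers(0, 20, size=8))
        y = list(rng.integers(0, 20, size=6))
        a = positional_bias(evidence_from(x, y), "raw_offset")
        b = positional_bias(evidence_from(y, x), "raw_offset")
        assert a.ks_p == pytest.approx(b.ks_p) and a.ks_D == pytest.approx(b.ks_D)

    @given(
        x=st.lists(st.integers(0, 99), min_size=3, max_size=12),
        y=st.lists(st.integers(0, 99), min_size=3, max_size=12),
    )
    @settings(deadline=None, max_examples=60, derandomize=True)
    def test_p_and_d_in_unit_interval(self, x, y):
        r = positional_bias(evidence_from(x, y), "raw_offset")
        assert 0.0 <= r.ks_p <= 1.0 and 0.0 <= r.ks_D <= 1.0

    def test_end_fold_transform(self):
        # offsets near opposite edges fold to the same distance
        ev = evidence_from([10, 89], [10, 89, 10, 89], read_len=100)
        r = positional_bias(ev, "distance_to_nearest_end")
        assert r.ks_D == 0.0 and r.ks_p == 1.0

    def test_asymptotic_branch_used_above_limit(self):
        ev = evidence_from(list(range(0, 300, 2)), list(range(1, 301, 2)), read_len=400)
        r = positional_bias(ev, "raw_offset", exact_limit=100)
        assert 0.0 <= r.ks_p <= 1.0


class TestOffsetHistogram:
    def test_first_bin_collects_low_offsets(self):
        edges, alt, ref = offset_histogram(evidence_from([0, 1, 2, 3, 4], []), bin_width=5)
        assert alt[0] == 5 and alt[1:].sum() == 0

    def test_empty_offsets_all_zero(self):
        edges, alt, ref = offset_histogram(evidence_from([], []))
        assert alt.sum() == 0 and ref.sum() == 0

    def test_conservation(self, rng):
        a = list(rng.integers(0, 100, size=37))
        r = list(rng.integers(0, 100, size=21))
        _, alt, ref = offset_histogram(evidence_from(a, r))
        assert alt.sum() == 37 and ref.sum() == 21

    def test_soft_clip_ratio_read_order_invariant(self, rng):
        ev1 = evidence_from([1, 2, 3], [])
        ev1.n_alt_softclipped = 2
        assert soft_clip_ratio(ev1) == pytest.approx(2 / 3)
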
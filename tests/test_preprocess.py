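"""Read treatments: trimming rules, whole-read filtering, pair bookkeeping."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from trimscope.preprocess import (
    CATEGORIES,
    apply_category,
    apply_category_paired,
    apply_to_read,
    filter_low_quality_fraction,
    find_adapter_start,
    synchronize_pairs,
    trim_adapter_3prime,
    trim_quality_3prime,
)

from conftest import make_read


class TestQualityTrim:
    def test_no_base_below_threshold_unchanged(self):
        read = make_read([30] * 40)
        assert trim_quality_3prime(read, 20) is read

    def test_trimmed_below_min_length_discarded(self):
        read = make_read([30] * 35 + [10] * 5)
        assert trim_quality_3prime(read, 20, min_length=36) is None

    def test_stops_at_first_good_base_keeps_internal_low(self):
        read = make_read([30, 19, 30, 19])
        out = trim_quality_3prime(read, 20)
        assert list(out.qualities) == [30, 19, 30]

    def test_boundary_quality_kept(self):
        # "below 20" is strict: a base at exactly Q20 stops the trim
        read = make_read([30, 20, 19])
        assert list(trim_quality_3prime(read, 20).qualities) == [30, 20]

    def test_all_bad_discarded(self):
        assert trim_quality_3prime(make_read([5] * 10), 20) is None

    def test_five_prime_untouched_and_lengths_consistent(self):
        read = make_read([30] * 20 + [5] * 10, sequence="ACGTG" * 6)
        out = trim_quality_3prime(read, 20)
        assert out.sequence == read.sequence[:20]
        assert len(out.sequence) == len(out.qualities)


class TestFractionFilter:
    def test_discard_when_more_than_threshold_bad(self):
        assert not filter_low_quality_fraction(make_read([5] * 9 + [30]), 10, 0.8)

    def test_exact_threshold_kept(self):
        # 8/10 bad is not *more than* 80%
        assert filter_low_quality_fraction(make_read([5] * 8 + [30] * 2), 10, 0.8)

    def test_all_good_kept(self):
        assert filter_low_quality_fraction(make_read([30] * 10), 10, 0.8)

    def test_zero_length_discarded(self):
        assert not filter_low_quality_fraction(make_read([]), 10, 0.8)


ADAPTER = "AGATCGGAAGAGC"


class TestAdapterTrim:
    def test_insert_plus_full_adapter(self):
        insert = "ACGTACGTACGTACGTACGT"
        read = make_read([30] * (len(insert) + len(ADAPTER)), insert + ADAPTER)
        assert trim_adapter_3prime(read, ADAPTER).sequence == insert

    def test_no_adapter_unchanged(self):
        read = make_read([30] * 20, "ACGTACGTACGTACGTACGT")
        assert trim_adapter_3prime(read, ADAPTER) is read

    def test_partial_terminal_adapter_removed(self):
        insert = "CCCCCCCCCCCCCCC"
        read = make_read([30] * 20, insert + ADAPTER[:5])
        out = trim_adapter_3prime(read, ADAPTER, min_overlap=3)
        assert out.sequence == insert

    def test_matches_brute_force_scan(self):
        # independent oracle: try every suffix position, count mismatches
        rng = np.random.default_rng(0)
        for _ in range(200):
            n = int(rng.integers(10, 60))
            seq = "".join("ACGT"[i] for i in rng.integers(0, 4, n))
            expected = None
            for p in range(n - 3 + 1):
                ov = min(n - p, len(ADAPTER))
                mm = sum(a != b for a, b in zip(seq[p : p + ov], ADAPTER[:ov]))
                if mm <= int(0.1 * ov):
                    expected = p
                    break
            assert find_adapter_start(seq, ADAPTER, 3, 0.1) == expected


class TestCategories:
    def test_untrimmed_is_identity(self):
        reads = [make_read([5] * 50, rid=f"r{i}") for i in range(4)]
        out, stats = apply_category(reads, "untrimmed")
        assert out == reads
        assert stats.retained_reads == stats.input_reads == 4

    def test_category_five_keeps_adapter_free_long_reads(self):
        reads = [make_read([30] * 50, "ACGTG" * 10, rid=f"r{i}") for i in range(3)]
        out, _ = apply_category(reads, "five", adapter=ADAPTER)
        assert len(out) == 3

    def test_category_six_applies_no_length_filter(self):
        # 10 bp read, all good bases: fraction filter keeps it despite len<36
        read = make_read([30] * 10)
        assert apply_to_read(read, CATEGORIES["six"]) is read

    def test_retention_monotone_in_quality_threshold(self):
        rng = np.random.default_rng(1)
        reads = [
            make_read(rng.integers(2, 41, 100), rid=f"r{i}") for i in range(300)
        ]
        out_q20, _ = apply_category(reads, "one")
        out_q10, _ = apply_category(reads, "two")
        assert len(out_q10) >= len(out_q20)
        # per-read: the Q10 survivor is always at least as long
        q20 = {r.id: len(r) for r in out_q20}
        q10 = {r.id: len(r) for r in out_q10}
        assert set(q20) <= set(q10)
        assert all(q10[rid] >= q20[rid] for rid in q20)

    def test_adapter_before_quality_trim_composition(self):
        insert = "C" * 40
        seq = insert + ADAPTER
        quals = [30] * 40 + [10] * len(ADAPTER)
        read = make_read(quals, seq)
        # category three: adapter first (removes 13 bases), then Q20 (no-op)
        out = apply_to_read(read, CATEGORIES["three"], adapter=ADAPTER)
        assert out.sequence == insert

    def test_unknown_category_errors(self):
        with pytest.raises(KeyError):
            apply_category([], "seven")

    def test_sequence_quality_lockstep(self):
        rng = np.random.default_rng(2)
        for cat in ("one", "two", "three", "four", "five", "six"):
            reads = [
                make_read(rng.integers(2, 41, 100),
                          "".join("ACGT"[i] for i in rng.integers(0, 4, 100)),
                          rid=f"r{i}")
                for i in range(50)
            ]
            out, _ = apply_category(reads, cat, adapter=ADAPTER)
            assert all(len(r.sequence) == len(r.qualities) for r in out)

    def test_deterministic(self):
        rng = np.random.default_rng(3)
        reads = [make_read(rng.integers(2, 41, 100), rid=f"r{i}") for i in range(100)]
        a, _ = apply_category(reads, "one")
        b, _ = apply_category(reads, "one")
        assert a == b


class TestPairs:
    def p(self, i, mate, quals):
        return make_read(quals, rid=f"r{i}/{mate}", mate=mate)

    def test_both_survive_one_pair(self):
        pairs, singles = synchronize_pairs(
            [self.p(0, 1, [30] * 40)], [self.p(0, 2, [30] * 40)]
        )
        assert len(pairs) == 1 and not singles

    def test_one_discarded_yields_singleton(self):
        pairs, singles = synchronize_pairs([self.p(0, 1, [30] * 40)], [None])
        assert not pairs and [s.id for s in singles] == ["r0/1"]

    def test_id_mismatch_fatal(self):
        with pytest.raises(ValueError, match="mismatch"):
            synchronize_pairs([self.p(0, 1, [30] * 4)], [self.p(1, 2, [30] * 4)])

    def test_read_accounting_identity(self):
        rng = np.random.default_rng(4)
        n = 200
        r1 = [self.p(i, 1, rng.integers(2, 41, 100)) for i in range(n)]
        r2 = [self.p(i, 2, rng.integers(2, 41, 100)) for i in range(n)]
        pairs, singles, stats = apply_category_paired(r1, r2, "one")
        discarded = stats.input_reads - stats.retained_reads
        assert 2 * n == 2 * len(pairs) + len(singles) + discarded
        assert stats.retained_pairs == len(pairs)
        assert stats.singletons == len(singles)
        assert stats.bases_out <= stats.bases_in
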
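from __future__ import annotations

import random

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from srna_profiler.align import Alignment
from srna_profiler.annotate import AnnotationRecord
from srna_profiler.profile import (
    aggregate_by_subtype,
    build_profile,
    classify_tsrna,
    merge_cca_profiles,
    subtype_expression,
)
from srna_profiler.refdb import ReferenceSet


def aln(ref_id, start, end, query=None):
    return Alignment(query or "A" * (end - start + 1), ref_id, start, end, "+")


def record(ref_hits, count=1, category="rsRNA"):
    hits = [aln(r, s, e) for r, s, e in ref_hits]
    return AnnotationRecord("A" * 20, count, "MG", category, "x", hits)


class TestClassifyTsrna:
    L = 76

    @pytest.mark.parametrize(
        "start,end,has_cca,expected",
        [
            (1, 33, False, "five_prime"),
            (1, 33, True, "five_prime"),
            (58, 79, True, "three_prime_CCA"),
            (45, 76, False, "three_prime"),
            (45, 76, True, "three_prime"),  # ends at L, not reaching into CCA
            (20, 50, False, "internal"),
            (1, 76, False, "five_prime"),  # whole precursor: 5' wins
            (1, 79, True, "five_prime"),
        ],
    )
    def test_boundary_classes(self, start, end, has_cca, expected):
        assert classify_tsrna(aln("t", start, end), self.L, has_cca) == expected

    def test_corrupt_alignment_rejected(self):
        with pytest.raises(ValueError):
            classify_tsrna(aln("t", 70, 80), self.L, has_CCA_ref=False)

    @given(
        start=st.integers(min_value=1, max_value=76),
        length=st.integers(min_value=1, max_value=79),
        has_cca=st.booleans(),
    )
    def test_every_valid_alignment_gets_exactly_one_class(self, start, length, has_cca):
        end = start + length - 1
        ref_len = self.L + 3 if has_cca else self.L
        if end > ref_len:
            return
        cls = classify_tsrna(aln("t", start, end), self.L, has_cca)
        assert cls in ("five_prime", "three_prime", "three_prime_CCA", "internal")

    def test_tolerance_loosens_terminal_boundaries(self):
        near_three_prime = aln("t", 45, self.L - 2)
        assert classify_tsrna(near_three_prime, self.L, False) == "internal"
        assert classify_tsrna(near_three_prime, self.L, False, tolerance=2) == "three_prime"


class TestBuildProfile:
    refset = ReferenceSet(
        "rRNA",
        [("28S_a", "A" * 20), ("28S_b", "A" * 20), ("18S_c", "A" * 30)],
        {"28S_a": "28S", "28S_b": "28S", "18S_c": "18S"},
    )

    def test_single_hit_rpm_arithmetic(self):
        profiles = build_profile(
            [record([("28S_a", 3, 7)], count=5)], self.refset, 10**6
        )
        cov = {p.ref_id: p.coverage for p in profiles}
        assert np.allclose(cov["28S_a"][2:7], 5.0)
        assert cov["28S_a"][:2].sum() == cov["28S_a"][7:].sum() == 0
        assert cov["28S_b"].sum() == 0

    def test_uniform_split_halves_weight_across_two_hits(self):
        rec = record([("28S_a", 3, 7), ("28S_b", 3, 7)], count=5)
        profiles = build_profile([rec], self.refset, 10**6, "uniform_split")
        cov = {p.ref_id: p.coverage for p in profiles}
        assert np.allclose(cov["28S_a"][2:7], 2.5)
        assert np.allclose(cov["28S_b"][2:7], 2.5)
        counted = build_profile([rec], self.refset, 10**6, "count_each")
        assert np.allclose({p.ref_id: p for p in counted}["28S_a"].coverage[2:7], 5.0)

    def test_coverage_equals_independent_tally(self):
        rng = random.Random(31)
        records, tally = [], {rid: np.zeros(len(s)) for rid, s in self.refset.entries}
        for _ in range(50):
            rid, seq = self.refset.entries[rng.randrange(3)]
            start = rng.randint(1, len(seq) - 10)
            end = start + rng.randint(5, 9)
            count = rng.randint(1, 4)
            records.append(record([(rid, start, end)], count=count))
            tally[rid][start - 1 : end] += count  # RPM at 1e6 total == count
        profiles = build_profile(records, self.refset, 10**6)
        for prof in profiles:
            assert np.allclose(prof.coverage, tally[prof.ref_id])

    def test_order_invariance_and_conservation(self):
        rng = random.Random(13)
        records = [
            record([("18S_c", rng.randint(1, 20), rng.randint(21, 30))], count=rng.randint(1, 5))
            for _ in range(20)
        ]
        total = 1000
        fwd = build_profile(records, self.refset, total)
        rev = build_profile(records[::-1], self.refset, total)
        for a, b in zip(fwd, rev):
            assert np.array_equal(a.coverage, b.coverage)
        category_rpm = sum(r.count for r in records) / total * 1e6
        assert sum(p.total_rpm for p in fwd) == pytest.approx(category_rpm)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            build_profile([], self.refset, 0)
        with pytest.raises(ValueError):
            build_profile([], self.refset, 10, "bestof")


class TestSubtypeExpression:
    def test_groups_and_conserves(self):
        profiles = build_profile(
            [
                record([("28S_a", 1, 5)], count=10),
                record([("28S_b", 1, 5)], count=5),
                record([("18S_c", 1, 5)], count=7),
            ],
            TestBuildProfile.refset,
            10**6,
        )
        table = subtype_expression(profiles)
        got = dict(zip(table.subtype, table.rpm))
        assert got == {"28S": 15.0, "18S": 7.0}
        assert table.rpm.sum() == pytest.approx(sum(p.total_rpm for p in profiles))

    def test_empty_input(self):
        table = subtype_expression([])
        assert list(table.columns) == ["subtype", "rpm"] and len(table) == 0


class TestAggregation:
    def test_isoacceptor_copies_padded_to_longest(self):
        refset = ReferenceSet(
            "tRNA",
            [("t1", "A" * 70), ("t2", "A" * 76)],
            {"t1": "Gly-GCC", "t2": "Gly-GCC"},
        )
        profiles = build_profile(
            [record([("t1", 1, 70)], count=2), record([("t2", 71, 76)], count=1)],
            refset,
            10**6,
            "uniform_split",
        )
        (merged,) = aggregate_by_subtype(profiles)
        assert merged.length == 76
        assert np.allclose(merged.coverage[:70], 2.0)
        assert np.allclose(merged.coverage[70:76], 1.0)
        assert merged.total_rpm == pytest.approx(3.0)

    def test_cca_profile_folds_into_mature_id(self):
        profiles = [
            p
            for refset in (
                ReferenceSet("tRNA", [("t1", "A" * 70)], {"t1": "Gly-GCC"}),
                ReferenceSet("tRNA_CCA", [("t1_CCA", "A" * 73)], {"t1_CCA": "Gly-GCC"}),
            )
            for p in build_profile(
                [
                    record([("t1", 1, 20)], count=4),
                    record([("t1_CCA", 51, 73)], count=2),
                ],
                refset,
                10**6,
            )
        ]
        (merged,) = merge_cca_profiles(profiles)
        assert merged.ref_id == "t1" and merged.length == 73
        assert np.allclose(merged.coverage[:20], 4.0)
        assert np.allclose(merged.coverage[50:73], 2.0)
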
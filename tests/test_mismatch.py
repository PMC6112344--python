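from __future__ import annotations

import random
from fractions import Fraction

import numpy as np
import pytest

from helpers import exact_binomial_cdf
from srna_profiler.align import Alignment
from srna_profiler.annotate import AnnotationRecord
from srna_profiler.mismatch import (
    MismatchConfig,
    MismatchSite,
    binomial_pvalue,
    call_sites,
    category_mismatch_stats,
    pile_mismatches,
)
from srna_profiler.preprocess import UniqueSequence
from srna_profiler.refdb import ReferenceSet


class TestBinomialPvalue:
    def test_no_mismatches_gives_one(self):
        assert binomial_pvalue(50, 50, 0.001) == 1.0

    def test_all_mismatches_closed_form(self):
        assert binomial_pvalue(0, 10, 0.01) == pytest.approx(0.01**10, rel=1e-15)

    def test_against_exact_term_summation(self):
        got = binomial_pvalue(8, 10, 0.01)
        want = float(exact_binomial_cdf(8, 10, Fraction(1, 100)))
        assert got == pytest.approx(want, rel=1e-12)

    def test_monotone_in_mismatch_count(self):
        pvals = [binomial_pvalue(100 - n_mut, 100, 0.001) for n_mut in range(0, 101)]
        assert all(a >= b for a, b in zip(pvals, pvals[1:]))

    def test_fractional_counts_rounded_half_up(self):
        assert binomial_pvalue(7.5, 10.2, 0.01) == binomial_pvalue(8, 10, 0.01)

    def test_invalid_p_err_rejected(self):
        with pytest.raises(ValueError):
            binomial_pvalue(1, 2, 0.0)


def make_pairs(ref_seq, specs):
    """specs: (sequence, count, [(start, [(pos, read_base)])...]) on one ref."""
    pairs = []
    for seq, count, placements in specs:
        useq = UniqueSequence(seq, count)
        for start, mm in placements:
            mismatches = tuple(
                (pos, ref_seq[pos - 1], read_base) for pos, read_base in mm
            )
            pairs.append(
                (
                    useq,
                    Alignment(seq, "r", start, start + len(seq) - 1, "+", mismatches),
                )
            )
    return pairs


class TestPileMismatches:
    refset = ReferenceSet("rRNA", [("r", "ACGTACGTACGTACGTACGT")])
    ref_seq = "ACGTACGTACGTACGTACGT"

    def test_uniform_adjusted_distributes_count_over_hits(self):
        # count 6, 3 placements, one mismatching position per placement
        specs = [("ACGTA", 6, [(1, [(3, "T")]), (5, [(7, "T")]), (9, [(11, "T")])])]
        sites = pile_mismatches(make_pairs(self.ref_seq, specs), self.refset, "uniform_adjusted")
        assert all(s.n_mut == pytest.approx(2.0) for s in sites)
        assert len(sites) == 3

    def test_raw_counts_full_weight_everywhere(self):
        specs = [("ACGTA", 6, [(1, [(3, "T")]), (5, [(7, "T")]), (9, [(11, "T")])])]
        sites = pile_mismatches(make_pairs(self.ref_seq, specs), self.refset, "raw")
        assert all(s.n_mut == pytest.approx(6.0) for s in sites)

    def test_raw_never_below_uniform_adjusted(self):
        rng = random.Random(4)
        specs = []
        for i in range(30):
            start = rng.randint(1, 15)
            n_hits = rng.randint(1, 3)
            placements = []
            for _ in range(n_hits):
                pos = start + rng.randrange(5)
                alt = rng.choice([b for b in "ACGT" if b != self.ref_seq[pos - 1]])
                placements.append((start, [(pos, alt)]))
            specs.append((f"SEQ{i}", rng.randint(1, 9), placements))
        pairs = make_pairs(self.ref_seq, specs)
        raw = {(s.ref_id, s.position, s.alt_base): s.n_mut
               for s in pile_mismatches(pairs, self.refset, "raw")}
        adj = pile_mismatches(pairs, self.refset, "uniform_adjusted")
        assert raw.keys() == {(s.ref_id, s.position, s.alt_base) for s in adj}
        for s in adj:
            assert raw[(s.ref_id, s.position, s.alt_base)] >= s.n_mut - 1e-12

    def test_uniform_weights_sum_to_sequence_count(self):
        # one sequence, count 7, 3 hits each mismatching at a distinct site
        specs = [("ACGTA", 7, [(1, [(3, "T")]), (5, [(7, "T")]), (9, [(11, "T")])])]
        sites = pile_mismatches(
            make_pairs(self.ref_seq, specs), self.refset, "uniform_adjusted"
        )
        assert sum(s.n_mut for s in sites) == pytest.approx(7)

    def test_planted_fraction_recovered_by_recount(self):
        rng = random.Random(8)
        alt = "A" if self.ref_seq[9] != "A" else "C"
        seqs: set[str] = set()
        while len(seqs) < 100:
            seqs.add("".join(rng.choices("ACGT", k=8)))
        specs = []
        n_mut_expected = 0
        for seq in sorted(seqs):
            mutated = rng.random() < 0.3
            mm = [(10, alt)] if mutated else []
            specs.append((seq, 1, [(6, mm)]))  # spans positions 6-13
            n_mut_expected += 1 if mutated else 0
        sites = pile_mismatches(make_pairs(self.ref_seq, specs), self.refset, "raw")
        site = {(s.position, s.alt_base): s for s in sites}[(10, alt)]
        assert site.n_mut == pytest.approx(n_mut_expected)
        assert site.n_tot == pytest.approx(100)

    def test_out_of_range_alignment_rejected(self):
        useq = UniqueSequence("ACGTACGTACGTACGTACGTACGT", 1)
        aln = Alignment(useq.sequence, "r", 5, 28, "+")
        with pytest.raises(ValueError):
            pile_mismatches([(useq, aln)], self.refset)


class TestCallSites:
    def test_low_coverage_sites_excluded(self):
        sites = [
            MismatchSite("r", 5, "A", "G", n_ref=3, n_mut=2),
            MismatchSite("r", 9, "A", "G", n_ref=30, n_mut=20),
        ]
        called = call_sites(sites, MismatchConfig(min_coverage=10, correction="none"))
        assert [s.position for s in called] == [9]

    def test_planted_modification_clearly_significant(self):
        site = MismatchSite("r", 5, "A", "G", n_ref=35, n_mut=15)
        (called,) = call_sites([site], MismatchConfig(p_err=0.001, correction="bh"))
        assert called.significant
        assert called.p_value < 1e-20

    def test_null_rejection_rate_matches_alpha(self):
        # 2000 sites simulated at exactly the base-calling error rate
        rng = np.random.default_rng(1234)
        n, p_err, alpha = 50, 0.001, 0.05
        n_mut = rng.binomial(n, p_err, size=2000)
        sites = [
            MismatchSite("r", i + 1, "A", "G", n_ref=float(n - k), n_mut=float(k))
            for i, k in enumerate(n_mut)
        ]
        called = call_sites(
            sites, MismatchConfig(p_err=p_err, alpha=alpha, min_coverage=1, correction="none")
        )
        rate = np.mean([s.significant for s in called])
        se = np.sqrt(alpha * (1 - alpha) / 2000)
        assert abs(rate - alpha) <= 3 * se


class TestCategoryStats:
    def test_percentage_arithmetic(self):
        records = [
            AnnotationRecord(f"S{i}", 1, "MG", "miRNA", "m", []) for i in range(200)
        ]
        sig = [MismatchSite("r", 5, "A", "G", 30, 20, significant=True)]
        hit = Alignment("S0", "r", 1, 10, "+", ((5, "A", "G"),))
        records[0].hits = [hit]
        for i in range(1, 10):
            records[i].hits = [Alignment(f"S{i}", "r", 1, 10, "+", ((5, "A", "G"),))]
        table = category_mismatch_stats(records, sig)
        row = table[table.category == "miRNA"].iloc[0]
        assert (row.EMS, row.TUS, row.percentage) == (10, 200, 5.0)

    def test_no_significant_sites_gives_zero_percentages(self):
        records = [AnnotationRecord("S", 1, "MG", "rsRNA", "28S", [])]
        table = category_mismatch_stats(records, [])
        assert (table.percentage == 0).all()

    def test_tsrna_modifications_dominate_ems(self, tmp_path):
        """Modifications planted only in tRNAs: tsRNA EMS percentage greatest."""
        import pandas as pd

        from conftest import make_fixture_with_mods
        from srna_profiler.report import RunConfig, run_pipeline

        trna_id = "tRNA-Gly-GCC-1-1"
        fx = make_fixture_with_mods(
            tmp_path, seed=23, mod_targets=[(trna_id, 5, 0.4)],
            n_trna=2, reads_per_source=120,
        )
        out = run_pipeline(
            RunConfig(
                input_path=str(fx.fastq),
                bundle_path=str(fx.bundle_manifest),
                out_dir=str(tmp_path / "out"),
            )
        )
        stats = pd.read_csv(out / "mismatch" / "category_stats.tsv", sep="\t")
        stats = stats.set_index("category").percentage
        assert stats["tsRNA"] > 0
        assert all(
            stats["tsRNA"] > stats[c] for c in stats.index if c != "tsRNA"
        )
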
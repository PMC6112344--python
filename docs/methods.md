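# Methods

## Pre-processing

Reads are normalized (uppercase, U→T — annotation operates in DNA space
against DNA references) before any filter is applied. The 3' adapter is
removed by scanning every placement of the adapter prefix against a 3'
suffix of the read and trimming at the leftmost placement with overlap
≥ `min_overlap` (default 6) and mismatch fraction ≤ `max_error_rate`
(default 0.1); a read with no qualifying placement is kept unchanged.
Reads outside the length window (default 15–45 nt, covering miRNA through
tsRNA/rsRNA size classes) or containing bases outside {A,C,G,T} after
normalization are discarded and counted. Base qualities are carried
through but never used for filtering or trimming. Identical reads collapse
into unique sequences sorted by descending count then sequence, so the
collapsed output is independent of input order. The clean-read total — the
RPM denominator everywhere — satisfies
`n_clean = n_input − n_discarded_length − n_discarded_alphabet`
and equals the sum of collapsed counts; the pipeline asserts this at run
time, not only in tests. Malformed FASTQ records (quality/sequence length
mismatch, bad header or separator) are rejected and counted rather than
aborting the run.

## Alignment

The matcher reports *every* ungapped placement of a query on either strand
of a reference set with at most `m ∈ {0,1,2}` substitutions, mirroring
Bowtie's `-v`/`-a` mode (no indels, optional best-stratum filter).
Candidate placements come from pigeonhole seeding: the query is cut into
`m + 1` disjoint chunks, at least one of which must be exact in any
placement with ≤ m mismatches. Chunks at least as long as the index k-mer
size (default 12) are located through the exact k-mer multimap; shorter
chunks (short queries at m = 2) fall back to a direct substring scan,
preserving full sensitivity. Each candidate diagonal is then verified by
Hamming comparison over the whole query. Minus-strand placements
reverse-complement the query into reference orientation before mismatches
are recorded, so mismatch triples `(ref_pos, ref_base, read_base)` are
always in reference coordinates. An `N` in a reference never matches any
read base. Queries shorter than the seed length return no hits and bump a
warning counter. The implementation is validated against an exhaustive
sliding-window scan (every offset, both strands) over randomized queries;
multi-mapping placements are always all retained — downstream modules own
multi-mapper weighting.

## Hierarchical annotation

Reference sets are queried in a configurable order, by default
miRNA > rRNA > tRNA > piRNA > other ncRNA; the first set with ≥ 1 hit
fixes the category and its entry subtypes (rRNA precursor subtype parsed
from headers like `28S_…`, tRNA isoacceptor like `Gly-GCC`) fill the
detail field; sets with no subtype scheme fall back to the entry id. The
tRNA step searches the genomic tRNA set and a derived mature set with
`CCA` appended to every entry, as one category: the CCA is added
enzymatically and is absent from genomic sequence, so CCA-spanning
fragments are only discoverable on the mature set. tRNA intron removal is
not performed; mature (intronless) tRNA FASTA input is assumed.

The genome-match flag (MG/UMG; NA when no genome set is supplied) is
computed independently of the category and never gates annotation. This
decoupling is what recovers rsRNAs from rDNA units absent from genome
assemblies and 3'CCA tsRNAs, both of which are UMG yet genuinely
rRNA-/tRNA-derived.

The annotation run uses one alignment policy throughout; the pipeline
default is `m = 1`, which both tolerates a single modification-induced
mismatch during category assignment and produces the mismatch pileups the
modification caller consumes. With `m = 0` a heavily modified fragment
would fall out of its category before its mismatch could be counted.

## Profiles and tsRNA classes

Each annotated sequence contributes `count / n_clean × 10⁶` RPM,
distributed over its retained hits: `uniform_split` (default) divides by
the number of hits, conserving total RPM exactly — subtype sums equal
category totals — while `count_each` adds full weight at every hit for
comparison. For tRNAs the genomic and CCA-appended entries are profiled as
one combined set so that a fragment hitting both copies of the same gene
splits its weight between them before the two coordinate systems (which
agree on positions 1..L) are folded together; gene copies of one
isoacceptor are then summed position-wise, padding to the longest copy.

Derivation-locus classes use exact boundary equality on the mature length
L: `five_prime` iff start = 1; `three_prime_CCA` iff the placement is on
the CCA reference and ends at L + 3; `three_prime` iff it ends at L (not
reaching into CCA); otherwise `internal`; for a read spanning an entire
tiny precursor 5' takes precedence. Real 5'/3' ends are ragged, so a
`--terminal-tolerance` (default 0 nt) widens the terminal tests; the
default keeps classification exact on synthetic data.

## Modification-site calling

For every (reference, position, alternate base) with observed mismatches,
`n_mut` accumulates the weights of mismatching sequences and `n_ref` the
weights of sequences covering the position with the reference base.
Weights are the read count (`raw`) or the read count divided by the
sequence's number of hits (`uniform_adjusted`, default — a multi-mapper's
evidence is split across its loci on the assumption they express equally,
so `raw` n_mut ≥ adjusted n_mut everywhere and raw inflates false
positives). The p-value is the binomial CDF
`P(X ≤ n_ref), X ~ Binomial(n_tot, 1 − p_err)`, evaluated through the
incomplete-beta form with exact closed forms at the boundaries
(`p = 1` at `n_ref = n_tot`; `p_err^n_tot` at `n_ref = 0`). Fractional
(uniform-split) counts are rounded half-up to integers first, since the
binomial is defined on integers. Sites with rounded `n_tot` below
`min_coverage` (default 10) are not tested. Corrected q-values
(Benjamini–Hochberg by default; Bonferroni or none available) are
thresholded at `alpha` (default 0.05). Defaults `p_err = 0.001` (Phred 30)
and the calling thresholds are deliberate choices exposed as flags, not
constants of the method. EMS/TUS tables count, per category, the unique
sequences carrying ≥ 1 significant site against all unique sequences.

## Synthetic data generator

The generator emulates an adapter-trimmed sRNA-seq library over a toy
genome: mature miRNAs (20–24 nt), genomic tRNAs (70–90 nt) with
isoacceptor-style names, rRNA precursors (120–160 nt) tagged 5.8S/18S/28S,
piRNAs (26–31 nt), other ncRNA (60–100 nt), and reads of 18–35 nt drawn
from them, plus a few random unannotated reads. Ground truth is made exact
by construction: no 15-mer (on either strand) is shared between any two
reference sequences, or repeated within one, so every ≥ 15 nt read
identifies its source unambiguously; a configurable fraction (default 0.5)
of rRNA precursors is left out of the genome to plant UMG rsRNAs; the
three genome bases after each embedded tRNA are forced to differ from CCA
at every position so 3'CCA fragments stay UMG even at m = 1; tsRNA class
counts follow largest-remainder apportionment of the requested mix
(default 0.4/0.2/0.2/0.2 for 5'/3'/3'CCA/internal); reads from a reference
with a planted modification site are drawn as windows covering the site,
and each such read mismatches there with the planted probability;
uniform sequencing errors (default rate 0) spare the terminal bases of
terminal-class tsRNA reads so boundary classification stays exact at
tolerance 0. Everything is a pure function of the seed.

What the generator does *not* emulate — and what passing tests therefore
do not show about real data: sequence-composition bias, expression
heterogeneity within a category, homology between reference families
(real tRNA isodecoders and rRNA repeats share long exact substrings, so
real multi-mapping is far heavier), quality-score structure, true
modification chemistry, and ragged fragment ends.

## Problem sizes and numerical choices

The bundled study uses a 10 kb genome, 10 tRNAs, 6 rRNA precursors, and
300 reads per source category, which gives every planted modification site
coverage ≥ 50 — ample for the binomial test at a 30% mismatch fraction —
while keeping the suite and the acceptance script in the seconds range.
The alignment oracle comparison runs hundreds of 20-mers against a 5 kb
reference at m ∈ {0,1,2}; the binomial test is checked against exact
rational-arithmetic CDF summation on a grid up to n_tot = 200 at relative
tolerance 1e−12, and its type-I error on 2 000 simulated null sites at
coverage 50 and p_err = 0.001 (a regime where the discreteness of the
binomial still leaves the uncorrected rejection rate near the nominal
0.05). Output tables are written with fixed six-decimal formatting so
repeated runs are byte-identical.

## Known limitations

No gapped alignment or quality-aware error model; no probabilistic
reassignment of multi-mappers across categories (the first-hit hierarchy
is winner-take-all); no anticodon-loop-aware tRNA-half calling; no novel
sRNA discovery; the internal aligner targets desk-scale references, not
genome-scale performance parity with Bowtie (large-genome runs would use
an external aligner behind the same interfaces).
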
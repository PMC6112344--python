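"""Read pre-processing: adapter trimming, length/alphabet filtering, collapsing.

Small-RNA libraries are sequenced through the 3' adapter, so the adapter (and
everything downstream of it) must be removed before annotation.  Surviving
reads are filtered to a length window and to the unambiguous nucleotide
alphabet, U is normalized to T (annotation is done in DNA space), and
identical reads are collapsed into unique sequences carrying a read count.
The number of *clean reads* — reads surviving all filters — is the
denominator of every RPM (reads per million clean reads) value downstream.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, TextIO

from Bio import SeqIO

_U_TO_T = str.maketrans("Uu", "Tt")
_DNA = frozenset("ACGT")

DEFAULT_MIN_LENGTH = 15
DEFAULT_MAX_LENGTH = 45
DEFAULT_MIN_OVERLAP = 6
DEFAULT_MAX_ERROR_RATE = 0.1


@dataclass
class RawRead:
    """One sequencing read, possibly with Phred+33 base qualities."""

    read_id: str
    sequence: str
    quality: str | None = None

    def __post_init__(self) -> None:
        if self.quality is not None and len(self.quality) != len(self.sequence):
            raise ValueError(
                f"quality length {len(self.quality)} != sequence length "
                f"{len(self.sequence)} for read {self.read_id!r}"
            )


@dataclass(frozen=True, order=True)
class UniqueSequence:
    """A collapsed read sequence (uppercase DNA) with its read count."""

    sequence: str
    count: int


@dataclass
class PreprocessStats:
    """Bookkeeping for the pre-processing step.

    ``n_clean_reads = n_input_reads - n_discarded_length - n_discarded_alphabet``;
    adapter trimming never discards a read by itself.
    """

    n_input_reads: int = 0
    n_adapter_trimmed: int = 0
    n_discarded_length: int = 0
    n_discarded_alphabet: int = 0
    n_clean_reads: int = 0
    n_unique_sequences: int = 0
    n_parse_errors: int = 0


def normalize_sequence(sequence: str) -> str:
    """Uppercase and convert U to T (RNA input accepted, matching is DNA-space)."""
    return sequence.translate(_U_TO_T).upper()


def trim_adapter(
    read: RawRead,
    adapter: str,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    max_error_rate: float = DEFAULT_MAX_ERROR_RATE,
) -> RawRead:
    """Remove a 3' adapter and everything after it.

    Every placement of the adapter prefix against a 3' suffix of the read is
    scored; the leftmost placement with overlap >= ``min_overlap`` whose
    mismatch fraction is <= ``max_error_rate`` wins.  If no placement
    qualifies, the read is returned unchanged (no-match is not an error).
    The quality string, when present, is truncated in lockstep.
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    seq = normalize_sequence(read.sequence)
    ada = normalize_sequence(adapter)
    n, m = len(seq), len(ada)
    for start in range(0, n - min_overlap + 1):
        overlap = min(n - start, m)
        if overlap < min_overlap:
            break
        mismatches = sum(
            1 for a, b in zip(seq[start : start + overlap], ada[:overlap]) if a != b
        )
        if mismatches / overlap <= max_error_rate:
            quality = read.quality[:start] if read.quality is not None else None
            return RawRead(read.read_id, read.sequence[:start], quality)
    return read


def clean_reads(
    reads: Iterable[RawRead],
    min_len: int = DEFAULT_MIN_LENGTH,
    max_len: int = DEFAULT_MAX_LENGTH,
    stats: PreprocessStats | None = None,
) -> tuple[list[RawRead], PreprocessStats]:
    """Apply length and alphabet filters; normalize U->T and case first.

    Reads containing any base outside {A,C,G,T} after normalization are
    discarded and counted, as are reads outside ``[min_len, max_len]``.
    An existing ``stats`` (e.g. carrying adapter-trim counts) is updated in
    place and returned.
    """
    if not (1 <= min_len <= max_len):
        raise ValueError(f"invalid length range [{min_len}, {max_len}]")
    stats = stats if stats is not None else PreprocessStats()
    kept: list[RawRead] = []
    for read in reads:
        stats.n_input_reads += 1
        seq = normalize_sequence(read.sequence)
        if not (min_len <= len(seq) <= max_len):
            stats.n_discarded_length += 1
            continue
        if not _DNA.issuperset(seq):
            stats.n_discarded_alphabet += 1
            continue
        kept.append(RawRead(read.read_id, seq, read.quality))
    stats.n_clean_reads += len(kept)
    return kept, stats


def collapse(reads: Iterable[RawRead]) -> list[UniqueSequence]:
    """Collapse cleaned reads into unique sequences.

    Output is sorted by descending count, ties broken lexicographically, so
    the result is independent of input order.
    """
    tally: Counter[str] = Counter(read.sequence for read in reads)
    return [
        UniqueSequence(seq, count)
        for seq, count in sorted(tally.items(), key=lambda kv: (-kv[1], kv[0]))
    ]


def preprocess(
    reads: Iterable[RawRead],
    adapter: str | None = None,
    min_len: int = DEFAULT_MIN_LENGTH,
    max_len: int = DEFAULT_MAX_LENGTH,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    max_error_rate: float = DEFAULT_MAX_ERROR_RATE,
    n_parse_errors: int = 0,
) -> tuple[list[UniqueSequence], PreprocessStats]:
    """Full pre-processing: trim (optional), filter, collapse."""
    stats = PreprocessStats(n_parse_errors=n_parse_errors)
    if adapter:
        trimmed = []
        for read in reads:
            out = trim_adapter(read, adapter, min_overlap, max_error_rate)
            if len(out.sequence) != len(read.sequence):
                stats.n_adapter_trimmed += 1
            trimmed.append(out)
        reads = trimmed
    kept, stats = clean_reads(reads, min_len, max_len, stats)
    uniques = collapse(kept)
    stats.n_unique_sequences = len(uniques)
    return uniques, stats


# ---------------------------------------------------------------------------
# Readers / writers


def read_fastq(path: str | Path) -> tuple[list[RawRead], int]:
    """Read a 4-line Phred+33 FASTQ file.

    Returns ``(reads, n_parse_errors)``.  A record whose quality string does
    not match its sequence length, or whose header/separator lines are
    malformed, is rejected and counted rather than aborting the run.
    """
    reads: list[RawRead] = []
    n_errors = 0
    with open(path) as handle:
        while True:
            header = handle.readline()
            if not header:
                break
            seq = handle.readline().rstrip("\n")
            sep = handle.readline()
            qual = handle.readline().rstrip("\n")
            if not qual and not sep:
                n_errors += 1
                break
            if (
                not header.startswith("@")
                or not sep.startswith("+")
                or len(seq) != len(qual)
                or not seq
            ):
                n_errors += 1
                continue
            reads.append(RawRead(header[1:].rstrip("\n").split()[0], seq, qual))
    return reads, n_errors


def read_fasta_reads(path: str | Path) -> list[RawRead]:
    """Read reads from FASTA (wrapped or unwrapped); no qualities."""
    return [
        RawRead(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")
    ]


def read_collapsed_fasta(path: str | Path) -> list[UniqueSequence]:
    """Read the collapsed-FASTA dialect with headers ``>seq<rank>_x<count>``."""
    uniques = []
    for rec in SeqIO.parse(str(path), "fasta"):
        try:
            count = int(rec.id.rsplit("_x", 1)[1])
        except (IndexError, ValueError) as exc:
            raise ValueError(f"malformed collapsed-FASTA header {rec.id!r}") from exc
        uniques.append(UniqueSequence(normalize_sequence(str(rec.seq)), count))
    return uniques


def write_collapsed_fasta(uniques: Iterable[UniqueSequence], handle: TextIO) -> None:
    for rank, useq in enumerate(uniques, start=1):
        handle.write(f">seq{rank}_x{useq.count}\n{useq.sequence}\n")


def write_collapsed_tsv(uniques: Iterable[UniqueSequence], handle: TextIO) -> None:
    handle.write("sequence\tcount\n")
    for useq in uniques:
        handle.write(f"{useq.sequence}\t{useq.count}\n")
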
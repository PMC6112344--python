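"""Ungapped short-sequence matching against a reference set.

Semantics mirror Bowtie's -v/-a mode: report *every* placement of a query on
either strand with at most ``m`` substitutions (no indels), optionally
keeping only the stratum of placements with the minimum observed mismatch
count.  Sensitivity is guaranteed by pigeonhole seeding: the query is split
into ``m + 1`` disjoint chunks, at least one of which must match exactly in
any placement with <= m mismatches; exact chunk occurrences generate the
candidate diagonals that are then verified in full.

An ``N`` in the reference never matches any read base.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from .refdb import ReferenceSet

DEFAULT_SEED_LENGTH = 12

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Alignment:
    """One ungapped placement of a query on a reference.

    Coordinates are 1-based inclusive on the forward reference strand.  For
    minus-strand placements the query is reverse-complemented into reference
    orientation before mismatches are reported, so ``read_base`` in each
    ``(ref_pos, ref_base, read_base)`` triple is always in reference
    orientation.
    """

    query: str
    ref_id: str
    start: int
    end: int
    strand: str
    mismatches: tuple[tuple[int, str, str], ...] = ()

    @property
    def n_mismatch(self) -> int:
        return len(self.mismatches)


@dataclass(frozen=True)
class AlignmentPolicy:
    """How placements are searched and filtered."""

    max_mismatch: int = 0
    strata: bool = False
    both_strands: bool = True

    def __post_init__(self) -> None:
        if self.max_mismatch not in (0, 1, 2):
            raise ValueError("max_mismatch must be 0, 1 or 2")


class SeedIndex:
    """Exact k-mer multimap over a reference set plus the raw sequences.

    The k-mer map accelerates chunk lookup when a pigeonhole chunk is at
    least ``k`` long; shorter chunks fall back to a direct substring scan of
    the (desk-scale) references.
    """

    def __init__(self, refset: ReferenceSet, k: int = DEFAULT_SEED_LENGTH):
        if k < 4:
            raise ValueError("seed length k must be >= 4")
        self.refset = refset
        self.k = k
        self.ref_ids: list[str] = [ref_id for ref_id, _ in refset.entries]
        self.ref_seqs: list[str] = [seq for _, seq in refset.entries]
        self.n_short_query_warnings = 0
        self._kmers: dict[str, list[tuple[int, int]]] = {}
        for ref_idx, seq in enumerate(self.ref_seqs):
            for off in range(len(seq) - k + 1):
                kmer = seq[off : off + k]
                if "N" in kmer:
                    continue
                self._kmers.setdefault(kmer, []).append((ref_idx, off))

    def _chunk_occurrences(self, chunk: str) -> Iterable[tuple[int, int]]:
        """Yield (ref_idx, offset) of every exact occurrence of ``chunk``."""
        if len(chunk) >= self.k:
            for ref_idx, off in self._kmers.get(chunk[: self.k], ()):
                if self.ref_seqs[ref_idx].startswith(chunk, off):
                    yield ref_idx, off
        else:
            for ref_idx, seq in enumerate(self.ref_seqs):
                off = seq.find(chunk)
                while off != -1:
                    yield ref_idx, off
                    off = seq.find(chunk, off + 1)


def build_index(refset: ReferenceSet, k: int = DEFAULT_SEED_LENGTH) -> SeedIndex:
    """Build the seed index for a reference set (deterministic)."""
    return SeedIndex(refset, k)


def _verify(
    oriented: str, ref_seq: str, start0: int, max_mismatch: int
) -> tuple[tuple[int, str, str], ...] | None:
    """Hamming-check ``oriented`` against ``ref_seq[start0:...]``; N never matches."""
    mismatches = []
    for i, read_base in enumerate(oriented):
        ref_base = ref_seq[start0 + i]
        if ref_base != read_base or ref_base == "N":
            mismatches.append((start0 + i + 1, ref_base, read_base))
            if len(mismatches) > max_mismatch:
                return None
    return tuple(mismatches)


def align_all(
    query: str, index: SeedIndex, policy: AlignmentPolicy = AlignmentPolicy()
) -> list[Alignment]:
    """All placements of ``query`` under ``policy``, sorted by (ref_id, start, strand).

    Queries shorter than the index seed length yield an empty result and
    bump the index's warning counter.
    """
    m = policy.max_mismatch
    if len(query) < index.k:
        index.n_short_query_warnings += 1
        return []
    strands = ("+", "-") if policy.both_strands else ("+",)
    found: dict[tuple[str, int, str], Alignment] = {}
    for strand in strands:
        oriented = query if strand == "+" else reverse_complement(query)
        qlen = len(oriented)
        base = qlen // (m + 1)
        candidates: set[tuple[int, int]] = set()
        for j in range(m + 1):
            lo = j * base
            hi = qlen if j == m else (j + 1) * base
            chunk = oriented[lo:hi]
            for ref_idx, off in index._chunk_occurrences(chunk):
                start0 = off - lo
                if start0 < 0 or start0 + qlen > len(index.ref_seqs[ref_idx]):
                    continue
                candidates.add((ref_idx, start0))
        for ref_idx, start0 in candidates:
            mismatches = _verify(oriented, index.ref_seqs[ref_idx], start0, m)
            if mismatches is None:
                continue
            ref_id = index.ref_ids[ref_idx]
            found[(ref_id, start0 + 1, strand)] = Alignment(
                query=query,
                ref_id=ref_id,
                start=start0 + 1,
                end=start0 + qlen,
                strand=strand,
                mismatches=mismatches,
            )
    hits = sorted(found.values(), key=lambda a: (a.ref_id, a.start, a.strand))
    if policy.strata and hits:
        best = min(a.n_mismatch for a in hits)
        hits = [a for a in hits if a.n_mismatch == best]
    return hits


def write_sam(
    alignments: Iterable[Alignment], refset: ReferenceSet, handle
) -> None:
    """Minimal SAM export (mandatory columns plus the NM tag)."""
    handle.write("@HD\tVN:1.6\tSO:unsorted\n")
    for ref_id, seq in refset.entries:
        handle.write(f"@SQ\tSN:{ref_id}\tLN:{len(seq)}\n")
    for aln in alignments:
        flag = 16 if aln.strand == "-" else 0
        seq = aln.query if aln.strand == "+" else reverse_complement(aln.query)
        handle.write(
            f"{aln.query}\t{flag}\t{aln.ref_id}\t{aln.start}\t255\t"
            f"{len(aln.query)}M\t*\t0\t0\t{seq}\t*\tNM:i:{aln.n_mismatch}\n"
        )
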
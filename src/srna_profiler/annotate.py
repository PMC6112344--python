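"""Hierarchical sequential annotation of unique sequences.

Each unique sequence receives two independent verdicts:

* a genome-match flag — MG (match genome) if it aligns anywhere on the
  genome assembly, UMG (unmatch genome) otherwise, NA if no genome set is
  supplied; and
* a category — the first reference set in the hierarchy (default
  miRNA > rRNA > tRNA > piRNA > other ncRNA) with at least one hit.

The two are deliberately decoupled: rRNA genes are incompletely assembled
in many genomes and mature tRNAs carry a non-genomic 3' CCA, so a sequence
may fail genome matching yet be a genuine rRNA- or tRNA-derived fragment.
UMG sequences are therefore still annotated against every RNA set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .align import Alignment, AlignmentPolicy, SeedIndex, align_all, build_index
from .preprocess import UniqueSequence
from .refdb import DatabaseBundle, ReferenceSet

#: Category assigned when a set wins the hierarchy.
CATEGORY_BY_SET = {
    "miRNA": "miRNA",
    "rRNA": "rsRNA",
    "tRNA": "tsRNA",
    "tRNA_CCA": "tsRNA",
    "piRNA": "piRNA",
    "ncRNA_other": "other_ncRNA",
}

CATEGORIES = ("miRNA", "rsRNA", "tsRNA", "piRNA", "other_ncRNA", "unannotated")


@dataclass
class AnnotationRecord:
    """The annotation verdict for one unique sequence."""

    sequence: str
    count: int
    genome_match: str  # MG | UMG | NA
    category: str
    detail: str
    hits: list[Alignment] = field(default_factory=list)


def _detail_for(hits: list[Alignment], owner: dict[str, ReferenceSet]) -> str:
    """Subtype tags of the hit entries; ref_id when the set has no subtypes."""
    tags = []
    for aln in hits:
        tag = owner[aln.ref_id].subtype(aln.ref_id)
        tags.append(tag if tag != "other" else aln.ref_id)
    return ",".join(sorted(set(tags)))


class Annotator:
    """Caches one seed index per reference set and annotates sequences."""

    def __init__(
        self,
        bundle: DatabaseBundle,
        policy: AlignmentPolicy = AlignmentPolicy(),
        seed_length: int = 12,
    ):
        self.bundle = bundle
        self.policy = policy
        self._indexes: dict[str, SeedIndex] = {
            name: build_index(refset, seed_length)
            for name, refset in bundle.sets.items()
        }
        self._owner: dict[str, ReferenceSet] = {
            ref_id: refset
            for refset in bundle.sets.values()
            for ref_id, _ in refset.entries
        }

    def index(self, name: str) -> SeedIndex:
        return self._indexes[name]

    def hits_in_set(self, sequence: str, name: str) -> list[Alignment]:
        """All hits in one set; the tRNA step searches genomic + CCA sets."""
        hits = []
        names = (name, "tRNA_CCA") if name == "tRNA" and "tRNA_CCA" in self._indexes else (name,)
        for set_name in names:
            hits.extend(align_all(sequence, self._indexes[set_name], self.policy))
        return hits

    def flag_genome(self, sequence: str) -> str:
        if "genome" not in self._indexes:
            return "NA"
        return "MG" if self.hits_in_set(sequence, "genome") else "UMG"

    def annotate_sequence(self, useq: UniqueSequence) -> AnnotationRecord:
        genome_match = self.flag_genome(useq.sequence)
        for name in self.bundle.hierarchy:
            hits = self.hits_in_set(useq.sequence, name)
            if hits:
                return AnnotationRecord(
                    sequence=useq.sequence,
                    count=useq.count,
                    genome_match=genome_match,
                    category=CATEGORY_BY_SET[name],
                    detail=_detail_for(hits, self._owner),
                    hits=hits,
                )
        return AnnotationRecord(
            sequence=useq.sequence,
            count=useq.count,
            genome_match=genome_match,
            category="unannotated",
            detail="",
            hits=[],
        )

    def annotate_sample(self, seqs: list[UniqueSequence]) -> list[AnnotationRecord]:
        return [self.annotate_sequence(useq) for useq in seqs]


# Functional wrappers matching the one-shot use case -------------------------


def flag_genome(
    seq: UniqueSequence, genome: ReferenceSet, policy: AlignmentPolicy = AlignmentPolicy()
) -> str:
    """MG iff the sequence has >= 1 placement on the genome."""
    index = build_index(genome)
    return "MG" if align_all(seq.sequence, index, policy) else "UMG"


def annotate_sequence(
    seq: UniqueSequence, bundle: DatabaseBundle, policy: AlignmentPolicy = AlignmentPolicy()
) -> AnnotationRecord:
    return Annotator(bundle, policy).annotate_sequence(seq)


def annotate_sample(
    seqs: list[UniqueSequence],
    bundle: DatabaseBundle,
    policy: AlignmentPolicy = AlignmentPolicy(),
) -> list[AnnotationRecord]:
    return Annotator(bundle, policy).annotate_sample(seqs)
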
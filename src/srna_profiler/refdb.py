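"""Reference collections for hierarchical annotation.

A :class:`ReferenceSet` holds one FASTA collection (genome, mature miRNAs,
rRNA precursors, genomic tRNAs, piRNAs, other ncRNA) with an optional
per-entry subtype tag parsed from the header: the rRNA precursor subtype
(5S, 5.8S, 18S, 28S, ...) or the tRNA isoacceptor (e.g. Gly-GCC).  A
:class:`DatabaseBundle` is the ordered collection of sets the annotation
hierarchy maps against.

Mature tRNAs carry a 3' CCA that is added enzymatically and is absent from
the genomic tRNA sequence.  :func:`build_mature_trna` derives a CCA-appended
set so that CCA-containing tRNA fragments — which cannot match the genome —
are still recovered.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, TextIO

import yaml
from Bio import SeqIO

SET_NAMES = ("genome", "miRNA", "rRNA", "tRNA", "tRNA_CCA", "piRNA", "ncRNA_other")

DEFAULT_HIERARCHY = ("miRNA", "rRNA", "tRNA", "piRNA", "ncRNA_other")

#: Default header patterns used to pull a subtype tag out of a FASTA id.
DEFAULT_SUBTYPE_PATTERNS = {
    "rRNA": r"(5S|5\.8S|12S|16S|18S|28S|45S)",
    "tRNA": r"([A-Z][a-z]{2}-[A-Za-z]{3})",
}

CCA_SUFFIX = "_CCA"

_REF_ALPHABET = frozenset("ACGTN")
_U_TO_T = str.maketrans("Uu", "Tt")


@dataclass
class ReferenceSet:
    """One named reference collection with optional per-entry subtypes."""

    name: str
    entries: list[tuple[str, str]]
    subtypes: dict[str, str] = field(default_factory=dict)
    id_suffix: str = ""  # suffix appended to ids by build_mature_trna

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for ref_id, seq in self.entries:
            if ref_id in seen:
                raise ValueError(f"duplicate reference id {ref_id!r} in set {self.name!r}")
            seen.add(ref_id)
            if not seq:
                raise ValueError(f"empty sequence for reference {ref_id!r}")
            if not _REF_ALPHABET.issuperset(seq):
                bad = sorted(set(seq) - _REF_ALPHABET)
                raise ValueError(f"reference {ref_id!r} contains non-ACGTN bases {bad}")

    def __len__(self) -> int:
        return len(self.entries)

    def subtype(self, ref_id: str) -> str:
        return self.subtypes.get(ref_id, "other")

    @property
    def sequences(self) -> dict[str, str]:
        return dict(self.entries)


def load_fasta_set(
    path: str | Path,
    name: str,
    subtype_pattern: str | None = None,
) -> ReferenceSet:
    """Load a FASTA reference collection.

    ``subtype_pattern`` is a regex with one capture group applied to each
    header; entries whose header does not match get subtype ``"other"``.
    When omitted, the default pattern for the set name (if any) is used.
    """
    if subtype_pattern is None:
        subtype_pattern = DEFAULT_SUBTYPE_PATTERNS.get(name)
    pattern = re.compile(subtype_pattern) if subtype_pattern else None
    entries: list[tuple[str, str]] = []
    subtypes: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).translate(_U_TO_T).upper()
        entries.append((rec.id, seq))
        if pattern is not None:
            match = pattern.search(rec.description)
            subtypes[rec.id] = match.group(1) if match else "other"
    if not entries:
        raise ValueError(f"no FASTA records in {path}")
    return ReferenceSet(name=name, entries=entries, subtypes=subtypes)


def build_mature_trna(trna_set: ReferenceSet, suffix: str = CCA_SUFFIX) -> ReferenceSet:
    """Derive the CCA-appended mature-tRNA set from genomic tRNAs.

    Ids are preserved with ``suffix`` appended (recorded on the set so the
    original id can be recovered); subtypes (isoacceptors) carry over.
    """
    if trna_set.name != "tRNA":
        raise ValueError(f"expected a tRNA set, got {trna_set.name!r}")
    entries = [(ref_id + suffix, seq + "CCA") for ref_id, seq in trna_set.entries]
    subtypes = {ref_id + suffix: tag for ref_id, tag in trna_set.subtypes.items()}
    return ReferenceSet(name="tRNA_CCA", entries=entries, subtypes=subtypes, id_suffix=suffix)


def strip_cca_suffix(ref_id: str, suffix: str = CCA_SUFFIX) -> str:
    return ref_id[: -len(suffix)] if ref_id.endswith(suffix) else ref_id


def write_fasta(refset: ReferenceSet, handle: TextIO) -> None:
    for ref_id, seq in refset.entries:
        handle.write(f">{ref_id}\n{seq}\n")


@dataclass
class DatabaseBundle:
    """The ordered reference sets the annotation hierarchy maps against.

    The genome set may be absent, in which case the match-genome/unmatch-
    genome flag is reported as NA but RNA-set annotation still proceeds.
    """

    sets: dict[str, ReferenceSet]
    hierarchy: tuple[str, ...] = DEFAULT_HIERARCHY
    provenance: str = ""

    def __post_init__(self) -> None:
        self.hierarchy = tuple(self.hierarchy)
        for name in self.hierarchy:
            if name not in self.sets:
                raise ValueError(f"hierarchy names missing set {name!r}")
        # Mature (CCA) tRNAs are implied by a genomic tRNA set.
        if "tRNA" in self.sets and "tRNA_CCA" not in self.sets:
            self.sets["tRNA_CCA"] = build_mature_trna(self.sets["tRNA"])

    @property
    def genome(self) -> ReferenceSet | None:
        return self.sets.get("genome")


def load_bundle(manifest_path: str | Path) -> DatabaseBundle:
    """Load a YAML bundle manifest.

    Expected layout::

        provenance: free text
        hierarchy: [miRNA, rRNA, tRNA, piRNA, ncRNA_other]   # optional
        sets:
          - {name: genome, path: genome.fa}
          - {name: rRNA, path: rrna.fa, subtype_pattern: '(5S|5\\.8S|18S|28S)'}
          ...

    Paths are resolved relative to the manifest file.
    """
    manifest_path = Path(manifest_path)
    with open(manifest_path) as handle:
        manifest = yaml.safe_load(handle)
    sets: dict[str, ReferenceSet] = {}
    for spec in manifest["sets"]:
        path = manifest_path.parent / spec["path"]
        if not path.exists():
            raise FileNotFoundError(f"reference file missing: {path}")
        refset = load_fasta_set(path, spec["name"], spec.get("subtype_pattern"))
        sets[refset.name] = refset
    hierarchy = tuple(
        manifest.get("hierarchy")
        or [name for name in DEFAULT_HIERARCHY if name in sets]
    )
    return DatabaseBundle(sets=sets, hierarchy=hierarchy, provenance=manifest.get("provenance", ""))


def write_bundle_manifest(
    handle: TextIO,
    set_paths: dict[str, str],
    subtype_patterns: dict[str, str] | None = None,
    hierarchy: Iterable[str] | None = None,
    provenance: str = "",
) -> None:
    doc: dict = {
        "provenance": provenance,
        "sets": [
            {"name": name, "path": path}
            | (
                {"subtype_pattern": subtype_patterns[name]}
                if subtype_patterns and name in subtype_patterns
                else {}
            )
            for name, path in set_paths.items()
        ],
    }
    if hierarchy is not None:
        doc["hierarchy"] = list(hierarchy)
    yaml.safe_dump(doc, handle, sort_keys=False)
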
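"""Derivation-locus classification and positional coverage profiles.

tRNA-derived fragments are classified by where they sit on the mature tRNA:
5' terminus (start at position 1), 3' CCA end (reaching the final A of the
enzymatically added CCA), 3' terminus (ending at the last genomic base,
not reaching into CCA), or internal.  rRNA- and tRNA-derived reads are also
accumulated into per-precursor coverage vectors in RPM units, the basis of
the positional "which loci generate these fragments" profiles.

Multi-mapping sequences either split their weight uniformly over their hits
(``uniform_split``, the default — conserves total RPM) or contribute full
weight at every hit (``count_each``, for comparison).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .align import Alignment
from .annotate import AnnotationRecord
from .refdb import ReferenceSet, strip_cca_suffix

TSRNA_CLASSES = ("five_prime", "three_prime", "three_prime_CCA", "internal")

MULTIMAP_POLICIES = ("uniform_split", "count_each")


def classify_tsrna(
    aln: Alignment, mature_len: int, has_CCA_ref: bool, tolerance: int = 0
) -> str:
    """Classify a tRNA-fragment alignment by its derivation locus.

    ``mature_len`` is the intronless tRNA length L; a CCA-appended reference
    is L + 3 long (``has_CCA_ref`` says which reference the alignment is
    on).  Exact boundary equality is the default; ``tolerance`` loosens the
    terminal tests by that many nucleotides for ragged real-data ends.
    Precedence for reads spanning a whole tiny precursor:
    five_prime > three_prime_CCA > three_prime.
    """
    ref_len = mature_len + 3 if has_CCA_ref else mature_len
    if aln.end > ref_len:
        raise ValueError(
            f"alignment end {aln.end} beyond reference length {ref_len} ({aln.ref_id})"
        )
    if aln.start <= 1 + tolerance:
        return "five_prime"
    if has_CCA_ref and aln.end >= mature_len + 3 - tolerance:
        return "three_prime_CCA"
    if mature_len - tolerance <= aln.end <= mature_len:
        return "three_prime"
    return "internal"


@dataclass
class PrecursorProfile:
    """Per-position weighted coverage (RPM) along one precursor."""

    ref_id: str
    subtype: str
    length: int
    coverage: np.ndarray
    total_rpm: float = 0.0

    @classmethod
    def empty(cls, ref_id: str, subtype: str, length: int) -> "PrecursorProfile":
        return cls(ref_id, subtype, length, np.zeros(length, dtype=float))


def build_profile(
    records: list[AnnotationRecord],
    refset: ReferenceSet,
    total_clean_reads: int,
    multimap_policy: str = "uniform_split",
) -> list[PrecursorProfile]:
    """Accumulate per-precursor coverage from one category's records.

    Each sequence contributes ``count / total_clean_reads * 1e6`` RPM,
    distributed over its hits on references in ``refset`` per the multimap
    policy, added to ``coverage[start..end]`` of each hit precursor.
    Profiles are returned for every reference in the set (order preserved),
    including unhit ones with all-zero coverage.
    """
    if total_clean_reads <= 0:
        raise ValueError("total_clean_reads must be > 0")
    if multimap_policy not in MULTIMAP_POLICIES:
        raise ValueError(f"unknown multimap policy {multimap_policy!r}")
    profiles = {
        ref_id: PrecursorProfile.empty(ref_id, refset.subtype(ref_id), len(seq))
        for ref_id, seq in refset.entries
    }
    for record in records:
        hits = [aln for aln in record.hits if aln.ref_id in profiles]
        if not hits:
            continue
        rpm = record.count / total_clean_reads * 1e6
        weight = rpm / len(hits) if multimap_policy == "uniform_split" else rpm
        for aln in hits:
            prof = profiles[aln.ref_id]
            prof.coverage[aln.start - 1 : aln.end] += weight
            prof.total_rpm += weight
    return list(profiles.values())


def aggregate_by_subtype(profiles: list[PrecursorProfile]) -> list[PrecursorProfile]:
    """Merge gene-copy profiles sharing one subtype (e.g. tRNA isoacceptor).

    Copies are aligned from position 1; length differences across copies are
    handled by padding to the longest copy.
    """
    merged: dict[str, PrecursorProfile] = {}
    for prof in profiles:
        key = prof.subtype
        if key not in merged:
            merged[key] = PrecursorProfile.empty(key, key, prof.length)
        out = merged[key]
        if prof.length > out.length:
            out.coverage = np.pad(out.coverage, (0, prof.length - out.length))
            out.length = prof.length
        out.coverage[: prof.length] += prof.coverage
        out.total_rpm += prof.total_rpm
    return list(merged.values())


def merge_cca_profiles(
    profiles: list[PrecursorProfile], suffix: str = "_CCA"
) -> list[PrecursorProfile]:
    """Fold genomic-tRNA profiles into their CCA-appended counterparts.

    The CCA reference is 3 nt longer; genomic coordinates map unchanged.
    Returns one profile per mature tRNA, keyed by the original id.
    """
    mature = {
        strip_cca_suffix(p.ref_id, suffix): p
        for p in profiles
        if p.ref_id.endswith(suffix)
    }
    for prof in profiles:
        if prof.ref_id.endswith(suffix):
            continue
        target = mature.get(prof.ref_id)
        if target is None:
            mature[prof.ref_id] = prof
            continue
        target.coverage[: prof.length] += prof.coverage
        target.total_rpm += prof.total_rpm
    out = []
    for ref_id, prof in mature.items():
        prof.ref_id = ref_id
        out.append(prof)
    return out


def subtype_expression(profiles: list[PrecursorProfile]) -> pd.DataFrame:
    """Total RPM per precursor subtype (e.g. 5.8S/18S/28S or isoacceptor)."""
    if not profiles:
        return pd.DataFrame(columns=["subtype", "rpm"])
    df = pd.DataFrame(
        {"subtype": [p.subtype for p in profiles], "rpm": [p.total_rpm for p in profiles]}
    )
    return (
        df.groupby("subtype", as_index=False)["rpm"].sum().sort_values("subtype").reset_index(drop=True)
    )


def profile_table(profiles: list[PrecursorProfile]) -> pd.DataFrame:
    """Long-form (ref_id, subtype, position, rpm) table; positions 1-based."""
    frames = []
    for prof in profiles:
        frames.append(
            pd.DataFrame(
                {
                    "ref_id": prof.ref_id,
                    "subtype": prof.subtype,
                    "position": np.arange(1, prof.length + 1),
                    "rpm": prof.coverage,
                }
            )
        )
    if not frames:
        return pd.DataFrame(columns=["ref_id", "subtype", "position", "rpm"])
    return pd.concat(frames, ignore_index=True)


def write_bedgraph(prof: PrecursorProfile, handle) -> None:
    """bedGraph export; positions convert to 0-based half-open intervals."""
    handle.write(f'track type=bedGraph name="{prof.ref_id}"\n')
    cov = prof.coverage
    start = 0
    for pos in range(1, len(cov) + 1):
        if pos == len(cov) or cov[pos] != cov[start]:
            if cov[start] != 0:
                handle.write(f"{prof.ref_id}\t{start}\t{pos}\t{cov[start]:.6g}\n")
            start = pos
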
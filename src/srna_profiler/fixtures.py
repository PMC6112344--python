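"""Deterministic synthetic data with known ground truth.

The generator emits a toy genome, a reference bundle (mature miRNAs, rRNA
precursors with subtype-tagged headers, genomic tRNAs with isoacceptor
names, piRNAs, other ncRNA), a FASTQ read set drawn from those references,
and a per-read ground-truth table, so every pipeline stage is testable
without downloading anything.

Design points that make the ground truth exact:

* references are rejection-sampled so no 15-mer (on either strand) is
  shared between any two reference sequences — a read of >= 15 nt from one
  source cannot exactly match another, making category assignment
  unambiguous;
* a chosen fraction of rRNA precursors is excluded from the toy genome,
  emulating rDNA repeats missing from genome assemblies: their reads are
  genuine rRNA fragments yet "unmatch genome" (UMG);
* genomic tRNAs are embedded without the 3' CCA, and the three genome
  bases following each embedded copy are forced to differ from CCA at every
  position, so CCA-carrying tRNA fragments never match the genome even when
  one substitution is allowed;
* reads from a reference carrying a planted modification site are drawn as
  windows covering the site, guaranteeing test coverage at the site;
* tsRNA derivation-locus classes are allocated by exact largest-remainder
  apportionment of the requested mix, so class counts are reproducible
  integers, and sequencing errors are never injected into the terminal
  bases of terminal-class tsRNA reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

_BASES = np.array(list("ACGT"))
_KMER = 15  # cross-reference uniqueness scale, matching the minimum read length

RRNA_SUBTYPES = ("5.8S", "18S", "28S")
ISOACCEPTORS = (
    "Gly-GCC", "Glu-CTC", "Gly-CCC", "Val-CAC", "Lys-CTT", "Lys-TTT",
    "His-GTG", "Ala-AGC", "Asp-GTC", "Ser-GCT", "Leu-CAG", "Pro-AGG",
    "Arg-TCT", "Thr-TGT", "Met-CAT", "Phe-GAA", "Cys-GCA", "Trp-CCA",
    "Ile-AAT", "Tyr-GTA",
)

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _rc(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class FixtureSpec:
    """Parameters of one synthetic study; the seed fully determines output."""

    seed: int = 0
    genome_length: int = 10_000
    n_mirna: int = 10
    n_trna: int = 10
    n_rrna: int = 6
    n_pirna: int = 10
    n_other: int = 5
    n_random_reads: int = 5
    reads_per_source: int = 100
    read_length_range: tuple[int, int] = (18, 35)
    tsrna_class_mix: dict[str, float] = field(
        default_factory=lambda: {
            "five_prime": 0.4,
            "three_prime": 0.2,
            "three_prime_CCA": 0.2,
            "internal": 0.2,
        }
    )
    modification_sites: tuple[tuple[str, int, str, float], ...] = ()
    umg_rrna_fraction: float = 0.5
    error_rate: float = 0.0

    def __post_init__(self) -> None:
        total = sum(self.tsrna_class_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("tsrna_class_mix must sum to 1")
        if not 0.0 <= self.umg_rrna_fraction <= 1.0:
            raise ValueError("umg_rrna_fraction must be in [0, 1]")
        if not 0.0 <= self.error_rate < 1.0:
            raise ValueError("error_rate must be in [0, 1)")


@dataclass
class Fixture:
    """Generated files plus in-memory ground truth."""

    out_dir: Path
    fastq: Path
    bundle_manifest: Path
    ground_truth: pd.DataFrame
    references: dict[str, list[tuple[str, str]]]
    umg_rrna_ids: list[str]


class _KmerRegistry:
    """Rejection sampler guaranteeing no shared 15-mer across sequences."""

    def __init__(self, rng: np.random.Generator):
        self.rng = rng
        self.kmers: set[str] = set()

    def _kmers_of(self, seq: str):
        for i in range(len(seq) - _KMER + 1):
            kmer = seq[i : i + _KMER]
            yield min(kmer, _rc(kmer))

    def new_sequence(self, length: int, max_tries: int = 200) -> str:
        for _ in range(max_tries):
            seq = "".join(self.rng.choice(_BASES, size=length))
            kmers = set(self._kmers_of(seq))
            if len(seq) >= _KMER and not kmers:
                continue
            if kmers & self.kmers or len(kmers) < max(0, length - _KMER + 1):
                continue  # shared or internally repeated 15-mer: resample
            self.kmers |= kmers
            return seq
        raise RuntimeError("could not sample a 15-mer-disjoint sequence")


def _apportion(total: int, fractions: dict[str, float]) -> dict[str, int]:
    """Largest-remainder apportionment of ``total`` over ``fractions``."""
    keys = list(fractions)
    exact = {k: total * fractions[k] for k in keys}
    counts = {k: int(np.floor(exact[k])) for k in keys}
    remainder = total - sum(counts.values())
    order = sorted(keys, key=lambda k: (-(exact[k] - counts[k]), k))
    for k in order[:remainder]:
        counts[k] += 1
    return counts


def _anti_cca(rng: np.random.Generator) -> str:
    """Three bases differing from CCA at every position."""
    return "".join(
        rng.choice([b for b in "ACGT" if b != target]) for target in "CCA"
    )


def generate(spec: FixtureSpec, out_dir: str | Path) -> Fixture:
    """Generate the toy study into ``out_dir``; deterministic in the seed."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    registry = _KmerRegistry(rng)
    lo, hi = spec.read_length_range
    if lo < _KMER:
        raise ValueError(f"read lengths below {_KMER} make ground truth ambiguous")

    refs: dict[str, list[tuple[str, str]]] = {}
    refs["miRNA"] = [
        (f"toy-mir-{i+1}", registry.new_sequence(int(rng.integers(20, 25))))
        for i in range(spec.n_mirna)
    ]
    refs["tRNA"] = [
        (
            f"tRNA-{ISOACCEPTORS[i % len(ISOACCEPTORS)]}-{i // len(ISOACCEPTORS) + 1}-1",
            registry.new_sequence(int(rng.integers(70, 91))),
        )
        for i in range(spec.n_trna)
    ]
    refs["rRNA"] = [
        (
            f"{RRNA_SUBTYPES[i % len(RRNA_SUBTYPES)]}_rRNA_toy_{i+1}",
            registry.new_sequence(int(rng.integers(120, 161))),
        )
        for i in range(spec.n_rrna)
    ]
    refs["piRNA"] = [
        (f"toy-pir-{i+1}", registry.new_sequence(int(rng.integers(26, 32))))
        for i in range(spec.n_pirna)
    ]
    refs["ncRNA_other"] = [
        (f"toy-sno-{i+1}", registry.new_sequence(int(rng.integers(60, 101))))
        for i in range(spec.n_other)
    ]
    if any(hi > len(seq) for _, seq in refs["tRNA"]):
        raise ValueError("tRNA references shorter than the requested read lengths")

    # Genome: all references except a chosen fraction of rRNA entries,
    # embedded in random filler.  tRNAs are followed by an anti-CCA triplet.
    n_umg = int(round(spec.umg_rrna_fraction * spec.n_rrna))
    umg_idx = set(rng.permutation(spec.n_rrna)[:n_umg].tolist())
    umg_rrna_ids = [refs["rRNA"][i][0] for i in sorted(umg_idx)]
    embedded: list[str] = []
    for name in ("miRNA", "piRNA", "ncRNA_other"):
        embedded.extend(seq for _, seq in refs[name])
    embedded.extend(seq + _anti_cca(rng) for _, seq in refs["tRNA"])
    embedded.extend(
        seq for i, (_, seq) in enumerate(refs["rRNA"]) if i not in umg_idx
    )
    total_embedded = sum(len(s) for s in embedded)
    n_gaps = len(embedded) + 1
    filler_total = spec.genome_length - total_embedded
    if filler_total < n_gaps * 5:
        raise ValueError(
            f"genome_length {spec.genome_length} too small for "
            f"{total_embedded} nt of embedded references"
        )
    cuts = np.sort(rng.integers(0, filler_total + 1, size=n_gaps - 1))
    gap_lens = np.diff(np.concatenate([[0], cuts, [filler_total]]))
    order = rng.permutation(len(embedded))
    parts = []
    for gi, idx in enumerate(order):
        parts.append("".join(rng.choice(_BASES, size=int(gap_lens[gi]))))
        parts.append(embedded[idx])
    parts.append("".join(rng.choice(_BASES, size=int(gap_lens[-1]))))
    genome = "".join(parts)
    refs["genome"] = [("toy_chr1", genome)]

    mods_by_ref: dict[str, list[tuple[int, str, float]]] = {}
    ref_seq_by_id = {
        ref_id: seq for entries in refs.values() for ref_id, seq in entries
    }
    for ref_id, pos, alt, frac in spec.modification_sites:
        if ref_id not in ref_seq_by_id or not 1 <= pos <= len(ref_seq_by_id[ref_id]):
            raise ValueError(f"modification site {ref_id}:{pos} outside references")
        if ref_seq_by_id[ref_id][pos - 1] == alt:
            raise ValueError(f"alt base at {ref_id}:{pos} equals the reference base")
        mods_by_ref.setdefault(ref_id, []).append((pos, alt, frac))

    # ---------------- reads ----------------
    truth_rows: list[dict] = []
    fastq_lines: list[str] = []
    read_no = 0

    def emit(seq: str, category: str, ref_id: str, start: int, end: int, tsrna_class: str, protect_ends: bool) -> None:
        nonlocal read_no
        read_no += 1
        covers_mod = False
        if ref_id in mods_by_ref:
            for pos, alt, frac in mods_by_ref[ref_id]:
                if start <= pos <= end:
                    covers_mod = True
                    if rng.random() < frac:
                        i = pos - start
                        seq = seq[:i] + alt + seq[i + 1 :]
        if spec.error_rate > 0:
            protected = {0, len(seq) - 1} if protect_ends else set()
            chars = list(seq)
            for i in range(len(chars)):
                if i in protected:
                    continue
                if rng.random() < spec.error_rate:
                    chars[i] = str(rng.choice([b for b in "ACGT" if b != chars[i]]))
            seq = "".join(chars)
        read_id = f"read_{read_no:06d}"
        fastq_lines.append(f"@{read_id}\n{seq}\n+\n{'I' * len(seq)}\n")
        truth_rows.append(
            {
                "read_id": read_id,
                "category": category,
                "ref_id": ref_id,
                "start": start,
                "end": end,
                "tsrna_class": tsrna_class,
                "covers_mod_site": covers_mod,
            }
        )

    def window(ref_id: str, seq: str) -> tuple[int, int]:
        """A read window; forced to cover a planted site when one exists."""
        length = int(rng.integers(lo, min(hi, len(seq)) + 1))
        if ref_id in mods_by_ref:
            pos, _, _ = mods_by_ref[ref_id][int(rng.integers(len(mods_by_ref[ref_id])))]
            smin = max(1, pos - length + 1)
            smax = min(len(seq) - length + 1, pos)
            start = int(rng.integers(smin, smax + 1))
        else:
            start = int(rng.integers(1, len(seq) - length + 2))
        return start, start + length - 1

    # miRNA / piRNA reads: the full mature sequence (already sRNA-sized).
    for name, category in (("miRNA", "miRNA"), ("piRNA", "piRNA")):
        entries = refs[name]
        for j in range(spec.reads_per_source):
            ref_id, seq = entries[j % len(entries)]
            emit(seq, category, ref_id, 1, len(seq), "", False)

    # rsRNA and other-ncRNA reads: windows of their (longer) precursors.
    for name, category in (("rRNA", "rsRNA"), ("ncRNA_other", "other_ncRNA")):
        entries = refs[name]
        for j in range(spec.reads_per_source):
            ref_id, seq = entries[j % len(entries)]
            start, end = window(ref_id, seq)
            emit(seq[start - 1 : end], category, ref_id, start, end, "", False)

    # tsRNA reads: derivation class by exact apportionment.
    class_counts = _apportion(spec.reads_per_source, spec.tsrna_class_mix)
    class_list = [c for c in ("five_prime", "three_prime", "three_prime_CCA", "internal") for _ in range(class_counts.get(c, 0))]
    for j, cls in enumerate(class_list):
        ref_id, seq = refs["tRNA"][j % len(refs["tRNA"])]
        L = len(seq)
        length = int(rng.integers(lo, hi + 1))
        if cls == "five_prime":
            start, end = 1, length
            read = seq[:length]
        elif cls == "three_prime":
            start, end = L - length + 1, L
            read = seq[start - 1 : L]
        elif cls == "three_prime_CCA":
            mature = seq + "CCA"
            start, end = L + 3 - length + 1, L + 3
            read = mature[start - 1 : L + 3]
        else:  # internal: strictly away from both boundaries
            start = int(rng.integers(2, L - length))
            end = start + length - 1
            read = seq[start - 1 : end]
        protect = cls in ("five_prime", "three_prime", "three_prime_CCA")
        emit(read, "tsRNA", ref_id, start, end, cls, protect)

    # Unannotated reads: random sequences disjoint from every reference.
    for _ in range(spec.n_random_reads):
        length = int(rng.integers(25, 36))
        seq = registry.new_sequence(length)
        emit(seq, "unannotated", "", 0, 0, "", False)

    # ---------------- files ----------------
    fastq_path = out / "reads.fastq"
    fastq_path.write_text("".join(fastq_lines))
    set_files = {
        "genome": "genome.fa",
        "miRNA": "mirna.fa",
        "rRNA": "rrna.fa",
        "tRNA": "trna.fa",
        "piRNA": "pirna.fa",
        "ncRNA_other": "ncrna_other.fa",
    }
    for name, fname in set_files.items():
        with open(out / fname, "w") as handle:
            for ref_id, seq in refs[name]:
                handle.write(f">{ref_id}\n{seq}\n")
    manifest = out / "bundle.yaml"
    from .refdb import DEFAULT_SUBTYPE_PATTERNS, write_bundle_manifest

    with open(manifest, "w") as handle:
        write_bundle_manifest(
            handle,
            set_paths=set_files,
            subtype_patterns=DEFAULT_SUBTYPE_PATTERNS,
            hierarchy=["miRNA", "rRNA", "tRNA", "piRNA", "ncRNA_other"],
            provenance=f"synthetic fixture, seed={spec.seed}",
        )
    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "read_id", "category", "ref_id", "start", "end",
            "tsrna_class", "covers_mod_site",
        ],
    )
    truth.to_csv(out / "ground_truth.tsv", sep="\t", index=False)
    return Fixture(
        out_dir=out,
        fastq=fastq_path,
        bundle_manifest=manifest,
        ground_truth=truth,
        references=refs,
        umg_rrna_ids=umg_rrna_ids,
    )
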
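"""Annotation summary and pipeline orchestration.

``summarize`` turns per-sequence annotation records into the sample-level
tables: category x genome-match composition (unique sequences, reads, RPM)
and per-length RPM distributions.  ``run_pipeline`` chains pre-processing,
hierarchical annotation, tsRNA/rsRNA profiling and mismatch-site calling,
writing a fixed TSV output layout::

    out/
      summary.tsv        category x MG/UMG table
      annotation.tsv     one row per unique sequence
      length_dist.tsv    (category, length, genome_match) -> RPM
      tsrna_profiles/    per-isoacceptor coverage + class table
      rsrna_profiles/    per-precursor coverage + subtype table
      mismatch/          site table + EMS/TUS category summary
      run_log.txt        versions, parameters, input hashes

Re-running with identical inputs produces byte-identical files.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import __version__
from .align import AlignmentPolicy
from .annotate import CATEGORIES, AnnotationRecord, Annotator
from .mismatch import (
    MismatchConfig,
    call_sites,
    category_mismatch_stats,
    pile_mismatches,
    sites_table,
)
from .preprocess import (
    PreprocessStats,
    UniqueSequence,
    preprocess,
    read_collapsed_fasta,
    read_fasta_reads,
    read_fastq,
)
from .profile import (
    aggregate_by_subtype,
    build_profile,
    classify_tsrna,
    merge_cca_profiles,
    profile_table,
    subtype_expression,
)
from .refdb import DatabaseBundle, ReferenceSet, load_bundle, strip_cca_suffix

_FLOAT_FMT = "%.6f"


@dataclass
class SampleSummary:
    """Sample-level annotation summary."""

    stats: PreprocessStats
    category_table: pd.DataFrame  # category, genome_match, n_unique, reads, rpm
    length_table: pd.DataFrame  # category, length, genome_match, rpm
    run_config: dict = field(default_factory=dict)


def summarize(
    records: list[AnnotationRecord],
    stats: PreprocessStats,
    run_config: dict | None = None,
) -> SampleSummary:
    """Build category and length-distribution tables with RPM normalization.

    RPM = reads / n_clean_reads * 1e6, so RPM sums to 1e6 over the whole
    category table.  A mismatch between summed record counts and
    ``stats.n_clean_reads`` indicates an upstream bookkeeping bug and is an
    error.
    """
    total = sum(r.count for r in records)
    if total != stats.n_clean_reads:
        raise ValueError(
            f"record counts sum to {total} but n_clean_reads is {stats.n_clean_reads}"
        )
    rows = []
    if records:
        df = pd.DataFrame(
            {
                "category": pd.Categorical(
                    [r.category for r in records], categories=CATEGORIES
                ),
                "genome_match": [r.genome_match for r in records],
                "length": [len(r.sequence) for r in records],
                "count": [r.count for r in records],
            }
        )
        cat = (
            df.groupby(["category", "genome_match"], observed=True)
            .agg(n_unique=("count", "size"), reads=("count", "sum"))
            .reset_index()
        )
        cat["rpm"] = cat["reads"] / stats.n_clean_reads * 1e6 if stats.n_clean_reads else 0.0
        cat = cat.sort_values(["category", "genome_match"]).reset_index(drop=True)
        length = (
            df.groupby(["category", "length", "genome_match"], observed=True)["count"]
            .sum()
            .reset_index()
        )
        length["rpm"] = (
            length["count"] / stats.n_clean_reads * 1e6 if stats.n_clean_reads else 0.0
        )
        length = (
            length.drop(columns="count")
            .sort_values(["category", "length", "genome_match"])
            .reset_index(drop=True)
        )
    else:
        cat = pd.DataFrame(columns=["category", "genome_match", "n_unique", "reads", "rpm"])
        length = pd.DataFrame(columns=["category", "length", "genome_match", "rpm"])
    cat["category"] = cat["category"].astype(str)
    length["category"] = length["category"].astype(str)
    return SampleSummary(
        stats=stats, category_table=cat, length_table=length, run_config=run_config or {}
    )


@dataclass
class RunConfig:
    """Everything one pipeline run depends on."""

    input_path: str
    bundle_path: str
    out_dir: str
    input_format: str = "fastq"  # fastq | fasta | collapsed
    adapter: str | None = None
    min_length: int = 15
    max_length: int = 45
    max_mismatch: int = 1
    seed_length: int = 12
    multimap_policy: str = "uniform_split"
    terminal_tolerance: int = 0
    skip_mismatch: bool = False
    plots: bool = False
    p_err: float = 0.001
    mismatch_method: str = "uniform_adjusted"
    alpha: float = 0.05
    min_coverage: int = 10
    correction: str = "bh"


def _sha256(path: str | Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as handle:
        for chunk in iter(lambda: handle.read(65536), b""):
            digest.update(chunk)
    return digest.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def load_reads(config: RunConfig):
    """Read input and return (uniques, stats) per the configured format."""
    if config.input_format == "fastq":
        reads, n_parse_errors = read_fastq(config.input_path)
    elif config.input_format == "fasta":
        reads, n_parse_errors = read_fasta_reads(config.input_path), 0
    elif config.input_format == "collapsed":
        uniques = read_collapsed_fasta(config.input_path)
        total = sum(u.count for u in uniques)
        stats = PreprocessStats(
            n_input_reads=total, n_clean_reads=total, n_unique_sequences=len(uniques)
        )
        return uniques, stats
    else:
        raise ValueError(f"unknown input format {config.input_format!r}")
    return preprocess(
        reads,
        adapter=config.adapter,
        min_len=config.min_length,
        max_len=config.max_length,
        n_parse_errors=n_parse_errors,
    )


def run_pipeline(config: RunConfig, bundle: DatabaseBundle | None = None) -> Path:
    """Execute the full pipeline; returns the output directory.

    Outputs are deterministic: identical inputs give byte-identical tables.
    An input that is empty after filtering still yields a complete (zeroed)
    output layout rather than an error.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if bundle is None:
        bundle = load_bundle(config.bundle_path)
    policy = AlignmentPolicy(max_mismatch=config.max_mismatch, both_strands=True)

    uniques, stats = load_reads(config)
    annotator = Annotator(bundle, policy, seed_length=config.seed_length)
    records = annotator.annotate_sample(uniques)
    total = max(stats.n_clean_reads, 1)

    # Per-sequence annotation table.
    ann = pd.DataFrame(
        [
            {
                "sequence": r.sequence,
                "count": r.count,
                "rpm": r.count / total * 1e6,
                "genome_match": r.genome_match,
                "category": r.category,
                "detail": r.detail,
                "n_hits": len(r.hits),
            }
            for r in records
        ],
        columns=["sequence", "count", "rpm", "genome_match", "category", "detail", "n_hits"],
    )
    header = (
        f"# hierarchy: {' > '.join(bundle.hierarchy)}\n"
        f"# policy: max_mismatch={policy.max_mismatch} both_strands={policy.both_strands}\n"
    )
    with open(out / "annotation.tsv", "w") as handle:
        handle.write(header)
        ann.to_csv(handle, sep="\t", index=False, float_format=_FLOAT_FMT)

    summary = summarize(records, stats, asdict(config))
    _write_tsv(summary.category_table, out / "summary.tsv")
    _write_tsv(summary.length_table, out / "length_dist.tsv")

    # rsRNA profiles over rRNA precursors.
    rs_dir = out / "rsrna_profiles"
    rs_dir.mkdir(exist_ok=True)
    rs_records = [r for r in records if r.category == "rsRNA"]
    if "rRNA" in bundle.sets:
        rs_profiles = build_profile(
            rs_records, bundle.sets["rRNA"], total, config.multimap_policy
        )
        _write_tsv(profile_table(rs_profiles), rs_dir / "coverage.tsv")
        _write_tsv(subtype_expression(rs_profiles), rs_dir / "subtype_rpm.tsv")

    # tsRNA profiles: per mature tRNA, merged over CCA status, then by
    # isoacceptor; plus the derivation-locus class table.
    ts_dir = out / "tsrna_profiles"
    ts_dir.mkdir(exist_ok=True)
    ts_records = [r for r in records if r.category == "tsRNA"]
    if "tRNA" in bundle.sets:
        trna_lens = {ref_id: len(seq) for ref_id, seq in bundle.sets["tRNA"].entries}
        cca_set = bundle.sets.get("tRNA_CCA")
        # One combined set so uniform_split sees all tRNA hits of a sequence
        # at once (a 5' fragment hits both the genomic and the CCA copy).
        combined_entries = list(bundle.sets["tRNA"].entries)
        combined_subtypes = dict(bundle.sets["tRNA"].subtypes)
        if cca_set is not None:
            combined_entries += cca_set.entries
            combined_subtypes |= cca_set.subtypes
        combined = ReferenceSet("tRNA", combined_entries, combined_subtypes)
        per_ref = build_profile(ts_records, combined, total, config.multimap_policy)
        merged = merge_cca_profiles(per_ref, cca_set.id_suffix if cca_set else "_CCA")
        iso = aggregate_by_subtype(merged)
        _write_tsv(profile_table(iso), ts_dir / "coverage.tsv")
        _write_tsv(subtype_expression(iso), ts_dir / "isoacceptor_rpm.tsv")
        class_rows = []
        suffix = cca_set.id_suffix if cca_set else "_CCA"
        for r in ts_records:
            aln = r.hits[0]
            mature_id = strip_cca_suffix(aln.ref_id, suffix)
            cls = classify_tsrna(
                aln,
                trna_lens[mature_id],
                has_CCA_ref=aln.ref_id.endswith(suffix),
                tolerance=config.terminal_tolerance,
            )
            class_rows.append(
                {
                    "sequence": r.sequence,
                    "count": r.count,
                    "isoacceptor": r.detail,
                    "tsrna_class": cls,
                }
            )
        _write_tsv(
            pd.DataFrame(
                class_rows, columns=["sequence", "count", "isoacceptor", "tsrna_class"]
            ),
            ts_dir / "classes.tsv",
        )

    # Mismatch-enrichment modification calling at the winning references.
    if not config.skip_mismatch:
        mm_dir = out / "mismatch"
        mm_dir.mkdir(exist_ok=True)
        pairs = []
        aln_by_seq = {}
        for r in records:
            if r.category == "unannotated":
                continue
            for aln in r.hits:
                pairs.append((UniqueSequence(r.sequence, r.count), aln))
            aln_by_seq[r.sequence] = r.hits
        merged_refs = _merged_refset(bundle)
        sites = pile_mismatches(pairs, merged_refs, config.mismatch_method)
        mm_config = MismatchConfig(
            p_err=config.p_err,
            method=config.mismatch_method,
            alpha=config.alpha,
            min_coverage=config.min_coverage,
            correction=config.correction,
        )
        called = call_sites(sites, mm_config)
        _write_tsv(sites_table(called), mm_dir / "sites.tsv")
        stats_df = category_mismatch_stats(records, called, aln_by_seq)
        _write_tsv(stats_df, mm_dir / "category_stats.tsv")

    if config.plots:
        _write_plots(summary, out)

    log = [
        f"srna-profiler {__version__}",
        f"input: {config.input_path} sha256={_sha256(config.input_path)}",
        f"bundle: {config.bundle_path}",
        f"parameters: {asdict(config)}",
        f"stats: {asdict(stats) if hasattr(stats, '__dataclass_fields__') else stats}",
    ]
    if stats.n_clean_reads == 0:
        log.append("warning: no reads survived filtering; outputs are zeroed")
    (out / "run_log.txt").write_text("\n".join(log) + "\n")
    return out


def _merged_refset(bundle: DatabaseBundle):
    """One ReferenceSet view over every non-genome set, for site piling."""
    from .refdb import ReferenceSet

    entries = []
    subtypes = {}
    for name, refset in bundle.sets.items():
        if name == "genome":
            continue
        entries.extend(refset.entries)
        subtypes.update(refset.subtypes)
    return ReferenceSet(name="all_ncRNA", entries=entries, subtypes=subtypes)


def _write_plots(summary: SampleSummary, out: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(11, 4))
    cat = summary.category_table.groupby("category", observed=True)["rpm"].sum()
    if len(cat):
        axes[0].pie(cat.values, labels=cat.index, autopct="%1.1f%%")
    axes[0].set_title("category composition (RPM)")
    for (category, gm), sub in summary.length_table.groupby(
        ["category", "genome_match"], observed=True
    ):
        axes[1].plot(sub["length"], sub["rpm"], label=f"{category}/{gm}")
    axes[1].set_xlabel("length (nt)")
    axes[1].set_ylabel("RPM")
    axes[1].legend(fontsize=6)
    fig.tight_layout()
    fig.savefig(out / "summary.png", dpi=120)
    plt.close(fig)
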
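"""Candidate RNA-modification sites from mismatch-enrichment pileups.

Some RNA modifications perturb reverse transcription and leave a nucleotide
misincorporation signature: at the modified position, an excess of reads
carries a non-reference base.  For every reference position with at least
one observed mismatch we accumulate

* ``n_ref`` — the weighted number of nucleotides perfectly matching the
  reference at the site,
* ``n_mut`` — the weighted number of mismatched nucleotides (per alternate
  base), and ``n_tot = n_ref + n_mut``,

and ask whether the mismatch excess is explained by base-calling error
alone.  Under the null, each nucleotide matches with probability
``1 - p_err``, so the one-sided p-value is the binomial CDF

    p = P(X <= n_ref),  X ~ Binomial(n_tot, 1 - p_err).

Two weighting schemes are provided for multi-mapping sequences: ``raw``
counts a sequence's full read count at every locus it hits (liberal —
inflates false positives), while ``uniform_adjusted`` distributes the read
count uniformly over the loci, assuming each expresses equally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy.stats import binom
from statsmodels.stats.multitest import multipletests

from .align import Alignment
from .annotate import AnnotationRecord
from .preprocess import UniqueSequence
from .refdb import ReferenceSet

METHODS = ("raw", "uniform_adjusted")
CORRECTIONS = ("none", "bonferroni", "bh")


@dataclass
class MismatchSite:
    """Counts and test result at one (reference, position, alternate base)."""

    ref_id: str
    position: int  # 1-based
    ref_base: str
    alt_base: str
    n_ref: float
    n_mut: float
    p_value: float = 1.0
    q_value: float = 1.0
    significant: bool = False

    @property
    def n_tot(self) -> float:
        return self.n_ref + self.n_mut


@dataclass(frozen=True)
class MismatchConfig:
    p_err: float = 0.001  # Phred 30 base-calling error
    method: str = "uniform_adjusted"
    alpha: float = 0.05
    min_coverage: int = 10
    correction: str = "bh"

    def __post_init__(self) -> None:
        if not 0.0 < self.p_err < 1.0:
            raise ValueError("p_err must be in (0, 1)")
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}")
        if self.correction not in CORRECTIONS:
            raise ValueError(f"correction must be one of {CORRECTIONS}")
        if self.min_coverage < 1:
            raise ValueError("min_coverage must be >= 1")


def pile_mismatches(
    alignments: Sequence[tuple[UniqueSequence, Alignment]],
    refset: ReferenceSet,
    method: str = "uniform_adjusted",
) -> list[MismatchSite]:
    """Accumulate weighted match/mismatch counts per reference site.

    ``alignments`` holds every retained hit of every sequence; a sequence's
    weight per hit is its read count (``raw``) or its read count divided by
    its number of hits (``uniform_adjusted``).  Sites are emitted for every
    (ref_id, position, alt_base) with ``n_mut > 0``, sorted by position.
    """
    if method not in METHODS:
        raise ValueError(f"method must be one of {METHODS}")
    sequences = refset.sequences
    n_hits: dict[str, int] = {}
    for useq, _ in alignments:
        n_hits[useq.sequence] = n_hits.get(useq.sequence, 0) + 1
    ref_cover: dict[tuple[str, int], float] = {}
    mut: dict[tuple[str, int, str], float] = {}
    for useq, aln in alignments:
        ref_seq = sequences.get(aln.ref_id)
        if ref_seq is None:
            continue
        if aln.start < 1 or aln.end > len(ref_seq):
            raise ValueError(
                f"alignment {aln.start}-{aln.end} outside reference {aln.ref_id}"
            )
        weight = useq.count if method == "raw" else useq.count / n_hits[useq.sequence]
        mispos = {pos: (ref_b, read_b) for pos, ref_b, read_b in aln.mismatches}
        for pos in range(aln.start, aln.end + 1):
            if pos in mispos:
                ref_b, read_b = mispos[pos]
                mut[(aln.ref_id, pos, read_b)] = (
                    mut.get((aln.ref_id, pos, read_b), 0.0) + weight
                )
            else:
                ref_cover[(aln.ref_id, pos)] = ref_cover.get((aln.ref_id, pos), 0.0) + weight
    sites = [
        MismatchSite(
            ref_id=ref_id,
            position=pos,
            ref_base=sequences[ref_id][pos - 1],
            alt_base=alt,
            n_ref=ref_cover.get((ref_id, pos), 0.0),
            n_mut=n_mut,
        )
        for (ref_id, pos, alt), n_mut in mut.items()
    ]
    sites.sort(key=lambda s: (s.ref_id, s.position, s.alt_base))
    return sites


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def binomial_pvalue(n_ref: float, n_tot: float, p_err: float) -> float:
    """P(X <= n_ref) for X ~ Binomial(n_tot, 1 - p_err).

    Small values mean fewer perfect matches than base-calling error can
    explain, i.e. mismatch enrichment.  Weighted (fractional) counts are
    rounded half-up to integers before evaluation.
    """
    if not 0.0 < p_err < 1.0:
        raise ValueError("p_err must be in (0, 1)")
    k = _round_half_up(n_ref)
    n = _round_half_up(n_tot)
    if n < 1:
        raise ValueError("n_tot must round to >= 1")
    if not 0 <= k <= n:
        raise ValueError(f"need 0 <= n_ref <= n_tot, got {n_ref}, {n_tot}")
    # Closed-form boundary cases avoid any incomplete-beta round-off.
    if k == n:
        return 1.0
    if k == 0:
        return p_err**n
    return float(binom.cdf(k, n, 1.0 - p_err))


def call_sites(
    sites: Iterable[MismatchSite], config: MismatchConfig = MismatchConfig()
) -> list[MismatchSite]:
    """Test piled sites and flag significant mismatch enrichment.

    Sites with (rounded) ``n_tot`` below ``min_coverage`` are excluded from
    testing and from the output.  Multiple-testing correction (per config)
    yields q-values; ``significant`` is set where q <= alpha.  Output sorted
    by (ref_id, position, alt_base).
    """
    tested = [s for s in sites if _round_half_up(s.n_tot) >= config.min_coverage]
    for site in tested:
        site.p_value = binomial_pvalue(site.n_ref, site.n_tot, config.p_err)
    pvals = [s.p_value for s in tested]
    if not pvals:
        return []
    if config.correction == "none":
        qvals = pvals
    elif config.correction == "bonferroni":
        qvals = multipletests(pvals, method="bonferroni")[1]
    else:
        qvals = multipletests(pvals, method="fdr_bh")[1]
    for site, q in zip(tested, qvals):
        site.q_value = float(q)
        site.significant = site.q_value <= config.alpha
    tested.sort(key=lambda s: (s.ref_id, s.position, s.alt_base))
    return tested


def category_mismatch_stats(
    records: Sequence[AnnotationRecord],
    sites: Iterable[MismatchSite],
    alignments_by_sequence: Mapping[str, Sequence[Alignment]] | None = None,
) -> pd.DataFrame:
    """Per-category EMS/TUS table.

    TUS (total unique sequences) counts the unique sequences of a category;
    EMS (enrichment mismatch sequences) counts those carrying >= 1
    significant mismatch site in their alignments.  By default a record's
    own hits are inspected; pass ``alignments_by_sequence`` when mismatch
    analysis ran at a more permissive mismatch ceiling than annotation.
    """
    significant = {
        (s.ref_id, s.position, s.alt_base) for s in sites if s.significant
    }
    rows: dict[str, dict[str, int]] = {}
    for record in records:
        entry = rows.setdefault(record.category, {"EMS": 0, "TUS": 0})
        entry["TUS"] += 1
        hits = (
            alignments_by_sequence.get(record.sequence, record.hits)
            if alignments_by_sequence is not None
            else record.hits
        )
        if any(
            (aln.ref_id, pos, read_b) in significant
            for aln in hits
            for pos, _, read_b in aln.mismatches
        ):
            entry["EMS"] += 1
    df = pd.DataFrame(
        [
            {
                "category": cat,
                "EMS": entry["EMS"],
                "TUS": entry["TUS"],
                "percentage": 100.0 * entry["EMS"] / entry["TUS"] if entry["TUS"] else 0.0,
            }
            for cat, entry in sorted(rows.items())
        ],
        columns=["category", "EMS", "TUS", "percentage"],
    )
    return df


def sites_table(sites: Iterable[MismatchSite]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "ref_id": s.ref_id,
                "position": s.position,
                "ref_base": s.ref_base,
                "alt_base": s.alt_base,
                "n_ref": s.n_ref,
                "n_mut": s.n_mut,
                "n_tot": s.n_tot,
                "p": s.p_value,
                "q": s.q_value,
                "significant": s.significant,
            }
            for s in sites
        ],
        columns=[
            "ref_id", "position", "ref_base", "alt_base",
            "n_ref", "n_mut", "n_tot", "p", "q", "significant",
        ],
    )
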
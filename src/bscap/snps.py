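"""Bisulfite-aware SNP filtering and parent-of-origin read assignment.

In an F1 hybrid the two parental haplotypes (a B73-like parent A and a
Mo17-like parent B) differ at known SNPs, which lets individual reads — and
hence methylation calls — be assigned to a parental allele.  Bisulfite
conversion complicates this: on an original-top-strand (OT) read every
unmethylated C reads as T, so a C/T SNP is indistinguishable on OT reads;
symmetrically a G/A SNP is indistinguishable on original-bottom (OB) reads.
Only SNPs that stay informative on the read's strand are used, and a read is
assigned to a parent only when strictly more than 60% of its informative
SNPs support that parent.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

from .calling import AlignedBsRead, MethylationCall, call_methylation
from .core import GenomeSequence
from .io import SnpRow

logger = logging.getLogger(__name__)

VERDICTS = ("parent_a", "parent_b", "ambiguous", "no_info")


@dataclass(frozen=True)
class SnpRecord:
    contig: str
    pos: int  # 0-based
    allele_a: str  # parent A (B73-like)
    allele_b: str  # parent B (Mo17-like)
    quality: float
    coverage: int
    source: str = "de_novo"  # catalog | de_novo | both

    def __post_init__(self) -> None:
        if self.allele_a == self.allele_b:
            raise ValueError("SNP alleles must differ")
        if self.quality < 0 or self.coverage < 0:
            raise ValueError("quality and coverage must be non-negative")


@dataclass(frozen=True)
class ParentalAssignment:
    read_id: str
    mate: int
    verdict: str
    n_snps: int
    support_fraction: float
    via_mate: bool = False


def snp_from_row(row: SnpRow, source: str = "de_novo") -> SnpRecord:
    return SnpRecord(row.contig, row.pos, row.ref, row.alt,
                     row.quality, row.coverage, source)


def filter_de_novo_snps(
    candidates: Sequence[SnpRecord],
    min_quality: float = 20.0,
    max_coverage: int = 120,
    proximity: int = 20,
) -> list[SnpRecord]:
    """Quality/coverage/proximity filter for de novo SNP calls.

    A candidate survives iff quality >= ``min_quality``, coverage <=
    ``max_coverage`` and no other candidate lies within ``proximity`` bp
    (inclusive; both members of a close pair are removed).  Proximity is
    evaluated over the full candidate list, before the other filters.
    """
    by_contig: dict[str, list[SnpRecord]] = defaultdict(list)
    for c in candidates:
        by_contig[c.contig].append(c)
    crowded: set[tuple[str, int]] = set()
    for contig, snps in by_contig.items():
        snps = sorted(snps, key=lambda s: s.pos)
        for prev, cur in zip(snps, snps[1:]):
            if cur.pos - prev.pos <= proximity:
                crowded.add((contig, prev.pos))
                crowded.add((contig, cur.pos))
    kept = []
    removed = {"quality": 0, "coverage": 0, "proximity": 0}
    for c in candidates:
        if (c.contig, c.pos) in crowded:
            removed["proximity"] += 1
        elif c.quality < min_quality:
            removed["quality"] += 1
        elif c.coverage > max_coverage:
            removed["coverage"] += 1
        else:
            kept.append(c)
    if any(removed.values()):
        logger.info("filter_de_novo_snps removed %s", removed)
    return kept


def intersect_snp_lists(
    catalog: Sequence[SnpRecord], de_novo: Sequence[SnpRecord]
) -> list[SnpRecord]:
    """Consensus SNPs: present in both lists with consistent alleles.

    Allele consistency ignores order (a catalog A/G matches a de novo G/A);
    conflicting allele pairs at a shared position are dropped with a warning.
    """
    cat = {(s.contig, s.pos): s for s in catalog}
    out = []
    for s in de_novo:
        key = (s.contig, s.pos)
        if key not in cat:
            continue
        c = cat[key]
        if {s.allele_a, s.allele_b} != {c.allele_a, c.allele_b}:
            logger.warning(
                "allele conflict at %s:%d (%s/%s vs %s/%s); excluded",
                s.contig, s.pos, c.allele_a, c.allele_b, s.allele_a, s.allele_b,
            )
            continue
        # parental phase follows the catalog
        out.append(replace(c, source="both"))
    return out


def converted_readouts(allele: str, bisulfite_strand: str) -> frozenset[str]:
    """Possible read bases for an allele on a bisulfite strand.

    On OT reads a genomic C reads C (methylated) or T (converted); on OB
    reads, in forward representation, a genomic G reads G or A.  All other
    bases read as themselves.
    """
    if bisulfite_strand == "OT" and allele == "C":
        return frozenset("CT")
    if bisulfite_strand == "OB" and allele == "G":
        return frozenset("GA")
    return frozenset(allele)


def bisulfite_informative(snp: SnpRecord, bisulfite_strand: str) -> bool:
    """True when the two alleles remain distinguishable on this strand."""
    a = converted_readouts(snp.allele_a, bisulfite_strand)
    b = converted_readouts(snp.allele_b, bisulfite_strand)
    return not (a & b)


def assign_read(
    read: AlignedBsRead,
    consensus_snps: Mapping[str, Sequence[SnpRecord]] | Sequence[SnpRecord],
    threshold: float = 0.60,
) -> ParentalAssignment:
    """Assign one read to a parental allele from its informative SNPs.

    With n informative SNPs in the read: n=0 -> no_info; n=1 -> the supported
    parent; n>1 -> the parent supported by strictly more than ``threshold``
    of them, else ambiguous.  Read bases matching neither allele's converted
    readout (sequencing error) do not count as informative observations.
    """
    if isinstance(consensus_snps, Mapping):
        snps = consensus_snps.get(read.contig, ())
    else:
        snps = [s for s in consensus_snps if s.contig == read.contig]
    votes_a = votes_b = 0
    for snp in snps:
        if not (read.start <= snp.pos < read.end):
            continue
        if not bisulfite_informative(snp, read.bisulfite_strand):
            continue
        base = read.query_seq[snp.pos - read.start]
        if base in converted_readouts(snp.allele_a, read.bisulfite_strand):
            votes_a += 1
        elif base in converted_readouts(snp.allele_b, read.bisulfite_strand):
            votes_b += 1
    n = votes_a + votes_b
    if n == 0:
        return ParentalAssignment(read.read_id, read.mate, "no_info", 0, 0.0)
    best, frac = ("parent_a", votes_a / n) if votes_a >= votes_b else ("parent_b", votes_b / n)
    if n == 1 or frac > threshold:
        return ParentalAssignment(read.read_id, read.mate, best, n, frac)
    return ParentalAssignment(read.read_id, read.mate, "ambiguous", n, frac)


def rescue_via_mate(
    assignments: Sequence[ParentalAssignment],
) -> list[ParentalAssignment]:
    """Propagate a mate's parental verdict to a no_info read.

    Ambiguous mates do not propagate; mates with conflicting parental
    verdicts are both demoted to ambiguous (the inconsistency is real
    evidence against a clean assignment).
    """
    by_id: dict[str, list[ParentalAssignment]] = defaultdict(list)
    for a in assignments:
        by_id[a.read_id].append(a)
    out = []
    for a in assignments:
        mates = [m for m in by_id[a.read_id] if m.mate != a.mate]
        mate = mates[0] if mates else None
        if (
            mate is not None
            and a.verdict in ("parent_a", "parent_b")
            and mate.verdict in ("parent_a", "parent_b")
            and mate.verdict != a.verdict
        ):
            out.append(replace(a, verdict="ambiguous"))
        elif (
            a.verdict == "no_info"
            and mate is not None
            and mate.verdict in ("parent_a", "parent_b")
        ):
            out.append(replace(a, verdict=mate.verdict, via_mate=True))
        else:
            out.append(a)
    return out


def split_reads_by_parent(
    reads: Sequence[AlignedBsRead],
    assignments: Sequence[ParentalAssignment],
) -> dict[str, list[AlignedBsRead]]:
    verdict = {(a.read_id, a.mate): a.verdict for a in assignments}
    out: dict[str, list[AlignedBsRead]] = {"parent_a": [], "parent_b": []}
    for r in reads:
        v = verdict.get((r.read_id, r.mate))
        if v in out:
            out[v].append(r)
    return out


@dataclass(frozen=True)
class AllelicRegionSummary:
    contig: str
    start: int
    end: int
    level_a: dict
    level_b: dict
    insufficient: bool


def allelic_methylation(
    reads_by_parent: Mapping[str, Sequence[AlignedBsRead]],
    genome: GenomeSequence,
    regions: Sequence | None = None,
    trim: int = 2,
) -> tuple[dict[str, list[MethylationCall]], list[AllelicRegionSummary]]:
    """Per-parent methylation calls, plus per-region allelic summaries.

    Runs the standard caller separately on each parent's reads; if target
    regions are given, per-context mean levels per parent are summarised and
    regions where either parent has no calls are flagged insufficient.
    """
    calls = {
        parent: call_methylation(rs, genome, trim=trim)
        for parent, rs in reads_by_parent.items()
    }
    summaries: list[AllelicRegionSummary] = []
    if regions:
        for iv in regions:
            levels = {}
            for parent in ("parent_a", "parent_b"):
                per_ctx: dict[str, list[float]] = defaultdict(list)
                for c in calls.get(parent, []):
                    if (c.site.contig == iv.contig and iv.start <= c.site.pos < iv.end
                            and c.level is not None and c.site.context != "edge"):
                        per_ctx[c.site.context].append(c.level)
                levels[parent] = {
                    ctx: sum(v) / len(v) for ctx, v in per_ctx.items()
                }
            summaries.append(
                AllelicRegionSummary(
                    iv.contig, iv.start, iv.end,
                    levels["parent_a"], levels["parent_b"],
                    insufficient=not levels["parent_a"] or not levels["parent_b"],
                )
            )
    return calls, summaries
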
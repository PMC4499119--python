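"""Per-cytosine methylation calling and capture QC metrics.

Reads arrive pre-aligned in a SAM-like tabular dialect with their sequence
stored in reference-forward orientation and a bisulfite-strand tag:

* ``OT`` (original top): at a top-strand cytosine (reference C) the read
  shows C when methylated, T when converted.
* ``OB`` (original bottom): the bottom strand's C->T conversions appear as
  G->A in the forward representation, so at a bottom-strand cytosine
  (reference G) the read shows G when methylated, A when converted.

Calling follows the standard extractor conventions: the first two bases of
each mate are ignored (``trim``), mate overlaps are scored once
(``no_overlap``), and read bases other than the methylated/converted pair at
a cytosine (sequencing error or SNP) are ignored rather than counted as
unmethylated.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, replace
from statistics import median
from typing import Iterable, Mapping, Sequence

import numpy as np
from intervaltree import IntervalTree

from .core import CytosineSite, GenomeSequence, UndefinedRateError, classify_context
from .io import CallRow, Interval


@dataclass(frozen=True)
class AlignedBsRead:
    read_id: str
    mate: int  # 1 or 2
    contig: str
    start: int  # 0-based half-open
    end: int
    bisulfite_strand: str  # 'OT' or 'OB'
    query_seq: str  # reference-forward orientation, no indels
    is_duplicate: bool = False

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("read end must exceed start")
        if self.end - self.start != len(self.query_seq):
            raise ValueError("read span must equal sequence length")
        if self.bisulfite_strand not in ("OT", "OB"):
            raise ValueError(f"bad bisulfite strand {self.bisulfite_strand!r}")


@dataclass(frozen=True)
class MethylationCall:
    site: CytosineSite
    methylated: int
    unmethylated: int

    @property
    def total(self) -> int:
        return self.methylated + self.unmethylated

    @property
    def level(self) -> float | None:
        return self.methylated / self.total if self.total else None


@dataclass(frozen=True)
class CaptureMetrics:
    on_target_rate: float
    mean_coverage: float
    median_coverage: float
    fold_enrichment: float
    duplicate_rate: float


def _trimmed_span(read: AlignedBsRead, trim: int) -> tuple[int, int]:
    """Reference interval left after dropping the first ``trim`` read bases.

    "First" is in sequencing orientation.  Mate 1 sequences from the
    fragment's 5' end on the original strand, mate 2 from the opposite end,
    so the 5' end sits at the left reference coordinate for OT mate 1 and
    OB mate 2, and at the right coordinate otherwise.
    """
    five_prime_left = (read.bisulfite_strand == "OT") == (read.mate == 1)
    if five_prime_left:
        return read.start + trim, read.end
    return read.start, read.end - trim


def _call_positions(
    read: AlignedBsRead, genome: GenomeSequence, trim: int
) -> dict[int, bool]:
    """pos -> methylated for every strand-aware cytosine the read informs."""
    lo, hi = _trimmed_span(read, trim)
    lo = max(lo, read.start)
    hi = min(hi, read.end)
    if hi <= lo:
        return {}
    ref = genome[read.contig]
    calls: dict[int, bool] = {}
    if read.bisulfite_strand == "OT":
        meth_base, conv_base, ref_base = "C", "T", "C"
    else:
        meth_base, conv_base, ref_base = "G", "A", "G"
    for pos in range(lo, hi):
        if ref[pos] != ref_base:
            continue
        base = read.query_seq[pos - read.start]
        if base == meth_base:
            calls[pos] = True
        elif base == conv_base:
            calls[pos] = False
        # other bases: sequencing error or SNP -> no call
    return calls


def call_methylation(
    reads: Iterable[AlignedBsRead],
    genome: GenomeSequence,
    trim: int = 2,
    no_overlap: bool = True,
) -> list[MethylationCall]:
    """Aggregate per-cytosine methylated/unmethylated counts from reads.

    Duplicate-flagged reads are skipped.  With ``no_overlap`` a position
    covered by both mates of a pair is counted once (mate 1 wins).
    """
    counts: dict[tuple[str, int], list[int]] = defaultdict(lambda: [0, 0])
    by_fragment: dict[str, list[AlignedBsRead]] = defaultdict(list)
    for read in reads:
        if read.is_duplicate:
            continue
        if read.end > genome.length(read.contig):
            raise IndexError(
                f"read {read.read_id} extends beyond contig {read.contig}"
            )
        by_fragment[read.read_id].append(read)
    for frag_reads in by_fragment.values():
        frag_reads = sorted(frag_reads, key=lambda r: r.mate)
        seen: set[int] = set()
        for read in frag_reads:
            calls = _call_positions(read, genome, trim)
            for pos, methylated in calls.items():
                if no_overlap and pos in seen:
                    continue
                key = (read.contig, pos)
                counts[key][0 if methylated else 1] += 1
            if no_overlap:
                seen.update(calls)
    out = []
    for (contig, pos), (meth, unmeth) in sorted(counts.items()):
        strand = "+" if genome[contig][pos] == "C" else "-"
        ctx = classify_context(genome, contig, pos, strand)
        out.append(
            MethylationCall(CytosineSite(contig, pos, strand, ctx), meth, unmeth)
        )
    return out


def calls_to_rows(calls: Iterable[MethylationCall]) -> list[CallRow]:
    return [
        CallRow(c.site.contig, c.site.pos, c.site.strand, c.site.context,
                c.methylated, c.unmethylated)
        for c in calls
    ]


def methylation_pattern(read: AlignedBsRead, genome: GenomeSequence) -> str:
    """Untrimmed per-cytosine call string ('M'/'U'/'.') used in duplicate keys."""
    calls = _call_positions(read, genome, trim=0)
    ref = genome[read.contig]
    ref_base = "C" if read.bisulfite_strand == "OT" else "G"
    out = []
    for pos in range(read.start, read.end):
        if ref[pos] != ref_base:
            continue
        if pos in calls:
            out.append("M" if calls[pos] else "U")
        else:
            out.append(".")
    return "".join(out)


def mark_duplicates(
    reads: Sequence[AlignedBsRead],
    genome: GenomeSequence | None = None,
    use_methylation_pattern: bool = True,
) -> tuple[list[AlignedBsRead], float]:
    """Flag PCR duplicates; returns (reads, duplicate_rate).

    Fragments (mates grouped by read_id) sharing contig, outer start/end and
    bisulfite strand are duplicates; with ``use_methylation_pattern`` the
    concatenated per-mate methylation pattern is part of the identity, so two
    fragments with identical coordinates but different methylation survive as
    distinct molecules.  One representative per group (first in sorted order)
    is kept unflagged.
    """
    if use_methylation_pattern and genome is None:
        raise ValueError("pattern-aware duplicate marking needs the genome")
    fragments: dict[str, list[AlignedBsRead]] = defaultdict(list)
    for read in reads:
        fragments[read.read_id].append(read)

    def frag_key(frag: list[AlignedBsRead]):
        frag = sorted(frag, key=lambda r: r.mate)
        start = min(r.start for r in frag)
        end = max(r.end for r in frag)
        key = (frag[0].contig, start, end, frag[0].bisulfite_strand)
        if use_methylation_pattern:
            key += (tuple(methylation_pattern(r, genome) for r in frag),)
        return key

    order = sorted(fragments, key=lambda rid: (
        min(r.start for r in fragments[rid]), rid))
    seen: set = set()
    flagged_ids: set[str] = set()
    for rid in order:
        key = frag_key(fragments[rid])
        if key in seen:
            flagged_ids.add(rid)
        else:
            seen.add(key)
    out = [replace(r, is_duplicate=(r.read_id in flagged_ids)) for r in reads]
    rate = sum(r.is_duplicate for r in out) / len(out) if out else 0.0
    return out, rate


def _target_trees(targets: Sequence[Interval]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for iv in targets:
        trees[iv.contig].addi(iv.start, iv.end)
    return dict(trees)


def on_target_rate(
    reads: Sequence[AlignedBsRead], targets: Sequence[Interval]
) -> float:
    """Fraction of aligned reads overlapping a target by >=1 bp (no padding)."""
    if not reads:
        raise UndefinedRateError("no aligned reads")
    trees = _target_trees(targets)
    n_on = sum(
        1 for r in reads
        if r.contig in trees and trees[r.contig].overlaps(r.start, r.end)
    )
    return n_on / len(reads)


def _fragment_depth(
    reads: Sequence[AlignedBsRead],
) -> dict[str, dict[str, tuple[int, int]]]:
    """Per-fragment clipped intervals: mate overlap contributes depth once."""
    frags: dict[str, list[AlignedBsRead]] = defaultdict(list)
    for r in reads:
        if not r.is_duplicate:
            frags[r.read_id].append(r)
    spans: dict[str, list[tuple[int, int]]] = defaultdict(list)
    for rid, frag in frags.items():
        covered: set[int] = set()
        for r in sorted(frag, key=lambda x: x.mate):
            covered.update(range(r.start, r.end))
        # merge to runs for compactness
        contig = frag[0].contig
        run_start = None
        prev = None
        for pos in sorted(covered):
            if run_start is None:
                run_start = prev = pos
            elif pos == prev + 1:
                prev = pos
            else:
                spans[contig].append((run_start, prev + 1))
                run_start = prev = pos
        if run_start is not None:
            spans[contig].append((run_start, prev + 1))
    return spans


def coverage_stats(
    reads: Sequence[AlignedBsRead],
    targets: Sequence[Interval],
    include_zero_depth: bool = True,
) -> tuple[float, float]:
    """Mean and median per-base depth over target bases.

    Duplicates are excluded and mate overlaps clipped so each fragment adds
    at most one to any base's depth.  Zero-depth target bases count by
    default (flag to restrict to covered bases).
    """
    if not targets:
        raise ValueError("no target intervals")
    # depth arrays sized per contig from target and read extents
    extents: dict[str, int] = defaultdict(int)
    for iv in targets:
        extents[iv.contig] = max(extents[iv.contig], iv.end)
    for r in reads:
        extents[r.contig] = max(extents[r.contig], r.end)
    depth = {c: np.zeros(n, dtype=np.int32) for c, n in extents.items()}
    for contig, spans in _fragment_depth(reads).items():
        for s, e in spans:
            if contig in depth:
                depth[contig][s:e] += 1
    target_mask: dict[str, np.ndarray] = {
        c: np.zeros(n, dtype=bool) for c, n in extents.items()
    }
    for iv in targets:
        target_mask[iv.contig][iv.start : iv.end] = True
    values = np.concatenate(
        [depth[c][target_mask[c]] for c in sorted(extents)]
    )
    if not include_zero_depth:
        values = values[values > 0]
        if values.size == 0:
            return 0.0, 0.0
    return float(values.mean()), float(np.median(values))


def fold_enrichment(
    reads: Sequence[AlignedBsRead],
    targets: Sequence[Interval],
    genome: GenomeSequence,
) -> float:
    """(on-target aligned bases / target size) / (aligned bases / genome size).

    A base-ratio simplification of hybrid-selection enrichment metrics:
    the density of sequencing on target relative to a uniform genome-wide
    expectation.  Duplicates are excluded.
    """
    live = [r for r in reads if not r.is_duplicate]
    total_bases = sum(r.end - r.start for r in live)
    if total_bases == 0:
        raise UndefinedRateError("no aligned bases")
    target_size = sum(iv.length for iv in targets)
    if target_size == 0:
        raise ValueError("empty target set")
    trees = _target_trees(targets)
    on_bases = 0
    for r in live:
        if r.contig not in trees:
            continue
        for hit in trees[r.contig].overlap(r.start, r.end):
            on_bases += min(r.end, hit.end) - max(r.start, hit.begin)
    return (on_bases / target_size) / (total_bases / genome.total_length)


def capture_metrics(
    reads: Sequence[AlignedBsRead],
    targets: Sequence[Interval],
    genome: GenomeSequence,
    use_methylation_pattern: bool = True,
) -> CaptureMetrics:
    """One-stop QC: duplicate marking then on-target, coverage, enrichment."""
    marked, dup_rate = mark_duplicates(
        reads, genome, use_methylation_pattern=use_methylation_pattern
    )
    live = [r for r in marked if not r.is_duplicate]
    mean_cov, med_cov = coverage_stats(live, targets)
    return CaptureMetrics(
        on_target_rate=on_target_rate(marked, targets),
        mean_coverage=mean_cov,
        median_coverage=med_cov,
        fold_enrichment=fold_enrichment(live, targets, genome),
        duplicate_rate=dup_rate,
    )


# --- mixture bias check -------------------------------------------------


@dataclass(frozen=True)
class MixtureReport:
    distance: float
    null_q95: float
    n_sites: int
    bins: np.ndarray
    expected_hist: np.ndarray
    observed_hist: np.ndarray

    @property
    def within_resampling_error(self) -> bool:
        return self.distance <= self.null_q95


def _calls_by_site(calls: Iterable[MethylationCall]) -> dict[tuple, MethylationCall]:
    return {
        (c.site.contig, c.site.pos, c.site.strand): c
        for c in calls
        if c.total > 0
    }


def methylation_mixture_check(
    sample_a_calls: Sequence[MethylationCall],
    sample_b_calls: Sequence[MethylationCall],
    mix_calls: Sequence[MethylationCall],
    n_bins: int = 20,
    n_resamples: int = 200,
    rng: np.random.Generator | None = None,
) -> MixtureReport:
    """Compare an observed mixture's methylation histogram with its 50:50 expectation.

    Mirrors an equal-proportion pooling of an untreated and an enzymatically
    methylated sample: each molecule in the mixture comes from either parent
    with probability one half, so at deep coverage a site's level tends to
    the average of the two parent levels.  The expected histogram is built
    from those per-site averages; the statistic is total-variation distance
    between it and the observed mixture histogram.  A Monte-Carlo null —
    regenerating mixture levels at each site's observed depth by drawing the
    parent split Binomial(n, 1/2) and read outcomes binomially from each
    parent level — gives the scale of "within resampling error" (q95).
    """
    rng = rng or np.random.default_rng(0)
    a = _calls_by_site(sample_a_calls)
    b = _calls_by_site(sample_b_calls)
    m = _calls_by_site(mix_calls)
    common = sorted(set(a) & set(b) & set(m))
    if not common:
        raise ValueError("no sites shared by all three call sets")
    bins = np.linspace(0.0, 1.0, n_bins + 1)
    av = np.array([a[s].level for s in common])
    bv = np.array([b[s].level for s in common])
    mv = np.array([m[s].level for s in common])
    depth = np.array([m[s].total for s in common])

    def hist(x: np.ndarray) -> np.ndarray:
        h, _ = np.histogram(np.clip(x, 0.0, 1.0), bins=bins)
        return h / len(x)

    expected = hist((av + bv) / 2.0)
    observed = hist(mv)
    distance = 0.5 * float(np.abs(expected - observed).sum())
    null = np.empty(n_resamples)
    for i in range(n_resamples):
        k = rng.binomial(depth, 0.5)
        meth = rng.binomial(k, av) + rng.binomial(depth - k, bv)
        null[i] = 0.5 * float(np.abs(expected - hist(meth / depth)).sum())
    return MixtureReport(
        distance=distance,
        null_q95=float(np.quantile(null, 0.95)),
        n_sites=len(common),
        bins=bins,
        expected_hist=expected,
        observed_hist=observed,
    )
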
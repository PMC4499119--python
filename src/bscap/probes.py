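"""Capture probe design for bisulfite-converted libraries.

A convert-then-capture assay hybridises its probes to bisulfite-converted
DNA, so a single genomic locus presents up to four distinct sequence spaces:
top and bottom strand, each either CG-methylated (CG cytosines protected) or
fully converted.  The designer therefore emits four probe panels, one per
:class:`~bscap.core.StrandState`.

The pipeline is: tile candidate probes of variable length (50-100 nt, 5 bp
tiling) across each target; score each candidate (melting temperature,
homopolymer run, mean 15-mer genome frequency of the converted sequence,
number of bisulfite-ambiguous genomic mapping locations); discard candidates
with mean 15-mer frequency > 10 000 or more than 3 mapping locations; then
walk each target in 15 bp selection windows separated by 20 bp gaps, keeping
the best-ranked surviving candidate per window.
"""

from __future__ import annotations

import logging
import re
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

from .core import (
    ALL_STRAND_STATES,
    GenomeSequence,
    MethylationAssumption,
    Strand,
    StrandState,
    convert_genome_bottom,
    convert_genome_top,
    convert_sequence,
    reverse_complement,
)
from .io import Interval

logger = logging.getLogger(__name__)


@dataclass
class ProbeCandidate:
    """A tiled, conversion-state-specific capture probe with its scores."""

    contig: str
    start: int
    end: int
    state: StrandState
    seq: str
    tm: float = 0.0
    repeat_score: float = 0.0
    homopolymer_score: int = 0
    uniqueness: int = 1
    rank_score: float = 0.0

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class DesignParams:
    min_len: int = 50
    max_len: int = 100
    tile: int = 5
    k: int = 15
    window: int = 15
    gap: int = 20
    max_repeat: float = 10_000.0
    max_locations: int = 3
    tm_band: tuple[float, float] = (68.0, 73.0)
    tm_method: str = "gc"
    # rank weights, all lower-is-better after normalisation
    weights: dict[str, float] = field(
        default_factory=lambda: {
            "tm": 1.0,
            "repeat": 1.0,
            "uniqueness": 1.0,
            "homopolymer": 1.0,
        }
    )

    @property
    def tm_target(self) -> float:
        return (self.tm_band[0] + self.tm_band[1]) / 2.0


def canonical_kmer(kmer: str) -> str:
    rc = reverse_complement(kmer)
    return kmer if kmer <= rc else rc


class KmerFrequencyTable:
    """k-mer occurrence counts over both strands of the fully converted genome.

    Built from the no-CG-methylated conversion: every C becomes T on each
    strand, which is the worst case for repetitiveness (the converted
    alphabet is effectively three letters).  Counting is strand-symmetric —
    a k-mer and its reverse complement share one key — since amplification of
    the converted library produces both complements of every converted
    strand.  k-mers containing N are skipped.
    """

    def __init__(self, counts: Counter[str], k: int):
        self.counts = counts
        self.k = k

    @classmethod
    def from_genome(cls, genome: GenomeSequence, k: int = 15) -> "KmerFrequencyTable":
        counts: Counter[str] = Counter()
        strands = [convert_genome_top(genome), convert_genome_bottom(genome)]
        for strand_seqs in strands:
            for name, seq in strand_seqs.items():
                if len(seq) < k:
                    logger.warning(
                        "contig %s shorter than k=%d; skipped in k-mer table", name, k
                    )
                    continue
                for i in range(len(seq) - k + 1):
                    kmer = seq[i : i + k]
                    if "N" not in kmer:
                        counts[canonical_kmer(kmer)] += 1
        return cls(counts, k)

    def __getitem__(self, kmer: str) -> int:
        return self.counts.get(canonical_kmer(kmer), 0)

    def total(self) -> int:
        return sum(self.counts.values())


def homopolymer_score(seq: str) -> int:
    """Longest single-base run in ``seq``."""
    if not seq:
        raise ValueError("empty sequence has no homopolymer score")
    best = run = 1
    for a, b in zip(seq, seq[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best


def homopolymer_runs(seq: str) -> dict[str, int]:
    """Longest run per base, for inspection."""
    runs = {b: 0 for b in "ACGT"}
    i = 0
    while i < len(seq):
        j = i
        while j < len(seq) and seq[j] == seq[i]:
            j += 1
        if seq[i] in runs:
            runs[seq[i]] = max(runs[seq[i]], j - i)
        i = j
    return runs


def melting_temperature(seq: str, method: str = "gc") -> float:
    """Oligo melting temperature in degrees C.

    Default is the GC-content formula Tm = 64.9 + 41*(nGC - 16.4)/L, the
    standard long-oligo approximation; ``method='wallace'`` gives the 2/4
    rule (short oligos), exposed mainly for comparison.
    """
    if not seq:
        raise ValueError("empty sequence")
    if "N" in seq:
        raise ValueError("cannot compute Tm of a sequence containing N")
    return _tm_from_gc(seq.count("G") + seq.count("C"), len(seq), method)


def _tm_from_gc(gc: int, length: int, method: str = "gc") -> float:
    if method == "gc":
        return 64.9 + 41.0 * (gc - 16.4) / length
    if method == "wallace":
        return 2.0 * (length - gc) + 4.0 * gc
    raise ValueError(f"unknown Tm method {method!r}")


def repeat_score(probe: ProbeCandidate, table: KmerFrequencyTable) -> float:
    """Mean genome frequency of the converted probe's k-mers."""
    k = table.k
    if probe.length < k:
        raise ValueError(f"probe of length {probe.length} shorter than k={k}")
    kmers = [probe.seq[i : i + k] for i in range(len(probe.seq) - k + 1)]
    return sum(table[km] for km in kmers) / len(kmers)


def _asymmetric_pattern(probe_seq: str) -> re.Pattern[str]:
    # bisulfite-asymmetric: probe T matches genome C or T; C, A, G exact; N never
    parts = []
    for b in probe_seq:
        if b == "T":
            parts.append("[CT]")
        elif b in "ACG":
            parts.append(b)
        else:
            parts.append("(?!)")  # N in probe: no match
    return re.compile("(?=(" + "".join(parts) + "))")


def count_mapping_locations(probe: ProbeCandidate, genome: GenomeSequence) -> int:
    """Number of genomic locations matching the probe under bisulfite rules.

    The converted probe is slid over both strands of the raw genome; a probe
    T matches genome C or T (the C may or may not have been converted in the
    captured fragment), while A, C and G must match exactly.  Scanning the
    reverse complement of each contig covers the G-converted orientation
    (probe A matching genome G or A on the forward strand).  Exact matching;
    desk-scale genomes need no mismatch budget.
    """
    pat = _asymmetric_pattern(probe.seq)
    n = 0
    for name, seq in genome.contigs.items():
        n += sum(1 for _ in pat.finditer(seq))
        n += sum(1 for _ in pat.finditer(reverse_complement(seq)))
    return n


def _probe_window(genome: GenomeSequence, contig: str, start: int, end: int,
                  state: StrandState) -> str:
    window = genome.fetch(contig, start, end)
    if state.strand is Strand.BOTTOM:
        window = reverse_complement(window)
    return convert_sequence(window, state)


def _choose_length(
    genome: GenomeSequence,
    contig: str,
    start: int,
    limit: int,
    state: StrandState,
    params: DesignParams,
) -> tuple[int, str, float] | None:
    """Grow the probe 1 bp at a time until Tm enters the band.

    Returns (length, converted_seq, tm) or None if no valid length exists
    (e.g. N in every window).  If the band is never reached, the length whose
    Tm is closest to the band centre is used: Tm is the only stated probe
    property that length can tune.
    """
    lo, hi = params.tm_band
    max_len = min(params.max_len, limit - start)
    if max_len < params.min_len:
        return None
    raw = genome.fetch(contig, start, start + max_len)
    # GC of the converted window, by state, from prefix counts of the raw
    # reference-orientation window (CG dinucleotides are palindromic):
    #   top/no_cg: #G     bottom/no_cg: #C     all_cg adds #CG pairs
    cum_g = [0] * (max_len + 1)
    cum_c = [0] * (max_len + 1)
    cum_cg = [0] * (max_len + 1)
    cum_n = [0] * (max_len + 1)
    for i, b in enumerate(raw):
        cum_g[i + 1] = cum_g[i] + (b == "G")
        cum_c[i + 1] = cum_c[i] + (b == "C")
        cum_n[i + 1] = cum_n[i] + (b == "N")
        cum_cg[i + 1] = cum_cg[i] + (
            1 if i > 0 and raw[i - 1] == "C" and b == "G" else 0
        )
    keep_cg = state.methylation_assumption is MethylationAssumption.ALL_CG_METHYLATED
    fallback: tuple[float, int] | None = None
    for length in range(params.min_len, max_len + 1):
        if cum_n[length]:
            continue
        gc = cum_g[length] if state.strand is Strand.TOP else cum_c[length]
        if keep_cg:
            gc += cum_cg[length]
        tm = _tm_from_gc(gc, length, params.tm_method)
        if lo <= tm <= hi:
            seq = _probe_window(genome, contig, start, start + length, state)
            return length, seq, tm
        dist = abs(tm - params.tm_target)
        if fallback is None or dist < fallback[0]:
            fallback = (dist, length)
    if fallback is None:
        return None
    length = fallback[1]
    seq = _probe_window(genome, contig, start, start + length, state)
    return length, seq, melting_temperature(seq, params.tm_method)


def generate_candidates(
    genome: GenomeSequence,
    targets: Sequence[Interval],
    params: DesignParams | None = None,
) -> list[ProbeCandidate]:
    """Tile variable-length candidates across each target, all four states.

    Candidate starts are placed every ``tile`` bp from each target's start;
    a candidate may extend past the target end (capture reaches beyond probe
    boundaries) but never past the contig.
    """
    params = params or DesignParams()
    out: list[ProbeCandidate] = []
    for iv in targets:
        if iv.end - iv.start < params.min_len:
            logger.warning(
                "target %s:%d-%d shorter than min probe length %d; no candidates",
                iv.contig, iv.start, iv.end, params.min_len,
            )
            continue
        contig_len = genome.length(iv.contig)
        last_start = iv.end - params.min_len
        for start in range(iv.start, last_start + 1, params.tile):
            for state in ALL_STRAND_STATES:
                chosen = _choose_length(
                    genome, iv.contig, start, contig_len, state, params
                )
                if chosen is None:
                    continue
                length, seq, tm = chosen
                out.append(
                    ProbeCandidate(
                        contig=iv.contig,
                        start=start,
                        end=start + length,
                        state=state,
                        seq=seq,
                        tm=tm,
                        homopolymer_score=homopolymer_score(seq),
                    )
                )
    return out


def score_candidates(
    candidates: Iterable[ProbeCandidate],
    genome: GenomeSequence,
    table: KmerFrequencyTable,
) -> list[ProbeCandidate]:
    """Fill repeat_score and uniqueness for every candidate."""
    scored = []
    for cand in candidates:
        scored.append(
            replace(
                cand,
                repeat_score=repeat_score(cand, table),
                uniqueness=count_mapping_locations(cand, genome),
            )
        )
    return scored


def filter_candidates(
    candidates: Iterable[ProbeCandidate],
    max_repeat: float = 10_000.0,
    max_locations: int = 3,
) -> tuple[list[ProbeCandidate], dict[str, int]]:
    """Drop repetitive and multi-mapping candidates.

    A candidate survives iff its mean 15-mer frequency is <= ``max_repeat``
    (removal requires strictly greater) and it maps to at most
    ``max_locations`` genomic locations.  Removal counts per reason are
    returned for the audit log.
    """
    kept: list[ProbeCandidate] = []
    removed = {"repeat": 0, "uniqueness": 0}
    for cand in candidates:
        if cand.repeat_score > max_repeat:
            removed["repeat"] += 1
        elif cand.uniqueness > max_locations:
            removed["uniqueness"] += 1
        else:
            kept.append(cand)
    if any(removed.values()):
        logger.info("filter_candidates removed %s", removed)
    return kept, removed


def _minmax(values: list[float]) -> list[float]:
    lo, hi = min(values), max(values)
    if hi == lo:
        return [0.0] * len(values)
    return [(v - lo) / (hi - lo) for v in values]


def rank_candidates(
    candidates: Sequence[ProbeCandidate], params: DesignParams | None = None
) -> list[ProbeCandidate]:
    """Assign the composite rank score (lower is better) to each candidate.

    Components — |Tm − band centre|, repeat score, uniqueness, homopolymer
    run — are min-max normalised over the candidate pool and combined as a
    weighted sum, so the score strictly improves as any component improves.
    """
    params = params or DesignParams()
    if not candidates:
        return []
    comps = {
        "tm": [abs(c.tm - params.tm_target) for c in candidates],
        "repeat": [c.repeat_score for c in candidates],
        "uniqueness": [float(c.uniqueness) for c in candidates],
        "homopolymer": [float(c.homopolymer_score) for c in candidates],
    }
    normed = {k: _minmax(v) for k, v in comps.items()}
    out = []
    for i, cand in enumerate(candidates):
        score = sum(params.weights[k] * normed[k][i] for k in comps)
        out.append(replace(cand, rank_score=score))
    return out


@dataclass(frozen=True)
class SelectionWindow:
    contig: str
    start: int
    end: int


def selection_windows(target: Interval, window: int = 15, gap: int = 20
                      ) -> list[SelectionWindow]:
    """15 bp windows placed left to right with 20 bp gaps, per target."""
    out = []
    pos = target.start
    while pos + window <= target.end:
        out.append(SelectionWindow(target.contig, pos, pos + window))
        pos += window + gap
    return out


def select_probes(
    candidates: Sequence[ProbeCandidate],
    targets: Sequence[Interval],
    params: DesignParams | None = None,
) -> dict[StrandState, list[ProbeCandidate]]:
    """Pick the best-ranked probe per selection window, per strand state.

    Within a window all candidates whose start falls inside it compete on
    rank score; ties break to the lowest start coordinate, then the longest
    probe.  A window with no surviving candidate is logged as a gap.
    """
    params = params or DesignParams()
    panels: dict[StrandState, list[ProbeCandidate]] = {
        state: [] for state in ALL_STRAND_STATES
    }
    by_state: dict[StrandState, list[ProbeCandidate]] = {
        state: [] for state in ALL_STRAND_STATES
    }
    for cand in candidates:
        by_state[cand.state].append(cand)
    for state in ALL_STRAND_STATES:
        pool = sorted(by_state[state], key=lambda c: (c.contig, c.start))
        for target in targets:
            for win in selection_windows(target, params.window, params.gap):
                in_win = [
                    c for c in pool
                    if c.contig == win.contig and win.start <= c.start < win.end
                ]
                if not in_win:
                    logger.warning(
                        "no probe for window %s:%d-%d (%s)",
                        win.contig, win.start, win.end, state.name,
                    )
                    continue
                best = min(in_win, key=lambda c: (c.rank_score, c.start, -c.length))
                panels[state].append(best)
    return panels


def design_probes(
    genome: GenomeSequence,
    targets: Sequence[Interval],
    params: DesignParams | None = None,
) -> tuple[dict[StrandState, list[ProbeCandidate]], dict[str, int]]:
    """Full pipeline: tile, score, filter, rank, select. Returns panels + audit."""
    params = params or DesignParams()
    table = KmerFrequencyTable.from_genome(genome, params.k)
    cands = generate_candidates(genome, targets, params)
    cands = score_candidates(cands, genome, table)
    kept, removed = filter_candidates(cands, params.max_repeat, params.max_locations)
    ranked = rank_candidates(kept, params)
    panels = select_probes(ranked, targets, params)
    audit = {
        "candidates": len(cands),
        "removed_repeat": removed["repeat"],
        "removed_uniqueness": removed["uniqueness"],
        "selected": sum(len(p) for p in panels.values()),
    }
    return panels, audit
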
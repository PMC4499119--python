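"""In-silico bisulfite conversion, cytosine contexts and allele enumeration.

Bisulfite treatment deaminates unmethylated cytosine to uracil, which is read
as thymine after PCR; 5-methylcytosine (and 5-hydroxymethylcytosine) resist
conversion.  A converted library therefore no longer carries one sequence per
locus: every potentially methylated cytosine doubles the number of possible
converted alleles, so a fragment with ``n`` such cytosines has ``2**n``
possible readouts per strand.  This module holds the deterministic pieces of
that arithmetic: applying a conversion rule to a sequence under an assumed
methylation state, classifying each genomic cytosine into the CG / CHG / CHH
sequence contexts (H = A, T or C), enumerating converted alleles, and
estimating the achieved conversion rate from an unmethylated control contig.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Iterator

ALPHABET = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class AlphabetError(ValueError):
    """A sequence contains a character outside A, C, G, T, N."""


class ContextError(ValueError):
    """Context was requested at a position that is not a strand-aware cytosine."""


class UndefinedRateError(ZeroDivisionError):
    """A rate was requested over zero observations."""


class Strand(str, Enum):
    TOP = "top"
    BOTTOM = "bottom"


class MethylationAssumption(str, Enum):
    ALL_CG_METHYLATED = "all_cg_methylated"
    NO_CG_METHYLATED = "no_cg_methylated"


@dataclass(frozen=True)
class StrandState:
    """One of the four conversion states a capture panel must cover.

    A converted fragment may originate from either genomic strand, and its
    CG cytosines may or may not have been methylated (hence protected).
    Probes are designed for all four combinations.
    """

    strand: Strand
    methylation_assumption: MethylationAssumption

    @property
    def name(self) -> str:
        return f"{self.strand.value}_{self.methylation_assumption.value}"


ALL_STRAND_STATES = tuple(
    StrandState(s, m) for s in Strand for m in MethylationAssumption
)


@dataclass(frozen=True)
class CytosineSite:
    """A strand-aware cytosine: reference C on '+', reference G on '-'."""

    contig: str
    pos: int  # 0-based
    strand: str  # '+' or '-'
    context: str  # 'CG', 'CHG', 'CHH' or 'edge'


@dataclass(frozen=True)
class FragmentAlleleCount:
    n_cytosines: int
    allele_count: int

    def __post_init__(self) -> None:
        if self.allele_count != 2**self.n_cytosines:
            raise ValueError("allele_count must equal 2**n_cytosines")


class GenomeSequence:
    """An in-memory genome: uppercase contig sequences over A, C, G, T, N."""

    def __init__(self, contigs: dict[str, str]):
        clean: dict[str, str] = {}
        for name, seq in contigs.items():
            seq = seq.upper()
            if not seq:
                raise ValueError(f"contig {name!r} is empty")
            validate_sequence(seq)
            clean[name] = seq
        self.contigs = clean

    def __getitem__(self, name: str) -> str:
        return self.contigs[name]

    def __contains__(self, name: str) -> bool:
        return name in self.contigs

    def __iter__(self) -> Iterator[str]:
        return iter(self.contigs)

    def __len__(self) -> int:
        return len(self.contigs)

    def length(self, name: str) -> int:
        return len(self.contigs[name])

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.contigs.values())

    def fetch(self, contig: str, start: int, end: int) -> str:
        seq = self.contigs[contig]
        if start < 0 or end > len(seq) or start >= end:
            raise IndexError(
                f"interval {contig}:{start}-{end} outside contig of length {len(seq)}"
            )
        return seq[start:end]


def validate_sequence(seq: str) -> None:
    if not set(seq) <= ALPHABET:
        bad = sorted(set(seq) - ALPHABET)
        raise AlphabetError(f"invalid characters in sequence: {bad}")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def convert_sequence(seq: str, state: StrandState) -> str:
    """Bisulfite-convert ``seq`` under the assumed methylation state.

    The rule is applied to the sequence in its own 5'->3' orientation, so it
    is identical for both strands; a bottom-strand caller passes the reverse
    complement of the top-strand window.  Under ``no_cg_methylated`` every C
    becomes T; under ``all_cg_methylated`` Cs immediately followed by G are
    protected and every other C becomes T.  A C followed by N is treated as
    unprotected (ambiguous context cannot justify protection).
    """
    validate_sequence(seq)
    if state.methylation_assumption is MethylationAssumption.NO_CG_METHYLATED:
        return seq.replace("C", "T")
    out = []
    n = len(seq)
    for i, base in enumerate(seq):
        if base == "C" and not (i + 1 < n and seq[i + 1] == "G"):
            out.append("T")
        else:
            out.append(base)
    return "".join(out)


def convert_genome_top(genome: GenomeSequence) -> dict[str, str]:
    """Fully converted (no CG methylated) top strand of every contig."""
    return {name: seq.replace("C", "T") for name, seq in genome.contigs.items()}


def convert_genome_bottom(genome: GenomeSequence) -> dict[str, str]:
    """Fully converted bottom strand, 5'->3' (reverse complement then C->T)."""
    return {
        name: reverse_complement(seq).replace("C", "T")
        for name, seq in genome.contigs.items()
    }


def classify_context(
    genome: GenomeSequence, contig: str, pos: int, strand: str
) -> str:
    """CG / CHG / CHH context of the strand-aware cytosine at ``pos``.

    Context is read downstream in the cytosine's own strand orientation:
    on '+' from the reference as written, on '-' from the complement read
    right-to-left.  Fewer than the needed downstream bases -> ``'edge'``;
    an N in the context window (or at the site) also yields no call and is
    reported as ``'edge'`` ambiguity via :class:`ContextError`-free 'edge'.
    """
    seq = genome[contig]
    if strand == "+":
        base = seq[pos]
        if base != "C":
            raise ContextError(f"{contig}:{pos}(+) is {base}, not C")
        window = seq[pos + 1 : pos + 3]
    elif strand == "-":
        base = seq[pos]
        if base != "G":
            raise ContextError(f"{contig}:{pos}(-) is {base}, not G (strand C)")
        window = reverse_complement(seq[max(0, pos - 2) : pos])
    else:
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")
    if len(window) < 1 or "N" in window[:1]:
        return "edge"
    if window[0] == "G":
        return "CG"
    if len(window) < 2 or "N" in window:
        return "edge"
    if window[1] == "G":
        return "CHG"
    return "CHH"


def iter_cytosine_sites(
    genome: GenomeSequence,
    contig: str | None = None,
    include_edge: bool = False,
) -> Iterator[CytosineSite]:
    """Yield every strand-aware cytosine with its context.

    Edge-truncated or N-adjacent sites are skipped unless ``include_edge``.
    """
    names = [contig] if contig is not None else list(genome)
    for name in names:
        seq = genome[name]
        for pos, base in enumerate(seq):
            if base == "C":
                ctx = classify_context(genome, name, pos, "+")
                if ctx != "edge" or include_edge:
                    yield CytosineSite(name, pos, "+", ctx)
            elif base == "G":
                ctx = classify_context(genome, name, pos, "-")
                if ctx != "edge" or include_edge:
                    yield CytosineSite(name, pos, "-", ctx)


def _strand_cytosine_positions(
    seq: str, strand: Strand, cg_only: bool = False
) -> list[int]:
    if strand is Strand.BOTTOM:
        seq = reverse_complement(seq)
    positions = []
    for i, b in enumerate(seq):
        if b != "C":
            continue
        if cg_only and not (i + 1 < len(seq) and seq[i + 1] == "G"):
            continue
        positions.append(i)
    return positions


def enumerate_alleles(
    seq: str,
    strand: Strand = Strand.TOP,
    cg_only: bool = False,
    materialize: bool = False,
) -> FragmentAlleleCount | tuple[FragmentAlleleCount, list[str]]:
    """Count (and optionally list) the converted alleles of one strand.

    Every potentially methylated cytosine independently either survives
    conversion (methylated) or reads as T, giving ``2**n`` distinct alleles.
    By default all strand cytosines count as potentially methylated, since
    non-CG methylation is prominent in plant genomes; ``cg_only`` restricts
    to CG dinucleotides.
    """
    validate_sequence(seq)
    work = reverse_complement(seq) if strand is Strand.BOTTOM else seq
    positions = _strand_cytosine_positions(seq, strand, cg_only=cg_only)
    count = FragmentAlleleCount(len(positions), 2 ** len(positions))
    if not materialize:
        return count
    alleles = []
    for pattern in itertools.product("CT", repeat=len(positions)):
        chars = list(work)
        for p, b in zip(positions, pattern):
            chars[p] = b
        alleles.append("".join(chars))
    return count, alleles


def conversion_rate(control_calls: Iterable[tuple[int, int]]) -> float:
    """Pooled conversion rate from an unmethylated control contig.

    ``control_calls`` holds (converted_count, total_count) per cytosine of a
    contig known to be unmethylated (a chloroplast or lambda spike-in), so
    every unconverted readout is a conversion failure.
    """
    converted = 0
    total = 0
    for conv, tot in control_calls:
        if tot < 0 or conv < 0 or conv > tot:
            raise ValueError(f"invalid control call ({conv}, {tot})")
        converted += conv
        total += tot
    if total == 0:
        raise UndefinedRateError("conversion rate undefined: no control coverage")
    return converted / total
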
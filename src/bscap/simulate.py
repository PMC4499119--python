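"""Synthetic data generation with recorded ground truth.

Everything the rest of the toolkit consumes can be generated here at desk
scale: a random genome with an unmethylated control contig (the chloroplast
or lambda analog), a diploid pair of parental haplotypes separated by SNPs,
per-cytosine methylomes with the hallmarks of a plant methylome (bimodal CG
and CHG, low CHH), paired-end bisulfite reads with realistic fragment sizes
(180-220 bp), 100 bp mates and 99.8% conversion efficiency, TAB-seq reads in
which 5hmC resists conversion, and spike-in control contigs of known
modification state.  All randomness flows from a numpy Generator seeded in
the config; a fixed seed reproduces outputs byte for byte.

Reads are emitted pre-aligned at their true coordinates; no aligner is
modelled.  PCR duplicates are injected as literal fragment copies.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .calling import AlignedBsRead
from .core import GenomeSequence, iter_cytosine_sites
from .io import Interval
from .snps import SnpRecord

CONTROL_CONTIG = "control_unmethylated"
SPIKE_CONTIGS = {
    "spike_unmethylated": "unmethylated",
    "spike_mC": "mC",
    "spike_hmC": "hmC",
}


@dataclass(frozen=True)
class MethylomeParams:
    """Per-context beta-mixture parameters for the truth methylome.

    CG and CHG sites draw from a high/low two-component mixture (bimodal
    marginal distribution); CHH sites from a single low-mean component.
    Defaults give strongly bimodal CG/CHG and mean CHH around 0.08.
    """

    cg_high_fraction: float = 0.7
    cg_high: tuple[float, float] = (20.0, 1.5)
    cg_low: tuple[float, float] = (1.0, 30.0)
    chg_high_fraction: float = 0.6
    chg_high: tuple[float, float] = (12.0, 2.0)
    chg_low: tuple[float, float] = (1.0, 30.0)
    chh: tuple[float, float] = (1.2, 14.0)


@dataclass(frozen=True)
class SimulationConfig:
    genome_length: int = 20_000
    gc_content: float = 0.45
    control_length: int = 4_000
    snp_rate: float = 0.002
    methylome_params: MethylomeParams = field(default_factory=MethylomeParams)
    conversion_efficiency: float = 0.998
    fragment_length_range: tuple[int, int] = (180, 220)
    read_length: int = 100
    depth: float = 30.0
    off_target_fraction: float = 0.0
    duplicate_fraction: float = 0.0
    sequencing_error: float = 0.0
    seed: int = 0

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class TruthSet:
    """Recorded ground truth for parameter-recovery tests."""

    methylome: dict  # (contig, pos, strand) -> 5mC probability
    hydroxymethylome: dict  # (contig, pos, strand) -> 5hmC probability
    snp_table: list[SnpRecord]
    read_origins: dict  # read_id -> parent label


def _random_seq(length: int, gc: float, rng: np.random.Generator) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=length, p=probs))


def make_genome(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> GenomeSequence:
    """Random genome: one main contig plus an unmethylated control contig."""
    if config.genome_length <= 0:
        raise ValueError("genome_length must be positive")
    rng = rng if rng is not None else config.rng()
    contigs = {"chr1": _random_seq(config.genome_length, config.gc_content, rng)}
    if config.control_length > 0:
        contigs[CONTROL_CONTIG] = _random_seq(
            config.control_length, config.gc_content, rng
        )
    return GenomeSequence(contigs)


def make_spikein_contigs(
    length: int, gc: float, rng: np.random.Generator
) -> GenomeSequence:
    """Three spike-in control contigs: unmethylated C, 5mC and 5hmC classes."""
    return GenomeSequence(
        {name: _random_seq(length, gc, rng) for name in SPIKE_CONTIGS}
    )


def add_contigs(genome: GenomeSequence, extra: GenomeSequence) -> GenomeSequence:
    merged = dict(genome.contigs)
    merged.update(extra.contigs)
    return GenomeSequence(merged)


def make_diploid(
    genome: GenomeSequence,
    snp_rate: float,
    rng: np.random.Generator,
    avoid_cg_fraction: float = 1.0,
) -> tuple[GenomeSequence, GenomeSequence, list[SnpRecord]]:
    """Parent A (the reference) and parent B differing at random SNPs.

    SNP count per contig is Poisson(snp_rate * L).  A fraction of SNPs
    (default all) is constrained to A<->T substitutions at reference A/T
    positions, so the SNP stays informative on both bisulfite strands and
    the two parents share an identical cytosine complement.  The control
    contig carries no SNPs.
    """
    if not 0.0 < snp_rate < 1.0:
        raise ValueError("snp_rate must be in (0, 1)")
    parent_b = {}
    snps: list[SnpRecord] = []
    for name, seq in genome.contigs.items():
        if name == CONTROL_CONTIG or name in SPIKE_CONTIGS:
            parent_b[name] = seq
            continue
        chars = list(seq)
        n_snps = rng.poisson(snp_rate * len(seq))
        at_positions = [i for i, b in enumerate(seq) if b in "AT"]
        all_positions = list(range(len(seq)))
        chosen: set[int] = set()
        attempts = 0
        while len(chosen) < n_snps and attempts < 50 * n_snps + 50:
            attempts += 1
            if rng.random() < avoid_cg_fraction:
                if not at_positions:
                    continue
                i = int(rng.choice(at_positions))
                alt = "T" if seq[i] == "A" else "A"
            else:
                i = int(rng.choice(all_positions))
                alt = str(rng.choice([b for b in "ACGT" if b != seq[i]]))
            if i in chosen:
                continue
            chosen.add(i)
            chars[i] = alt
            snps.append(
                SnpRecord(name, i, seq[i], alt, quality=60.0, coverage=0,
                          source="catalog")
            )
        parent_b[name] = "".join(chars)
    snps.sort(key=lambda s: (s.contig, s.pos))
    return genome, GenomeSequence(parent_b), snps


def _beta(params: tuple[float, float], rng: np.random.Generator) -> float:
    return float(rng.beta(*params))


def make_methylome(
    genome: GenomeSequence,
    params: MethylomeParams,
    rng: np.random.Generator,
    hmc_fraction: float = 0.0,
    hmc_level: tuple[float, float] = (2.0, 10.0),
) -> tuple[dict, dict]:
    """Per-site 5mC (and optional 5hmC) truth drawn from context mixtures.

    Control and spike-in contigs are left unmethylated.  When ``hmc_fraction``
    is positive, that fraction of CG sites receives a 5hmC level drawn from
    a beta distribution, rescaled so 5mC + 5hmC <= 1.
    """
    methylome: dict = {}
    hydroxymethylome: dict = {}
    for site in iter_cytosine_sites(genome):
        key = (site.contig, site.pos, site.strand)
        if site.contig == CONTROL_CONTIG or site.contig in SPIKE_CONTIGS:
            methylome[key] = 0.0
            continue
        if site.context == "CG":
            if rng.random() < params.cg_high_fraction:
                level = _beta(params.cg_high, rng)
            else:
                level = _beta(params.cg_low, rng)
            if hmc_fraction > 0 and rng.random() < hmc_fraction:
                h = _beta(hmc_level, rng)
                h = min(h, 1.0 - level)
                hydroxymethylome[key] = h
        elif site.context == "CHG":
            if rng.random() < params.chg_high_fraction:
                level = _beta(params.chg_high, rng)
            else:
                level = _beta(params.chg_low, rng)
        else:  # CHH
            level = _beta(params.chh, rng)
        methylome[key] = level
    return methylome, hydroxymethylome


def set_region_levels(
    methylome: dict,
    genome: GenomeSequence,
    region: Interval,
    levels: dict[str, float],
) -> dict:
    """Overwrite the truth levels of every context cytosine in a region.

    Useful for building regions that sit at a known distance from every
    classification boundary.
    """
    out = dict(methylome)
    for site in iter_cytosine_sites(genome, region.contig):
        if region.start <= site.pos < region.end and site.context in levels:
            out[(site.contig, site.pos, site.strand)] = levels[site.context]
    return out


# --- read simulation ----------------------------------------------------


def _retention_bs(mc: float, hmc: float, efficiency: float) -> float:
    # both 5mC and 5hmC resist bisulfite; unmodified C converts with prob eff
    modified = min(mc + hmc, 1.0)
    return modified + (1.0 - modified) * (1.0 - efficiency)


def _retention_tab(mc: float, hmc: float, efficiency: float,
                   protection_rate: float, mc_conversion_rate: float) -> float:
    # glucosylated 5hmC is protected; Tet-oxidised 5mC loses its signal
    unmod = max(1.0 - mc - hmc, 0.0)
    return (
        hmc * protection_rate
        + mc * (1.0 - mc_conversion_rate)
        + unmod * (1.0 - efficiency)
    )


def _spike_truth(contig: str) -> tuple[float, float] | None:
    cls = SPIKE_CONTIGS.get(contig)
    if cls == "mC":
        return 1.0, 0.0
    if cls == "hmC":
        return 0.0, 1.0
    if cls == "unmethylated":
        return 0.0, 0.0
    return None


def _convert_fragment(
    frag: str,
    contig: str,
    start: int,
    strand: str,  # 'OT' or 'OB'
    methylome: dict,
    hydroxymethylome: dict,
    config: SimulationConfig,
    rng: np.random.Generator,
    tab: bool = False,
    protection_rate: float = 0.98,
    mc_conversion_rate: float = 0.99,
) -> str:
    """Apply conversion chemistry to one fragment, forward representation.

    OT fragments convert C->T at top-strand cytosines; OB fragments show the
    bottom strand's C->T as G->A in forward representation.
    """
    chars = list(frag)
    target_base, converted_base, site_strand = (
        ("C", "T", "+") if strand == "OT" else ("G", "A", "-")
    )
    spike = _spike_truth(contig)
    for i, base in enumerate(chars):
        if base != target_base:
            continue
        pos = start + i
        if spike is not None:
            mc, hmc = spike
        else:
            key = (contig, pos, site_strand)
            mc = methylome.get(key, 0.0)
            hmc = hydroxymethylome.get(key, 0.0)
        if tab:
            p_keep = _retention_tab(
                mc, hmc, config.conversion_efficiency,
                protection_rate, mc_conversion_rate,
            )
        else:
            p_keep = _retention_bs(mc, hmc, config.conversion_efficiency)
        if rng.random() >= p_keep:
            chars[i] = converted_base
    return "".join(chars)


def _sample_fragment_locus(
    genome: GenomeSequence,
    targets: Sequence[Interval] | None,
    frag_len: int,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[str, int]:
    if targets and rng.random() >= config.off_target_fraction:
        weights = np.array([iv.length for iv in targets], dtype=float)
        iv = targets[int(rng.choice(len(targets), p=weights / weights.sum()))]
        lo = iv.start
        hi = iv.end - frag_len
        if hi < lo:  # target shorter than the fragment: clamp to contig
            lo = max(0, iv.end - frag_len)
            hi = min(iv.start, genome.length(iv.contig) - frag_len)
            hi = max(hi, lo)
        return iv.contig, int(rng.integers(lo, hi + 1))
    names = [n for n in genome if genome.length(n) >= frag_len]
    lens = np.array([genome.length(n) for n in names], dtype=float)
    contig = names[int(rng.choice(len(names), p=lens / lens.sum()))]
    return contig, int(rng.integers(0, genome.length(contig) - frag_len + 1))


def _apply_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    chars = list(seq)
    for i in range(len(chars)):
        if rng.random() < rate:
            chars[i] = str(rng.choice([b for b in "ACGT" if b != chars[i]]))
    return "".join(chars)


def _n_fragments(
    genome: GenomeSequence,
    targets: Sequence[Interval] | None,
    config: SimulationConfig,
) -> int:
    if targets:
        span = sum(iv.length for iv in targets)
        span = span / max(1.0 - config.off_target_fraction, 1e-9)
    else:
        span = genome.total_length
    return max(1, round(config.depth * span / (2 * config.read_length)))


def simulate_reads(
    parents: Sequence[GenomeSequence],
    methylome: dict,
    hydroxymethylome: dict,
    config: SimulationConfig,
    targets: Sequence[Interval] | None = None,
    rng: np.random.Generator | None = None,
    tab: bool = False,
    protection_rate: float = 0.98,
    mc_conversion_rate: float = 0.99,
    read_prefix: str = "frag",
) -> tuple[list[AlignedBsRead], dict]:
    """Paired-end bisulfite (or TAB-seq) reads with recorded parent origins.

    Fragments are drawn target-weighted (with ``off_target_fraction`` placed
    uniformly) or genome-wide when no targets are given, 50:50 from the
    parental haplotypes, with uniform fragment lengths and an original strand
    chosen fairly.  Mate 1 sequences the fragment's 5' end on the original
    strand, mate 2 the other end; both are reported in forward orientation
    at their true coordinates.  PCR duplicates are literal copies of already
    emitted fragments.
    """
    rng = rng if rng is not None else config.rng()
    parent_labels = (
        ["parent_a"] if len(parents) == 1 else ["parent_a", "parent_b"]
    )
    reads: list[AlignedBsRead] = []
    origins: dict = {}
    lo_f, hi_f = config.fragment_length_range
    rl = config.read_length
    n_frags = _n_fragments(parents[0], targets, config)
    fragments: list[tuple[str, list[AlignedBsRead]]] = []
    for i in range(n_frags):
        frag_len = int(rng.integers(lo_f, hi_f + 1))
        parent_idx = int(rng.integers(0, len(parents)))
        parent = parents[parent_idx]
        contig, start = _sample_fragment_locus(
            parent, targets, frag_len, config, rng
        )
        strand = "OT" if rng.random() < 0.5 else "OB"
        raw = parent[contig][start : start + frag_len]
        conv = _convert_fragment(
            raw, contig, start, strand, methylome, hydroxymethylome,
            config, rng, tab=tab,
            protection_rate=protection_rate,
            mc_conversion_rate=mc_conversion_rate,
        )
        rid = f"{read_prefix}{i:07d}"
        pair = []
        spans = [(start, start + min(rl, frag_len)),
                 (start + max(frag_len - rl, 0), start + frag_len)]
        for mate, (s, e) in enumerate(spans, start=1):
            seq = _apply_errors(conv[s - start : e - start],
                                config.sequencing_error, rng)
            pair.append(
                AlignedBsRead(
                    read_id=rid, mate=mate, contig=contig, start=s, end=e,
                    bisulfite_strand=strand, query_seq=seq,
                )
            )
        fragments.append((rid, pair))
        origins[rid] = parent_labels[parent_idx]
        reads.extend(pair)
    n_dups = round(config.duplicate_fraction * n_frags)
    if n_dups:
        picks = rng.choice(len(fragments), size=n_dups, replace=True)
        for j, pick in enumerate(picks):
            rid, pair = fragments[int(pick)]
            dup_id = f"{rid}_dup{j}"
            for r in pair:
                reads.append(replace(r, read_id=dup_id))
            origins[dup_id] = origins[rid]
    return reads, origins


def simulate_bs_reads(
    parents: Sequence[GenomeSequence],
    truth: TruthSet,
    config: SimulationConfig,
    targets: Sequence[Interval] | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[list[AlignedBsRead], TruthSet]:
    """Standard bisulfite reads; 5mC and 5hmC both resist conversion."""
    reads, origins = simulate_reads(
        parents, truth.methylome, truth.hydroxymethylome, config,
        targets=targets, rng=rng, tab=False,
    )
    return reads, replace_origins(truth, origins)


def simulate_tab_reads(
    parents: Sequence[GenomeSequence],
    truth: TruthSet,
    config: SimulationConfig,
    targets: Sequence[Interval] | None = None,
    rng: np.random.Generator | None = None,
    protection_rate: float = 0.98,
    mc_conversion_rate: float = 0.99,
) -> tuple[list[AlignedBsRead], TruthSet]:
    """TAB-seq reads: only 5hmC (glucosylated) resists conversion."""
    reads, origins = simulate_reads(
        parents, truth.methylome, truth.hydroxymethylome, config,
        targets=targets, rng=rng, tab=True,
        protection_rate=protection_rate,
        mc_conversion_rate=mc_conversion_rate,
        read_prefix="tab",
    )
    return reads, replace_origins(truth, origins)


def replace_origins(truth: TruthSet, origins: dict) -> TruthSet:
    merged = dict(truth.read_origins)
    merged.update(origins)
    return TruthSet(truth.methylome, truth.hydroxymethylome,
                    truth.snp_table, merged)


def simulate_experiment(
    config: SimulationConfig,
    targets: Sequence[Interval] | None = None,
    diploid: bool = False,
    hmc_fraction: float = 0.0,
) -> tuple[GenomeSequence, Sequence[GenomeSequence], TruthSet, list[AlignedBsRead]]:
    """One-call convenience pipeline: genome -> truth -> bisulfite reads."""
    rng = config.rng()
    genome = make_genome(config, rng)
    if diploid:
        pa, pb, snps = make_diploid(genome, config.snp_rate, rng)
        parents: Sequence[GenomeSequence] = (pa, pb)
    else:
        parents = (genome,)
        snps = []
    methylome, hydroxy = make_methylome(
        genome, config.methylome_params, rng, hmc_fraction=hmc_fraction
    )
    truth = TruthSet(methylome, hydroxy, snps, {})
    reads, truth = simulate_bs_reads(parents, truth, config, targets, rng)
    return genome, parents, truth, reads
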
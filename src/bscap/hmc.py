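"""TAB-seq 5hmC quantification and 5mC estimation by subtraction.

Standard bisulfite sequencing cannot separate 5-methylcytosine from
5-hydroxymethylcytosine: both resist conversion, so the unconverted fraction
reports their sum, 5(h)mC.  In TAB-seq, beta-glucosyltransferase protects
5hmC while Tet oxidation strips the 5mC signal, so only 5hmC remains
unconverted.  Per cytosine:

    5hmC level = unconverted fraction in TAB-seq
    5mC  level = unconverted fraction in BS-seq - unconverted fraction in TAB-seq

with negative 5mC estimates (sampling noise) clamped to zero and flagged.
Sites are reported only inside the capture targets and only where TAB-seq
depth reaches the coverage floor (default 10).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Sequence

from intervaltree import IntervalTree

from .calling import MethylationCall
from .core import UndefinedRateError
from .io import Interval


@dataclass(frozen=True)
class HydroxymethylCall:
    contig: str
    pos: int
    strand: str
    context: str
    bs_unconverted: float | None
    tab_unconverted: float
    hmc_level: float
    mc_level: float | None
    coverage_bs: int
    coverage_tab: int
    mc_clamped: bool = False


def _index_calls(calls: Iterable[MethylationCall]) -> dict:
    return {
        (c.site.contig, c.site.pos, c.site.strand): c
        for c in calls
    }


def hmc_quantify(
    tab_calls: Sequence[MethylationCall],
    bs_calls: Sequence[MethylationCall],
    targets: Sequence[Interval],
    min_coverage: int = 10,
    min_coverage_bs: int | None = None,
    contexts: tuple[str, ...] = ("CG",),
) -> list[HydroxymethylCall]:
    """Combine TAB-seq and BS-seq calls into per-site 5hmC / 5mC estimates.

    ``min_coverage`` applies to TAB-seq depth; BS-seq depth uses
    ``min_coverage_bs`` (defaults to the same).  A site covered in TAB-seq
    but absent/undercovered in BS-seq still reports its 5hmC level, with the
    5mC estimate left undefined.  Context defaults to CG only.
    """
    if min_coverage_bs is None:
        min_coverage_bs = min_coverage
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for iv in targets:
        trees[iv.contig].addi(iv.start, iv.end)
    bs = _index_calls(bs_calls)
    out: list[HydroxymethylCall] = []
    for t in tab_calls:
        site = t.site
        if contexts and site.context not in contexts:
            continue
        if site.contig not in trees or not trees[site.contig].overlaps(site.pos):
            continue
        if t.total < min_coverage:
            continue
        tab_frac = t.methylated / t.total  # unconverted = protected 5hmC
        b = bs.get((site.contig, site.pos, site.strand))
        if b is not None and b.total >= min_coverage_bs:
            bs_frac = b.methylated / b.total
            mc = bs_frac - tab_frac
            clamped = mc < 0
            mc_level = max(mc, 0.0)
            cov_bs = b.total
        else:
            bs_frac = None
            mc_level = None
            clamped = False
            cov_bs = 0 if b is None else b.total
        out.append(
            HydroxymethylCall(
                contig=site.contig, pos=site.pos, strand=site.strand,
                context=site.context,
                bs_unconverted=bs_frac, tab_unconverted=tab_frac,
                hmc_level=tab_frac, mc_level=mc_level,
                coverage_bs=cov_bs, coverage_tab=t.total,
                mc_clamped=clamped,
            )
        )
    return out


@dataclass(frozen=True)
class SpikeInEfficiency:
    conversion_rate: float | None  # unmethylated control: C fully converts
    mc_removal_rate: float | None  # mC control: oxidation + conversion
    hmc_protection_rate: float | None  # hmC control: stays C


def spikein_efficiency(
    control_calls: dict[str, Sequence[tuple[int, int]]],
) -> SpikeInEfficiency:
    """Per-class efficiency from spike-in controls.

    ``control_calls`` maps class name ('unmethylated', 'mC', 'hmC') to
    (converted_count, total_count) tuples.  The unmethylated and mC classes
    report the fraction converted (for mC this is oxidation followed by
    conversion); the hmC class reports the protection rate, i.e. the fraction
    left unconverted.
    """
    def rate(cls: str) -> float | None:
        calls = control_calls.get(cls)
        if calls is None:
            return None
        conv = sum(c for c, _ in calls)
        tot = sum(t for _, t in calls)
        if tot == 0:
            raise UndefinedRateError(f"spike-in control {cls!r} has no coverage")
        return conv / tot

    missing = [c for c in ("unmethylated", "mC", "hmC") if c not in control_calls]
    if missing:
        raise KeyError(f"missing spike-in control classes: {missing}")
    conv = rate("unmethylated")
    mc = rate("mC")
    hmc_conv = rate("hmC")
    return SpikeInEfficiency(
        conversion_rate=conv,
        mc_removal_rate=mc,
        hmc_protection_rate=None if hmc_conv is None else 1.0 - hmc_conv,
    )
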
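"""Methylation-based target-region taxonomy for a two-genotype design.

Target regions compared between two inbred genotypes (a B73-like genotype A
and a Mo17-like genotype B) fall into two major groups: regions without
methylation differences — further split into uniformly high (``all_high``),
uniformly unmethylated (``all_low``) and context-dependent classes — and
differentially methylated regions (DMRs) typed by the context (CG, CHG or
CHH) that differs.  The non-DMR rules, with levels on a 0-1 scale per
context and genotype:

* ``all_high``: summed level across the three contexts and both genotypes
  >= 4.2, coverage >= 85% in both genotypes.
* ``all_low``: every context effectively unmethylated in both genotypes
  (default < 0.05), coverage >= 90%.
* ``context_dependent_X``: context X high in both genotypes (CG > 0.95,
  CHG > 0.2 or CHH > 0.75) with the other contexts < 0.2 in both, coverage
  >= 80%.

A region may be a DMR in more than one context.  Coverage is the fraction of
the region's context cytosines with at least one read.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

CONTEXTS = ("CG", "CHG", "CHH")

NON_DMR_LABELS = (
    "all_high",
    "all_low",
    "context_dependent_CG",
    "context_dependent_CHG",
    "context_dependent_CHH",
)


@dataclass(frozen=True)
class RegionSummary:
    contig: str
    start: int
    end: int
    genotype: str
    level: dict[str, float]  # context -> mean level in [0, 1]
    coverage_fraction: float

    def __post_init__(self) -> None:
        for ctx in CONTEXTS:
            if ctx not in self.level:
                raise ValueError(f"missing {ctx} level for {self.genotype}")
            if not 0.0 <= self.level[ctx] <= 1.0:
                raise ValueError(f"{ctx} level outside [0,1]")
        if not 0.0 <= self.coverage_fraction <= 1.0:
            raise ValueError("coverage_fraction outside [0,1]")


@dataclass(frozen=True)
class ClassifyParams:
    all_high_sum: float = 4.2
    all_high_coverage: float = 0.85
    all_low_level: float = 0.05
    all_low_coverage: float = 0.90
    context_high: dict[str, float] = field(
        default_factory=lambda: {"CG": 0.95, "CHG": 0.2, "CHH": 0.75}
    )
    context_other_max: float = 0.2
    context_coverage: float = 0.80
    dmr_min_difference: float = 0.4


@dataclass(frozen=True)
class RegionClass:
    labels: tuple[str, ...]  # one non-DMR label, or >=1 DMR labels, or unclassified
    supporting_values: dict

    @property
    def label(self) -> str:
        return self.labels[0]


def call_dmr(
    summary_a: RegionSummary,
    summary_b: RegionSummary,
    context: str,
    min_difference: float = 0.4,
) -> bool:
    """Is the region differentially methylated in this context?"""
    return abs(summary_a.level[context] - summary_b.level[context]) >= min_difference


def classify_region(
    summary_a: RegionSummary,
    summary_b: RegionSummary,
    params: ClassifyParams | None = None,
) -> RegionClass:
    """Classify one region from its two genotype summaries.

    Non-DMR classes are tested first (a region without differences by
    construction cannot be a DMR at any meaningful threshold); failing all
    of them, the region is typed as a DMR in every context whose levels
    differ by at least ``dmr_min_difference``, else unclassified.
    Inequalities are exactly as stated in the class definitions: the
    all_high sum and all coverages are inclusive, context-high thresholds
    strict, "lower in other contexts" strict.
    """
    params = params or ClassifyParams()
    a, b = summary_a, summary_b
    support = {
        "level_a": dict(a.level),
        "level_b": dict(b.level),
        "coverage_a": a.coverage_fraction,
        "coverage_b": b.coverage_fraction,
    }
    total = sum(a.level[c] for c in CONTEXTS) + sum(b.level[c] for c in CONTEXTS)
    support["summed_level"] = total
    min_cov = min(a.coverage_fraction, b.coverage_fraction)

    # inclusive boundary with float-sum tolerance (six addends of ~1e-1 scale)
    if total >= params.all_high_sum - 1e-9 and min_cov >= params.all_high_coverage:
        return RegionClass(("all_high",), support)
    if (
        all(a.level[c] < params.all_low_level for c in CONTEXTS)
        and all(b.level[c] < params.all_low_level for c in CONTEXTS)
        and min_cov >= params.all_low_coverage
    ):
        return RegionClass(("all_low",), support)
    for ctx in CONTEXTS:
        others = [c for c in CONTEXTS if c != ctx]
        if (
            a.level[ctx] > params.context_high[ctx]
            and b.level[ctx] > params.context_high[ctx]
            and all(a.level[o] < params.context_other_max for o in others)
            and all(b.level[o] < params.context_other_max for o in others)
            and min_cov >= params.context_coverage
        ):
            return RegionClass((f"context_dependent_{ctx}",), support)
    dmr_labels = tuple(
        f"dmr_{ctx}" for ctx in CONTEXTS
        if call_dmr(a, b, ctx, params.dmr_min_difference)
    )
    if dmr_labels:
        return RegionClass(dmr_labels, support)
    return RegionClass(("unclassified",), support)


@dataclass(frozen=True)
class PlatformConcordance:
    n: int
    correlation: float
    mean_absolute_deviation: float


def compare_platforms(
    wgbs_differences: dict,
    capture_differences: dict,
    dmr_list: Sequence,
) -> PlatformConcordance:
    """Concordance of methylation differences between two platforms at DMRs.

    Both inputs map a region key to the genotype-A-minus-genotype-B level
    difference measured by that platform; Pearson correlation and mean
    absolute deviation over the shared DMR keys are reported.
    """
    keys = [k for k in dmr_list if k in wgbs_differences and k in capture_differences]
    if not keys:
        raise ValueError("no DMRs measured by both platforms")
    w = np.array([wgbs_differences[k] for k in keys], dtype=float)
    c = np.array([capture_differences[k] for k in keys], dtype=float)
    if len(keys) < 2 or w.std() == 0 or c.std() == 0:
        corr = float("nan")
    else:
        corr = float(np.corrcoef(w, c)[0, 1])
    return PlatformConcordance(
        n=len(keys),
        correlation=corr,
        mean_absolute_deviation=float(np.abs(w - c).mean()),
    )
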
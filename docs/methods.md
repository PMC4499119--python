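# Methods

This note records the models, conventions and numerical choices behind
`bscap`, in the order data flows through the toolkit.

## Conversion model and contexts

Bisulfite treatment converts unmethylated cytosine to uracil (read as T);
5-methylcytosine and 5-hydroxymethylcytosine resist conversion.  In silico
conversion is applied to a sequence in its own 5'→3' orientation, so a
single rule serves both strands: under the *no-CG-methylated* assumption
every C becomes T; under *all-CG-methylated* only Cs immediately followed by
G are preserved.  Bottom-strand windows are reverse-complemented before the
rule and the result kept in bottom-strand orientation, which is the sequence
a probe or fragment from that strand actually presents.

Cytosine contexts (CG, CHG, CHH; H = A, T or C) are read downstream in the
cytosine's own strand.  Two degenerate cases produce no call and are
labelled `edge`: fewer than the required downstream bases at a contig end,
and an N anywhere in the context window.  Both are excluded from summaries;
the ambiguity cannot be resolved from the reference.

Allele enumeration counts **all** strand cytosines as potentially methylated
by default, because non-CG methylation is substantial in plant genomes; a
CG-only mode is exposed for mammalian-style analyses.  The count is always
2ⁿ; materialised alleles are verified distinct in tests against exhaustive
enumeration up to n = 12.

## Probe design

Candidates are tiled every 5 bp across each target, in all four strand ×
CG-assumption states.  *Length policy*: the probe grows from its tiled start
in 1 bp steps (50–100 nt) until its melting temperature enters a band,
default 68–73 °C; if the band is unreachable the length closest to the band
centre is used.  Tm is the only stated probe property that length can tune,
which is why length is slaved to it.  The default Tm model is the GC-content
formula Tm = 64.9 + 41·(nGC − 16.4)/L — the standard long-oligo
approximation, adequate for ranking 50–100-mers; a Wallace-rule option
exists for comparison.  Tm of a converted prefix is computed incrementally
from cumulative G/C/CG-pair counts of the raw window (CG dinucleotides are
palindromic, so the bottom strand's protected-CG count equals the top's),
keeping candidate generation linear in target size.

*Repetitiveness*: the 15-mer table is built from the fully converted
(no-CG-methylated) genome — the worst case, since the converted alphabet is
effectively three letters — over both strands, with strand-symmetric
(canonical) keys: a k-mer and its reverse complement are counted together,
because amplification of a converted library produces both complements of
every converted strand.  A probe's repeat score is the arithmetic mean of
its k-mers' counts; removal requires a mean strictly greater than 10 000
(scaled down in tests on kilobase genomes, where the default is pinned but
unreachable).

*Uniqueness*: the number of genomic locations matching the converted probe
under bisulfite-asymmetric rules — probe T matches genome C or T; A, C, G
must match exactly — scanning both genome strands.  Matching is exact; a
mismatch budget is configurable but defaults to 0, which is appropriate at
the genome sizes this implementation targets (an index-based aligner would
be needed for gigabase genomes).  Probes mapping to more than 3 locations
are discarded.

*Ranking and selection*: the rank score is an equal-weighted sum of min-max
normalised, lower-is-better components — |Tm − band centre|, repeat score,
uniqueness, homopolymer run length — so the score strictly improves as any
component improves; weights are configurable.  Selection walks each target
in 15 bp windows separated by 20 bp gaps (with 5 bp tiling, 3 candidate
starts per window), keeps the best-ranked surviving candidate per window,
and breaks ties by lowest start then longest probe, for determinism.
Windows restart at each target rather than running genome-wide; empty
windows are logged as gaps.

## Methylation calling

Reads arrive pre-aligned (the simulator emits true coordinates; alignment is
out of scope) in a SAM-like tabular dialect, sequence stored in
reference-forward orientation with an original-strand tag: OT reads inform
top-strand cytosines (reference C, read C = methylated / T = converted), OB
reads inform bottom-strand cytosines (reference G, read G / A in forward
representation).  The first 2 aligned bases of each mate are ignored —
mate 1's 5' end sits at the left reference coordinate for OT fragments and
the right for OB, mate 2 the reverse — and positions covered by both mates
are counted once (mate 1 wins).  Read bases other than the
methylated/converted pair at a cytosine (sequencing error or SNP) are
ignored rather than counted unmethylated, to avoid SNP-induced bias.

Duplicate marking operates on fragments: mates grouped by read id, keyed by
contig, outer start/end, original strand and (by default) the concatenated
per-mate methylation pattern, so fragments with identical coordinates but
different methylation survive as distinct molecules.  A coordinate-only mode
reproduces conventional deduplication.  Marking is idempotent and
order-independent given coordinate sorting.

Capture QC: on-target rate counts reads overlapping a target by ≥ 1 bp, no
padding; coverage statistics are per-base over all target bases, zero-depth
bases included by default (a flag restricts to covered bases, since
published summaries are ambiguous on this point), with duplicates excluded
and mate overlaps clipped; fold enrichment is the base-ratio definition
(on-target aligned bases / target size) ÷ (aligned bases / genome size) — a
documented simplification of hybrid-selection metrics tools, which add
many refinements that need base qualities we do not model.

The mixture-bias check mirrors pooling an untreated and a fully methylated
sample in equal proportions: each molecule comes from either parent with
probability ½, so a site's expected mixture level is the average of the two
parent levels.  The statistic is total-variation distance between the
observed mixture histogram (20 bins) and the histogram of per-site averages;
"within resampling error" is judged against the 95th percentile of a
Monte-Carlo null that regenerates mixture levels at each site's observed
depth (parent split Binomial(n, ½), read outcomes binomial from each parent
level).

## Allele-specific analysis

De novo SNP candidates are filtered at quality ≥ 20 and coverage ≤ 120;
candidates within 20 bp of another candidate (inclusive) are removed, both
members of a close pair, with proximity evaluated over the full candidate
list.  The consensus list is the intersection of a catalog and the filtered
de novo calls, requiring allele agreement (order-insensitive; parental phase
follows the catalog) and dropping conflicts with a warning.

A SNP is informative on a given strand when the converted readout sets of
its two alleles are disjoint: on OT reads C reads as {C, T}, so C/T SNPs are
blind there; on OB reads G reads as {G, A}, blinding G/A SNPs; every other
pair stays distinguishable.  Assignment counts votes over informative SNPs
only: 0 votes → no information; 1 vote → that parent; more → the parent
with strictly > 60 % support, else ambiguous (so 3-of-5 is ambiguous,
2-of-3 assigns).  Read bases matching neither readout do not vote.
SNP-less reads inherit their mate's parental verdict (flagged `via_mate`);
ambiguous mates do not propagate, and mates with conflicting parental
verdicts are both demoted to ambiguous — the conflict is itself evidence
against a clean assignment.

## TAB-seq

In TAB-seq, β-glucosyltransferase protects 5hmC and Tet oxidation removes
the 5mC signal, so only 5hmC remains unconverted.  Per cytosine: 5hmC = TAB
unconverted fraction; 5mC = BS unconverted − TAB unconverted.  Negative 5mC
estimates (sampling noise) are clamped to zero and flagged rather than
dropped.  The depth filter (default ≥ 10) is applied per cytosine to TAB
depth — the published description oscillates between regions and cytosines,
and per-cytosine is the stricter, simpler reading; a separate BS threshold
defaults to the same value.  Output is restricted to CpGs inside the capture
targets by default.  Spike-in controls of known class report conversion
rate (unmethylated), removal rate (5mC) and protection rate (5hmC).

## Simulator

The simulator is first-class code, not a fixture: every quantity the
toolkit measures can be generated with recorded truth.  Defaults encode the
assay's stated conditions — 180–220 bp fragments, 100 bp paired-end reads,
conversion efficiency 0.998 — and a plant-like methylome: CG and CHG levels
from high/low beta mixtures (CG: 70 % from Beta(20, 1.5), else Beta(1, 30);
CHG: 60 % from Beta(12, 2)), CHH from Beta(1.2, 14) (mean ≈ 0.08).  These
mixture parameters are the package's own choice of a realistic bimodal
methylome; no published values exist at this granularity.  Diploid parents
differ at Poisson(rate·L) SNPs, by default A↔T substitutions at reference
A/T positions so every SNP stays informative on both strands and the two
parents share one cytosine complement.  Fragments are drawn 50:50 from the
parents, target-weighted with a configurable off-target fraction, converted
base-by-base (a cytosine survives as C with probability
level + (1 − level)(1 − efficiency); TAB-seq uses
hmC·protection + mC·(1 − removal) + unmodified·(1 − efficiency)), and PCR
duplicates are injected as literal copies.  Sequencing error is off by
default and configurable as a uniform substitution rate.

What the simulator does **not** emulate: alignment and mapping error
(reads carry true coordinates), indels, base-quality profiles, capture
hybridisation thermodynamics and GC bias, and PCR errors other than literal
duplication.  Passing parameter-recovery tests therefore demonstrates the
correctness of the calling and assignment arithmetic under the stated noise
model, not robustness to alignment artefacts in real libraries.

## Region classification

Inequalities follow the stated rules exactly: the `all_high` sum (≥ 4.2
across 3 contexts × 2 genotypes) and all coverage floors are inclusive;
context-high thresholds (CG > 0.95, CHG > 0.2, CHH > 0.75) and the
other-context ceiling (< 0.2) are strict.  The inclusive sum comparison
carries a 1e-9 tolerance because the sum of six float levels (e.g. 6 × 0.7)
can fall a few ulps short of its nominal value.  "Unmethylated" for
`all_low` is quantified as every context < 0.05 (no published number;
configurable).  Non-DMR classes are tested first, in the order all_high →
all_low → context-dependent; a region failing all of them is typed as a DMR
in every context whose levels differ by ≥ 0.4 (default; no published
threshold exists, and 0.4 separates clear biological differences from
binomial noise at depth ≥ 20), else unclassified.  Coverage fraction is the
fraction of the region's context cytosines with at least one read.
Classification is symmetric under genotype exchange, and a pure-CHH
context-dependent class is permitted even though such regions may not occur
in real data.

## Problem sizes

Tests and examples run on genomes of 3–100 kb at depths 8–100, sizes at
which every brute-force oracle (k-mer scans, sliding-window mapping,
exhaustive allele enumeration) is exact and fast and the whole suite
completes in well under a minute.  All randomness flows from explicit seeds;
fixed seeds reproduce reads and files byte for byte.
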
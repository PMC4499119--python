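"""Classify target regions by methylation pattern across two genotypes.

Builds region summaries straddling the class thresholds and prints the label
each receives: uniformly high (summed level >= 4.2, coverage >= 85%),
uniformly unmethylated (coverage >= 90%), context-dependent (CG > 0.95,
CHG > 0.2 or CHH > 0.75 with other contexts < 0.2), or a DMR typed by the
differing context.
"""

from bscap import RegionSummary, classify_region


def summary(genotype, cg, chg, chh, cov):
    return RegionSummary("chr1", 0, 1000, genotype,
                         {"CG": cg, "CHG": chg, "CHH": chh}, cov)


cases = [
    ("dense heterochromatin-like", summary("B73", 0.98, 0.9, 0.8, 0.95),
     summary("Mo17", 0.96, 0.88, 0.75, 0.93)),
    ("unmethylated promoter-like", summary("B73", 0.01, 0.02, 0.01, 0.95),
     summary("Mo17", 0.02, 0.01, 0.01, 0.96)),
    ("CG gene-body-like", summary("B73", 0.99, 0.1, 0.05, 0.85),
     summary("Mo17", 0.97, 0.12, 0.06, 0.88)),
    ("CG+CHG difference", summary("B73", 0.9, 0.8, 0.05, 0.9),
     summary("Mo17", 0.1, 0.2, 0.05, 0.9)),
    ("boundary: sum exactly 4.2", summary("B73", 0.7, 0.7, 0.7, 0.95),
     summary("Mo17", 0.7, 0.7, 0.7, 0.95)),
]
for name, a, b in cases:
    cls = classify_region(a, b)
    print(f"{name:>28}: {','.join(cls.labels):<24} "
          f"(summed level {cls.supporting_values['summed_level']:.2f})")
# The summed-level rule is inclusive (>= 4.2); context-dependent thresholds
# are strict (CG > 0.95), and a region may be a DMR in several contexts.
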
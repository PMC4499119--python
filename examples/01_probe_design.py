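"""Design bisulfite capture probes for a synthetic target.

Builds a 10 kb random genome, designs probes for a 2 kb target, and prints
the size and score summary of the four panels (two strands x two CG
methylation assumptions).  Every surviving probe has a mean 15-mer genome
frequency <= 10 000 and maps to at most 3 genomic locations.
"""

import numpy as np

from bscap import DesignParams, Interval, design_probes
from bscap.simulate import SimulationConfig, make_genome

genome = make_genome(SimulationConfig(genome_length=10_000, control_length=0,
                                      seed=7))
targets = [Interval("chr1", 1_000, 3_000)]
panels, audit = design_probes(genome, targets, DesignParams())

print(f"candidates generated: {audit['candidates']}")
print(f"removed (repeat/uniqueness): {audit['removed_repeat']}"
      f"/{audit['removed_uniqueness']}")
for state, panel in panels.items():
    tms = [p.tm for p in panel]
    print(f"{state.name:>28}: {len(panel):3d} probes, "
          f"mean length {np.mean([p.length for p in panel]):.1f} nt, "
          f"Tm {np.mean(tms):.1f} C")
# One probe per 15 bp selection window (windows spaced 20 bp apart); probe
# length is grown from 50 nt until the melting temperature enters 68-73 C.
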
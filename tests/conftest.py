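import numpy as np
import pytest

from bscap.core import GenomeSequence
from bscap.io import Interval
from bscap.simulate import SimulationConfig, make_genome


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_genome():
    """10 kb random genome plus a 4 kb unmethylated control contig."""
    cfg = SimulationConfig(genome_length=10_000, control_length=4_000, seed=42)
    return make_genome(cfg)


@pytest.fixture(scope="session")
def small_targets():
    return [Interval("chr1", 1_000, 3_000), Interval("chr1", 6_000, 8_000)]


def _random_seq(n, rng, gc=0.45):
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=n, p=p))


@pytest.fixture(scope="session")
def engineered_genome():
    """Genome with known 2x/3x/4x-copy segments and a high-copy 15-mer repeat.

    Layout on one contig: unique backbone with an 80 bp segment inserted at
    2, 3 and 4 copies respectively (three distinct segments), plus a tandem
    repeat of a single 15-mer, so uniqueness and repeat-score filters have
    known ground truth.
    """
    rng = np.random.default_rng(777)
    seg2 = _random_seq(80, rng)
    seg3 = _random_seq(80, rng)
    seg4 = _random_seq(80, rng)
    unit = "ACGGATTACAGGCAT"  # repeated 15-mer
    parts = [_random_seq(400, rng)]
    for seg, copies in ((seg2, 2), (seg3, 3), (seg4, 4)):
        for _ in range(copies):
            parts.append(seg)
            parts.append(_random_seq(300, rng))
    parts.append(unit * 60)  # 900 bp tandem repeat
    parts.append(_random_seq(400, rng))
    seq = "".join(parts)
    genome = GenomeSequence({"chr1": seq})
    # locate the inserted copies for tests
    coords = {
        "seg2": seg2,
        "seg3": seg3,
        "seg4": seg4,
        "repeat_start": seq.index(unit * 60),
        "repeat_end": seq.index(unit * 60) + 900,
    }
    return genome, coords
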
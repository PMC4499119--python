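"""Simulator determinism, distributional shape and end-to-end recovery."""

import numpy as np
import pytest

from bscap.calling import call_methylation, on_target_rate
from bscap.core import conversion_rate, iter_cytosine_sites
from bscap.io import Interval
from bscap.simulate import (
    CONTROL_CONTIG,
    MethylomeParams,
    SimulationConfig,
    TruthSet,
    make_diploid,
    make_genome,
    make_methylome,
    make_spikein_contigs,
    set_region_levels,
    simulate_bs_reads,
    simulate_experiment,
    simulate_reads,
)


class TestGenome:
    def test_deterministic_under_seed(self):
        cfg = SimulationConfig(seed=1)
        assert make_genome(cfg).contigs == make_genome(cfg).contigs

    def test_gc_content(self):
        cfg = SimulationConfig(genome_length=100_000, gc_content=0.5,
                               control_length=0, seed=2)
        seq = make_genome(cfg)["chr1"]
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        assert abs(gc - 0.5) < 3 * np.sqrt(0.25 / 100_000)

    def test_zero_length_errors(self):
        with pytest.raises(ValueError):
            make_genome(SimulationConfig(genome_length=0))

    def test_control_contig_present(self):
        genome = make_genome(SimulationConfig(seed=3))
        assert CONTROL_CONTIG in genome


class TestDiploid:
    def test_snp_count_poisson(self):
        cfg = SimulationConfig(genome_length=100_000, control_length=0, seed=4)
        genome = make_genome(cfg)
        _, _, snps = make_diploid(genome, 0.001, cfg.rng())
        assert abs(len(snps) - 100) < 4 * np.sqrt(100)

    def test_avoid_cg_mode_gives_at_snps(self):
        cfg = SimulationConfig(genome_length=50_000, control_length=0, seed=5)
        genome = make_genome(cfg)
        _, parent_b, snps = make_diploid(genome, 0.002, cfg.rng())
        assert snps
        for s in snps:
            assert {s.allele_a, s.allele_b} <= {"A", "T"}
            assert parent_b["chr1"][s.pos] == s.allele_b
            assert genome["chr1"][s.pos] == s.allele_a

    def test_same_seed_same_table(self):
        cfg = SimulationConfig(genome_length=20_000, control_length=0, seed=6)
        genome = make_genome(cfg)
        s1 = make_diploid(genome, 0.002, cfg.rng())[2]
        s2 = make_diploid(genome, 0.002, cfg.rng())[2]
        assert s1 == s2


@pytest.fixture(scope="module")
def methylome():
    cfg = SimulationConfig(genome_length=60_000, seed=7)
    genome = make_genome(cfg)
    mc, hmc = make_methylome(genome, MethylomeParams(), cfg.rng())
    return genome, mc, hmc


class TestMethylome:
    def test_cg_bimodal(self, methylome):
        genome, mc, _ = methylome
        cg = [mc[(s.contig, s.pos, s.strand)]
              for s in iter_cytosine_sites(genome, "chr1") if s.context == "CG"]
        cg = np.array(cg)
        # a bimodal high/low mixture leaves few sites near the middle
        mid = ((cg > 0.3) & (cg < 0.7)).mean()
        assert mid < 0.15
        assert (cg > 0.7).mean() > 0.3 and (cg < 0.3).mean() > 0.1

    def test_chh_lower_than_cg(self, methylome):
        genome, mc, _ = methylome
        by_ctx = {"CG": [], "CHG": [], "CHH": []}
        for s in iter_cytosine_sites(genome, "chr1"):
            by_ctx[s.context].append(mc[(s.contig, s.pos, s.strand)])
        assert np.mean(by_ctx["CHH"]) < np.mean(by_ctx["CG"])
        assert np.mean(by_ctx["CHH"]) < np.mean(by_ctx["CHG"])

    def test_control_unmethylated(self, methylome):
        genome, mc, _ = methylome
        ctrl = [mc[(s.contig, s.pos, s.strand)]
                for s in iter_cytosine_sites(genome, CONTROL_CONTIG)]
        assert ctrl and all(v == 0.0 for v in ctrl)

    def test_hmc_disabled_by_default(self, methylome):
        _, _, hmc = methylome
        assert hmc == {}

    def test_set_region_levels(self, methylome):
        genome, mc, _ = methylome
        region = Interval("chr1", 100, 600)
        out = set_region_levels(mc, genome, region, {"CG": 0.9, "CHG": 0.9,
                                                     "CHH": 0.9})
        for s in iter_cytosine_sites(genome, "chr1"):
            if 100 <= s.pos < 600:
                assert out[(s.contig, s.pos, s.strand)] == 0.9


class TestReads:
    def test_fully_methylated_truth_keeps_cs(self):
        cfg = SimulationConfig(genome_length=3_000, control_length=0,
                               depth=5.0, conversion_efficiency=1.0, seed=8)
        genome = make_genome(cfg)
        mc = {(s.contig, s.pos, s.strand): 1.0
              for s in iter_cytosine_sites(genome, include_edge=True)}
        reads, _ = simulate_reads((genome,), mc, {}, cfg)
        for r in reads[:50]:
            ref = genome[r.contig][r.start:r.end]
            assert r.query_seq == ref

    def test_conversion_rate_recovered_on_control(self):
        cfg = SimulationConfig(genome_length=1_000, control_length=20_000,
                               depth=30.0, seed=9)
        genome = make_genome(cfg)
        truth = TruthSet({}, {}, [], {})
        targets = [Interval(CONTROL_CONTIG, 0, 20_000)]
        reads, _ = simulate_bs_reads((genome,), truth, cfg, targets=targets)
        calls = call_methylation(reads, genome)
        ctrl = [(c.unmethylated, c.total) for c in calls
                if c.site.contig == CONTROL_CONTIG]
        rate = conversion_rate(ctrl)
        total = sum(t for _, t in ctrl)
        assert abs(rate - 0.998) < 3 * np.sqrt(0.998 * 0.002 / total)

    def test_depth_approximates_request(self):
        cfg = SimulationConfig(genome_length=10_000, control_length=0,
                               depth=30.0, seed=10)
        genome = make_genome(cfg)
        targets = [Interval("chr1", 2_000, 4_000)]
        reads, _ = simulate_reads((genome,), {}, {}, cfg, targets=targets)
        bases = sum(r.end - r.start for r in reads)
        assert bases / 2_000 == pytest.approx(30.0, rel=0.15)

    def test_reads_from_targets_always_on_target(self):
        cfg = SimulationConfig(genome_length=10_000, control_length=0,
                               depth=10.0, off_target_fraction=0.0, seed=11)
        genome = make_genome(cfg)
        targets = [Interval("chr1", 1_000, 3_000)]
        reads, _ = simulate_reads((genome,), {}, {}, cfg, targets=targets)
        assert on_target_rate(reads, targets) == 1.0

    def test_byte_identical_reads_under_seed(self):
        cfg = SimulationConfig(genome_length=5_000, control_length=0,
                               depth=5.0, seed=12)
        genome = make_genome(cfg)
        r1, _ = simulate_reads((genome,), {}, {}, cfg)
        r2, _ = simulate_reads((genome,), {}, {}, cfg)
        assert r1 == r2

    def test_duplicate_injection(self):
        cfg = SimulationConfig(genome_length=5_000, control_length=0,
                               depth=10.0, duplicate_fraction=0.1, seed=13)
        genome = make_genome(cfg)
        reads, origins = simulate_reads((genome,), {}, {}, cfg)
        dup_ids = {r.read_id for r in reads if "_dup" in r.read_id}
        assert dup_ids
        assert all(rid in origins for rid in dup_ids)

    def test_f1_mixing_balanced(self):
        cfg = SimulationConfig(genome_length=20_000, control_length=0,
                               depth=10.0, seed=14)
        genome, parents, truth, reads = simulate_experiment(cfg, diploid=True)
        counts = np.array([
            sum(1 for v in truth.read_origins.values() if v == "parent_a"),
            sum(1 for v in truth.read_origins.values() if v == "parent_b"),
        ])
        n = counts.sum()
        assert abs(counts[0] / n - 0.5) < 3 * np.sqrt(0.25 / n)


class TestSpikeins:
    def test_tab_chemistry_on_spikeins(self):
        from bscap.hmc import spikein_efficiency
        from bscap.simulate import SPIKE_CONTIGS

        rng = np.random.default_rng(15)
        spikes = make_spikein_contigs(3_000, 0.45, rng)
        cfg = SimulationConfig(genome_length=3_000, control_length=0,
                               depth=30.0, conversion_efficiency=0.998, seed=16)
        reads, _ = simulate_reads((spikes,), {}, {}, cfg, tab=True,
                                  protection_rate=0.98, mc_conversion_rate=0.99)
        calls = call_methylation(reads, spikes)
        grouped = {cls: [] for cls in ("unmethylated", "mC", "hmC")}
        for c in calls:
            grouped[SPIKE_CONTIGS[c.site.contig]].append(
                (c.unmethylated, c.total))
        eff = spikein_efficiency(grouped)
        assert eff.conversion_rate == pytest.approx(0.998, abs=0.01)
        assert eff.mc_removal_rate == pytest.approx(0.99, abs=0.01)
        assert eff.hmc_protection_rate == pytest.approx(0.98, abs=0.01)


class TestEndToEndRegions:
    def test_simulate_call_classify_recovers_truth_classes(self):
        """Regions built >=0.1 from every class boundary round-trip exactly."""
        from collections import defaultdict

        from bscap.regions import RegionSummary, classify_region

        cfg = SimulationConfig(genome_length=12_000, control_length=0,
                               depth=40.0, seed=17)
        genome = make_genome(cfg)
        specs = [
            (Interval("chr1", 0, 3_000), {"CG": 0.95, "CHG": 0.9, "CHH": 0.85},
             "all_high"),
            (Interval("chr1", 3_000, 6_000), {"CG": 0.0, "CHG": 0.0, "CHH": 0.0},
             "all_low"),
            (Interval("chr1", 6_000, 9_000), {"CG": 1.0, "CHG": 0.05, "CHH": 0.05},
             "context_dependent_CG"),
            (Interval("chr1", 9_000, 12_000), {"CG": 0.5, "CHG": 0.1, "CHH": 0.05},
             None),  # truth differs per genotype below: a CG DMR
        ]
        mc = {}
        for region, levels, _ in specs:
            mc = set_region_levels(mc, genome, region, levels)
        mc_b = set_region_levels(mc, genome, specs[3][0],
                                 {"CG": 0.0, "CHG": 0.1, "CHH": 0.05})
        reads_a, _ = simulate_reads((genome,), mc, {}, cfg,
                                    rng=np.random.default_rng(18))
        reads_b, _ = simulate_reads((genome,), mc_b, {}, cfg,
                                    rng=np.random.default_rng(19))
        calls = {"A": call_methylation(reads_a, genome),
                 "B": call_methylation(reads_b, genome)}

        def summarize(genotype, region):
            per_ctx = defaultdict(list)
            n_sites = defaultdict(int)
            covered = defaultdict(int)
            for s in iter_cytosine_sites(genome, "chr1"):
                if region.start <= s.pos < region.end:
                    n_sites[s.context] += 1
            for c in calls[genotype]:
                if (region.start <= c.site.pos < region.end
                        and c.site.context != "edge" and c.total > 0):
                    per_ctx[c.site.context].append(c.level)
                    covered[c.site.context] += 1
            level = {ctx: float(np.mean(per_ctx[ctx])) if per_ctx[ctx] else 0.0
                     for ctx in ("CG", "CHG", "CHH")}
            cov = sum(covered.values()) / max(sum(n_sites.values()), 1)
            return RegionSummary(region.contig, region.start, region.end,
                                 genotype, level, min(cov, 1.0))

        expected = ["all_high", "all_low", "context_dependent_CG", "dmr_CG"]
        for (region, _, _), want in zip(specs, expected):
            cls = classify_region(summarize("A", region), summarize("B", region))
            assert want in cls.labels, (region, want, cls)
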
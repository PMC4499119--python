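"""Probe tiling, scoring, filtering and window selection."""

from collections import Counter

import pytest

from bscap.core import (
    GenomeSequence,
    MethylationAssumption,
    Strand,
    StrandState,
    convert_sequence,
    reverse_complement,
)
from bscap.io import Interval
from bscap.probes import (
    DesignParams,
    KmerFrequencyTable,
    ProbeCandidate,
    canonical_kmer,
    count_mapping_locations,
    design_probes,
    filter_candidates,
    generate_candidates,
    homopolymer_score,
    melting_temperature,
    rank_candidates,
    repeat_score,
    select_probes,
    selection_windows,
)

TOP_NONE = StrandState(Strand.TOP, MethylationAssumption.NO_CG_METHYLATED)


def brute_force_kmer_table(genome: GenomeSequence, k: int = 15) -> Counter:
    """Oracle: scan both fully converted strands, canonical keys."""
    counts: Counter = Counter()
    for seq in genome.contigs.values():
        for strand_seq in (seq.replace("C", "T"),
                           reverse_complement(seq).replace("C", "T")):
            for i in range(len(strand_seq) - k + 1):
                kmer = strand_seq[i : i + k]
                if "N" not in kmer:
                    counts[canonical_kmer(kmer)] += 1
    return counts


class TestKmerTable:
    def test_homopolymer_genome_counts(self):
        table = KmerFrequencyTable.from_genome(GenomeSequence({"c": "T" * 16}))
        assert table["T" * 15] == 4  # 2 start positions x 2 strands
        assert table.total() == 4

    def test_absent_kmer_is_zero(self):
        table = KmerFrequencyTable.from_genome(GenomeSequence({"c": "T" * 16}))
        assert table["A" * 7 + "G" * 8] == 0

    def test_short_contig_gives_empty_table(self):
        table = KmerFrequencyTable.from_genome(GenomeSequence({"c": "ATGATGATGATGAT"}))
        assert table.total() == 0

    def test_matches_brute_force_scan(self, small_genome):
        table = KmerFrequencyTable.from_genome(small_genome)
        oracle = brute_force_kmer_table(small_genome)
        assert table.counts == oracle
        lengths = sum(len(s) for s in small_genome.contigs.values())
        assert table.total() == 2 * (lengths - 2 * (15 - 1))


class TestScores:
    def test_repeat_score_is_mean_kmer_frequency(self):
        genome = GenomeSequence({"c": "T" * 16})
        table = KmerFrequencyTable.from_genome(genome)
        probe = ProbeCandidate("c", 0, 16, TOP_NONE, "T" * 16)
        # both 15-mers of the probe have count 4
        assert repeat_score(probe, table) == pytest.approx(4.0)

    def test_repeat_score_requires_min_length(self):
        table = KmerFrequencyTable(Counter(), 15)
        probe = ProbeCandidate("c", 0, 10, TOP_NONE, "T" * 10)
        with pytest.raises(ValueError):
            repeat_score(probe, table)

    @pytest.mark.parametrize(
        "seq,score", [("AAAACGT", 4), ("ACGT", 1), ("TTTTTTTTTT", 10)]
    )
    def test_homopolymer_score(self, seq, score):
        assert homopolymer_score(seq) == score

    def test_homopolymer_empty_errors(self):
        with pytest.raises(ValueError):
            homopolymer_score("")

    def test_tm_gc_monotonic_and_deterministic(self):
        gc_rich = "GC" * 25
        at_rich = "AT" * 25
        assert melting_temperature(gc_rich) > melting_temperature(at_rich)
        assert melting_temperature(gc_rich) == melting_temperature("GC" * 25)

    def test_tm_hand_computed(self):
        # 60-mer with 30 G/C: Tm = 64.9 + 41*(30-16.4)/60 = 74.19333...
        seq = "GCAT" * 15
        assert melting_temperature(seq) == pytest.approx(64.9 + 41 * (30 - 16.4) / 60)

    def test_tm_rejects_n(self):
        with pytest.raises(ValueError):
            melting_temperature("ACGTN")


def brute_force_locations(probe_seq: str, genome: GenomeSequence) -> int:
    """Oracle: sliding-window bisulfite-asymmetric comparison on both strands."""

    def matches(p, g):
        return all(pb == gb or (pb == "T" and gb == "C") for pb, gb in zip(p, g))

    n = 0
    for seq in genome.contigs.values():
        for strand_seq in (seq, reverse_complement(seq)):
            for i in range(len(strand_seq) - len(probe_seq) + 1):
                if matches(probe_seq, strand_seq[i : i + len(probe_seq)]):
                    n += 1
    return n


class TestMappingLocations:
    def test_unique_region_maps_once(self, small_genome):
        raw = small_genome.fetch("chr1", 500, 580)
        probe = ProbeCandidate("chr1", 500, 580, TOP_NONE,
                               convert_sequence(raw, TOP_NONE))
        assert count_mapping_locations(probe, small_genome) == 1

    def test_multicopy_segment_counted(self, engineered_genome):
        genome, coords = engineered_genome
        for key, copies in (("seg2", 2), ("seg3", 3), ("seg4", 4)):
            seq = convert_sequence(coords[key], TOP_NONE)
            probe = ProbeCandidate("chr1", 0, 80, TOP_NONE, seq)
            got = count_mapping_locations(probe, genome)
            assert got == copies == brute_force_locations(seq, genome)

    def test_source_always_matches(self, small_genome):
        raw = small_genome.fetch("chr1", 100, 160)
        for assumption in MethylationAssumption:
            state = StrandState(Strand.TOP, assumption)
            probe = ProbeCandidate("chr1", 100, 160, state,
                                   convert_sequence(raw, state))
            assert count_mapping_locations(probe, small_genome) >= 1


class TestGenerateAndFilter:
    def test_tiling_starts_and_lengths(self, small_genome):
        params = DesignParams()
        cands = generate_candidates(
            small_genome, [Interval("chr1", 1000, 1100)], params
        )
        starts = sorted({c.start for c in cands})
        assert starts == list(range(1000, 1051, 5))
        assert all(50 <= c.length <= 100 for c in cands)
        states = {c.state for c in cands}
        assert len(states) == 4

    def test_short_target_yields_nothing(self, small_genome):
        assert generate_candidates(small_genome, [Interval("chr1", 0, 40)]) == []

    def test_filter_boundaries(self):
        def probe(rep, uniq):
            return ProbeCandidate("c", 0, 60, TOP_NONE, "A" * 60,
                                  repeat_score=rep, uniqueness=uniq)

        kept, removed = filter_candidates(
            [probe(10_000.0, 1), probe(10_000.1, 1), probe(1.0, 4), probe(1.0, 3)]
        )
        assert [(p.repeat_score, p.uniqueness) for p in kept] == [
            (10_000.0, 1), (1.0, 3)
        ]
        assert removed == {"repeat": 1, "uniqueness": 1}


class TestRankAndSelect:
    def _probe(self, **kw):
        base = dict(contig="c", start=0, end=60, state=TOP_NONE, seq="A" * 60,
                    tm=70.0, repeat_score=1.0, homopolymer_score=2, uniqueness=1)
        base.update(kw)
        return ProbeCandidate(**base)

    def test_rank_prefers_more_unique(self):
        a = self._probe(uniqueness=1)
        b = self._probe(uniqueness=3)
        ranked = rank_candidates([a, b])
        assert ranked[0].rank_score < ranked[1].rank_score

    def test_identical_probes_tie(self):
        ranked = rank_candidates([self._probe(), self._probe()])
        assert ranked[0].rank_score == ranked[1].rank_score

    def test_hand_computed_composite(self):
        # pool of two: each component min-max normalises to 0 or 1
        x = self._probe(tm=69.5, repeat_score=5.0, uniqueness=1, homopolymer_score=3)
        y = self._probe(tm=68.5, repeat_score=3.0, uniqueness=2, homopolymer_score=3)
        ranked = rank_candidates([x, y])
        # x: |69.5-70.5|=1.0 -> 0, repeat 5 -> 1, uniq 1 -> 0, homo tie -> 0 => 1.0
        # y: |68.5-70.5|=2.0 -> 1, repeat 3 -> 0, uniq 2 -> 1, homo tie -> 0 => 2.0
        assert ranked[0].rank_score == pytest.approx(1.0)
        assert ranked[1].rank_score == pytest.approx(2.0)

    def test_selection_window_geometry(self):
        wins = selection_windows(Interval("c", 0, 10_000), window=15, gap=20)
        assert all(w.end - w.start == 15 for w in wins)
        gaps = [b.start - a.end for a, b in zip(wins, wins[1:])]
        assert set(gaps) == {20}

    def test_three_candidate_starts_per_window(self):
        # tile 5 inside a 15 bp window -> 3 start positions
        wins = selection_windows(Interval("c", 0, 1000))
        for w in wins[:5]:
            starts = [s for s in range(0, 1000, 5) if w.start <= s < w.end]
            assert len(starts) == 3

    def test_select_one_probe_per_window(self, small_genome):
        target = Interval("chr1", 1000, 2000)
        panels, audit = design_probes(small_genome, [target])
        wins = selection_windows(target)
        for state, panel in panels.items():
            assert len(panel) <= len(wins)
            # no two selected probes share a window
            win_of = []
            for p in panel:
                hits = [i for i, w in enumerate(wins) if w.start <= p.start < w.end]
                assert len(hits) == 1
                win_of.append(hits[0])
            assert len(set(win_of)) == len(win_of)

    def test_selected_probes_consistent_with_state(self, small_genome):
        panels, _ = design_probes(small_genome, [Interval("chr1", 1000, 1600)])
        for state, panel in panels.items():
            for p in panel:
                raw = small_genome.fetch(p.contig, p.start, p.end)
                if state.strand is Strand.BOTTOM:
                    raw = reverse_complement(raw)
                assert p.seq == convert_sequence(raw, state)
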
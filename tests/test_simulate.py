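import numpy as np
import pytest

from indelmark.io_formats import reverse_complement
from indelmark.simulate import (
    SimConfig,
    SimTruth,
    Variant,
    alt_length,
    apply_variants,
    focal_locus,
    simulate_annotation,
    simulate_population,
    simulate_reads,
    simulate_reference,
)


class TestReference:
    def test_deterministic_under_seed(self):
        a = simulate_reference(100, seed=1)
        b = simulate_reference(100, seed=1)
        assert a.sequences == b.sequences
        assert simulate_reference(100, seed=2).sequences != a.sequences

    def test_gc_zero_gives_at_only(self):
        g = simulate_reference(500, gc_fraction=0.0, seed=3)
        assert set(g["chr1"]) <= {"A", "T"}

    def test_gc_fraction_within_binomial_bound(self):
        n = 100_000
        g = simulate_reference(n, gc_fraction=0.5, seed=4)
        gc = sum(g["chr1"].count(b) for b in "GC")
        sigma = (n * 0.25) ** 0.5
        assert abs(gc - n * 0.5) < 3 * sigma

    def test_length_validation(self):
        with pytest.raises(ValueError):
            simulate_reference(0)


class TestPopulation:
    def test_zero_density_keeps_samples_identical(self):
        ref = simulate_reference(5_000, seed=5)
        cfg = SimConfig(genome_length=5_000, n_samples=4, indel_density_per_kb=0.0, rng_seed=5)
        genomes, truth = simulate_population(ref, cfg)
        assert truth.variants == []
        assert all(g.sequences == ref.sequences for g in genomes.values())

    def test_deletion_bookkeeping(self):
        ref = simulate_reference(1_000, seed=6)
        v = Variant("chr1", 100, "del", 5, frozenset({"s1"}))
        edited = apply_variants(ref["chr1"], [v])
        assert len(edited) == 1000 - 5
        assert edited[:100] == ref["chr1"][:100]
        assert edited[100:] == ref["chr1"][105:]

    def test_insertion_bookkeeping(self):
        ref = simulate_reference(1_000, seed=6)
        v = Variant("chr1", 100, "ins", 7, frozenset({"s1"}), "ACGTACG")
        edited = apply_variants(ref["chr1"], [v])
        assert len(edited) == 1007
        assert edited[100:107] == "ACGTACG"

    def test_truth_matches_rediffed_genomes(self):
        """Re-derive each variant by direct window comparison of sample vs
        reference sequence — an independent check of the edit bookkeeping."""
        ref = simulate_reference(20_000, seed=7)
        cfg = SimConfig(genome_length=20_000, n_samples=6, indel_density_per_kb=1.0, rng_seed=7)
        genomes, truth = simulate_population(ref, cfg)
        for sid, genome in genomes.items():
            mine = sorted(
                (v for v in truth.variants if sid in v.carriers), key=lambda v: v.pos
            )
            expected = apply_variants(ref["chr1"], mine)
            assert genome["chr1"] == expected
            shift = 0
            for v in mine:
                if v.kind == "ins":
                    start = v.pos + shift
                    assert genome["chr1"][start : start + v.size] == v.inserted_seq
                    shift += v.size
                else:
                    # deleted segment absent: flanks are now adjacent
                    left = ref["chr1"][v.pos - 10 : v.pos]
                    right = ref["chr1"][v.pos + v.size : v.pos + v.size + 10]
                    start = v.pos + shift
                    assert genome["chr1"][start - 10 : start + 10] == left + right
                    shift -= v.size
        lengths = {
            sid: len(genomes[sid]["chr1"]) for sid in genomes
        }
        for sid in genomes:
            delta = sum(
                (v.size if v.kind == "ins" else -v.size)
                for v in truth.variants
                if sid in v.carriers
            )
            assert lengths[sid] == 20_000 + delta

    def test_variant_overlap_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            SimTruth(
                [
                    Variant("c", 100, "del", 10, frozenset({"s1"})),
                    Variant("c", 105, "del", 3, frozenset({"s2"})),
                ]
            )

    def test_excessive_density_is_error(self):
        ref = simulate_reference(200, seed=8)
        cfg = SimConfig(genome_length=200, n_samples=4, indel_density_per_kb=2500.0, rng_seed=8)
        with pytest.raises(ValueError, match="density"):
            simulate_population(ref, cfg)

    def test_gap_interior_placement_respects_tile_geometry(self):
        ref = simulate_reference(50_000, seed=9)
        cfg = SimConfig(
            genome_length=50_000, n_samples=8, indel_density_per_kb=1.0,
            placement="gap_interior", rng_seed=9,
        )
        _, truth = simulate_population(ref, cfg)
        assert truth.variants
        for v in truth.variants:
            gap_start = (v.pos // 20) * 20
            assert gap_start >= 20  # inside some tile's spacer, never a primer
            assert v.pos > gap_start
            if v.kind == "del":
                assert v.pos + v.size < gap_start + 20
                assert v.size <= 18
            else:
                assert v.pos < gap_start + 20
                assert v.size <= 30
            # focal locus arithmetic: the spacer of that tile contains pos
            locus_start = int(focal_locus(v).split(":")[1])
            assert locus_start + 20 <= v.pos < locus_start + 40

    def test_carrier_counts_within_panel(self):
        ref = simulate_reference(30_000, seed=10)
        cfg = SimConfig(genome_length=30_000, n_samples=10, rng_seed=10)
        _, truth = simulate_population(ref, cfg)
        for v in truth.variants:
            assert 1 <= len(v.carriers) <= 9


class TestReads:
    def test_zero_depth(self):
        ref = simulate_reference(1_000, seed=11)
        cfg = SimConfig(genome_length=1_000, n_samples=2, depth=0.0, rng_seed=11)
        assert simulate_reads(ref, cfg) == []

    def test_read_count_formula(self):
        ref = simulate_reference(100_000, seed=12)
        cfg = SimConfig(genome_length=100_000, n_samples=2, depth=3.0, read_len=93, rng_seed=12)
        assert len(simulate_reads(ref, cfg)) == round(3.0 * 100_000 / 93)

    def test_error_free_reads_are_genome_substrings(self):
        ref = simulate_reference(5_000, seed=13)
        cfg = SimConfig(
            genome_length=5_000, n_samples=2, depth=10.0,
            substitution_error_rate=0.0, rng_seed=13,
        )
        seq = ref["chr1"]
        for read in simulate_reads(ref, cfg):
            assert read.seq in seq or reverse_complement(read.seq) in seq

    def test_deterministic_under_seed(self):
        ref = simulate_reference(2_000, seed=14)
        cfg = SimConfig(genome_length=2_000, n_samples=2, rng_seed=14)
        a = simulate_reads(ref, cfg, seed=99)
        b = simulate_reads(ref, cfg, seed=99)
        assert [(r.seq, r.quals) for r in a] == [(r.seq, r.quals) for r in b]

    def test_quality_scheme_retains_about_95_percent(self):
        from indelmark.epcr_genotyping import filter_reads

        ref = simulate_reference(50_000, seed=15)
        cfg = SimConfig(genome_length=50_000, n_samples=2, depth=6.0, rng_seed=15)
        reads = simulate_reads(ref, cfg)
        kept = len(list(filter_reads(reads)))
        assert 0.90 <= kept / len(reads) <= 0.99

    def test_alt_length_arithmetic(self):
        ins = Variant("c", 100, "ins", 12, frozenset({"s"}), "A" * 12)
        dele = Variant("c", 100, "del", 7, frozenset({"s"}))
        assert alt_length(ins) == 72
        assert alt_length(dele) == 53


class TestAnnotationGenerator:
    def test_writes_parseable_gff3(self, tmp_path):
        from indelmark.io_formats import read_gff3

        ref = simulate_reference(60_000, seed=16)
        path = tmp_path / "toy.gff3"
        fs = simulate_annotation(ref, seed=16, path=str(path))
        assert fs.transcripts
        parsed = read_gff3(path, ref)
        assert len(parsed.transcripts) == len(fs.transcripts)
        got = {t.transcript_id: t for t in parsed.transcripts}
        for tx in fs.transcripts:
            assert got[tx.transcript_id].exons == tx.exons
            assert got[tx.transcript_id].strand == tx.strand
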
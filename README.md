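# indelmark

Genome-wide discovery of insertion/deletion (indel) molecular markers from
short-read resequencing panels, by **in-silico PCR (e-PCR)** — for plant (or
any) geneticists who want gel-scorable, highly polymorphic length markers
without calling variants through read mapping.

## The method

Indels are awkward for alignment-based callers: reads spanning them map
poorly, and gap placement is error-prone. The e-PCR strategy sidesteps
mapping entirely:

1. **Tiling.** The reference genome is tiled with virtual primer pairs: a
   20-bp forward primer, a 20-bp spacer, and the reverse complement of the
   next 20 bp as the reverse primer, stepping 20 bp between pairs. Every
   pair defines a 60-bp reference amplicon; the spacer is the variable
   region.
2. **Uniqueness.** Each 20-mer is matched against the whole genome on both
   strands allowing up to 3 mismatches (ungapped). Primers hitting more
   than one position are discarded — what survives is a set of single-copy
   virtual amplicons.
3. **e-PCR genotyping.** For every sample, quality-filtered reads (≥ 70 % of
   bases at Phred ≥ 20) are searched directly for both primer sites of each
   locus, allowing 1 mismatch per primer, in both read orientations. The
   distance spanned is the amplicon length; the most frequent length across
   a sample's reads is that sample's allele (ties go to the smaller length).
   An indel inside the spacer shifts the length by exactly its size.
4. **Polymorphism scoring.** Per locus, allele-length frequencies *p_j*
   over the genomes with data give the polymorphism information content,
   PIC = 1 − Σ_j p_j². A locus is an *indel* if it has data in ≥ 20 genomes
   and PIC > 0, and *highly polymorphic* if PIC ≥ 0.5. The *major allele
   difference* is |length(top allele) − length(second allele)|.
5. **Annotation & selection.** Loci are classified by overlap with
   TSS_up_0.5Kb / 5′UTR / 3′UTR / CDS / intron / TES_down_0.5Kb /
   intergenic footprints (strand-aware, multi-category). Markers are
   selected per gel mode: polyacrylamide (difference ≥ 3 bp, product
   60–100 bp) or agarose (difference ≥ 8 bp, product 150–300 bp).
6. **Primer design.** Wet-lab primers are picked around each selected locus
   by exhaustive enumeration under hard constraints (20–28 nt, Tm 60–65 °C
   by nearest-neighbor thermodynamics, GC 30–70 %, Tm spread ≤ 3 °C, 3′ G/C
   clamp) minimising an explicit penalty, so designs are fully reproducible.

A built-in simulator (`indelmark.simulate`) generates a reference, a panel
of inbred sample genomes with planted indels (known positions, sizes and
carriers), and error-bearing reads — so the entire pipeline is verifiable
against ground truth without any external data.

## Worked example

```python
from indelmark import (
    SimConfig, design_tiled_pairs, filter_unique_pairs, filter_reads,
    genotype_sample, gate_and_score, simulate_population, simulate_reads,
    simulate_reference,
)
from indelmark.locus_stats import build_spectrum, overall_rates
from indelmark.simulate import evaluate_recovery

ref = simulate_reference(50_000, seed=7)
cfg = SimConfig(genome_length=50_000, n_samples=24, depth=10.0,
                substitution_error_rate=0.0, indel_density_per_kb=0.8,
                placement="gap_interior", rng_seed=7)
genomes, truth = simulate_population(ref, cfg)

pairs = design_tiled_pairs(ref)                 # tiled virtual primer pairs
unique = filter_unique_pairs(pairs, ref)        # genome-unique ones
matrix = {}
for i, (sid, genome) in enumerate(genomes.items()):
    reads = filter_reads(simulate_reads(genome, cfg, seed=100 + i))
    for call in genotype_sample(unique, reads, sample_id=sid):
        matrix.setdefault(call.locus_id, {})[sid] = call.modal_length

stats = gate_and_score([build_spectrum(l, row) for l, row in matrix.items()])
located = sum(s.n_genomes >= 20 for s in stats)
indels = sum(s.is_indel for s in stats)
high = sum(s.is_high_poly for s in stats)
print(f"tiled pairs:        {len(pairs)}")
print(f"unique pairs:       {len(unique)}")
print(f"loci in >=20 genomes: {located}")
print(f"indel loci (PIC>0): {indels}")
print(f"highly polymorphic: {high}")
print("rates:", overall_rates(len(pairs), len(unique), located, indels, high))
report = evaluate_recovery(truth, matrix, [p.locus_id for p in unique], list(genomes))
print(f"planted indels recovered: {report.n_recovered}/{report.n_eligible} "
      f"(size-exact: {report.n_size_exact})")
```

prints

```
tiled pairs:        2498
unique pairs:       2472
loci in >=20 genomes: 2409
indel loci (PIC>0): 44
highly polymorphic: 2
rates: {'unique_primer_rate': 98.96, 'located_rate': 97.45, 'indel_rate': 1.83, 'high_poly_share': 4.55}
planted indels recovered: 40/40 (size-exact: 40)
```

All 40 planted indels whose loci stayed unique and read-spannable come back
with exactly the planted size. The `unique_primer_rate` is near 100 % here
because a random 50-kb sequence has almost no repeats; on a real repeat-rich
plant genome it drops by an order of magnitude. The detected "indel" count
(44 > 40) includes loci adjacent to planted variants whose primer sites the
variant disrupted in carriers.

The same run is available as a CLI over plain-TSV intermediates:

```bash
indelmark run-all --outdir out --seed 7          # simulate → … → select
indelmark stats   --outdir out                   # rerun any single stage
```

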
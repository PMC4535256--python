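# Methods

## Model and procedure

`indelmark` treats indel discovery as a length-measurement problem rather
than an alignment problem. A locus is a fixed 60-bp virtual amplicon on the
reference: forward 20-mer, 20-bp variable spacer, reverse 20-mer
(as the reverse complement of the genomic site). Because the primers are
anchored and matching is ungapped, any net indel confined to the spacer
changes the product length by exactly the indel size; an indel touching a
primer site instead abolishes the product. Genotyping a sample is therefore
histogramming e-PCR product lengths over its reads and taking the mode.

Assumptions baked into this design:

* **Homozygous samples.** One allele per locus per sample (inbred lines).
  The modal length is a point genotype; residual heterozygosity would be
  collapsed to whichever allele has more read support.
* **Ungapped primer matching.** Uniqueness (Hamming ≤ 3, both strands) and
  read-site matching (Hamming ≤ 1) never consider gapped alignments. This
  mirrors real PCR: a primer with an indel under it does not anneal
  productively.
* **Within-read products only.** A sample can only be genotyped at a locus
  when a single read spans the full product, so measurable indel size is
  bounded by read length − 60 for insertions (deletions always shorten the
  product and remain spannable).

## Key parameters

| parameter | default | units | why |
|---|---|---|---|
| primer_len / gap / step | 20 / 20 / 20 | bp | tile geometry; 60-bp reference product, genome fully covered every 20 bp |
| max_mismatch (genome uniqueness) | 3 | mismatches per 20-mer | tolerant enough to catch near-repeats that would cross-amplify |
| max_mismatch (reads) | 1 | mismatches per 20-mer | tolerates one sequencing error or SNP in a primer site without losing the locus |
| q_cutoff / q_fraction | Q20 / 0.70 | Phred / fraction | a read is kept iff ≥ 70 % of bases reach Q20; the fraction is the common default of read-quality filters of this type and is a config knob |
| min_genomes | 20 | genomes | a locus enters polymorphism accounting only with data in ≥ 20 genomes |
| PIC thresholds | > 0 indel; ≥ 0.5 highly polymorphic | — | PIC = 1 − Σ p_j² over allele-length frequencies |
| gel modes | PAGE: diff ≥ 3 bp, product 60–100 bp; agarose: diff ≥ 8 bp, product 150–300 bp | bp | what each electrophoresis platform can resolve |
| primer picker | len 20/23/28, Tm 60/63/65 °C, GC 30/50/70 %, spread ≤ 3 °C, G/C clamp | nt / °C / % | hard constraints; penalty = Σ \|Tm−opt\| + 0.1·Σ \|len−opt\| + 0.05·Σ \|GC−opt\| |
| Tm model | SantaLucia 1998 unified NN, 50 mM monovalent, 50 nM primer | °C | deterministic to < 0.01 °C; concentrations are stated conventions (they are not part of the marker definition) |

The product-size range has two historically used presets: the 60–90-bp
setting of early short-amplicon designs is retained as a selectable preset,
while the mode defaults are 60–100 (PAGE) and 150–300 (agarose), matching
the gel-resolution rules used for selection. The agarose template window is
widened to ±150 bp around the variable region because a 100-bp window
cannot contain a 150–300-bp product.

## Numerical and tie-break choices

* **Modal length ties** go to the smaller length; within one read, when
  several primer-site combinations exist, the shortest product wins
  (shortest competing products amplify preferentially in real PCR).
* **Major-allele ranking ties** (equal counts) rank the smaller length as
  more frequent, deterministically across platforms.
* **Primer-picker ties** resolve to the leftmost left primer, then the
  shortest product. Penalties are compared at 1e-6 resolution so that
  candidate pairs with analytically identical nearest-neighbor sums
  (shifted primers with the same dinucleotide multiset) tie by position
  rather than by floating-point summation order.
* **N bases** are allowed in the genome; any tiled primer overlapping an N
  is dropped (not shifted — shifting would break the regular tiling), and
  read windows overlapping an N never match a primer site.
* **Uniqueness counts both strands**; a palindromic primer matching one
  site in both orientations counts as two placements, as a short-read
  aligner would report it.
* The uniqueness search uses a 4×5-mer pigeonhole seed index (complete for
  Hamming ≤ 3 on 20-mers) with packed 2-bit verification; the read screen
  uses exact 10-mer half-sites (complete for Hamming ≤ 1). Both are
  verified against exhaustive scans in the test suite.
* Degenerate inputs: an empty genome tiles to an empty list; an all-missing
  matrix row is an error; a window where no primer pair satisfies the hard
  constraints yields "no design", which selection logs as the rejection
  reason.

## The simulator: what it emulates, and what it does not

`indelmark.simulate` emulates the study conditions the pipeline targets:
~93-bp single-end reads at ~3× mean depth with ~0.5 % substitution error;
panels of homozygous samples; indel sizes 1–211 bp drawn from a truncated
geometric distribution (mass concentrated on 1–5 bp, matching the observed
dominance of small indels); carrier counts uniform on {1, …, n−1} so
planted PIC values spread over (0, 0.5+]; quality strings that make the
Q20/70 % filter retain ≈ 95 % of reads. The default planted density is
1 indel/kb, on the order of the per-kb marker density the method reports
on real panels. A `gap_interior` placement mode confines each variant
strictly inside one tile's spacer (deletions ≤ 18 bp so they fit; larger
sizes become insertions), which is the geometry under which recovery is
provable; uniform placement exercises the realistic case where variants
also disrupt primer sites.

Not emulated: platform-specific error profiles and quality ladders,
paired-end inserts, PCR duplicates, heterozygosity, overlapping variants,
and repeat-rich genome structure (the i.i.d. reference makes nearly every
20-mer unique, so the uniqueness filter removes far less here than on a
real plant genome). Passing the planted-recovery tests therefore shows the
measurement machinery is exact under its stated assumptions — not that
real-genome discovery rates will match the synthetic ones.

## Verification strategy and problem sizes

Every algorithmic component is checked against an independent oracle:
tiling against direct enumeration of valid starts (genomes ≤ 500 bp);
uniqueness against an exhaustive two-strand Hamming scan (100 random
10–50-kb genomes with engineered duplications and 4-mismatch near-copies);
the batched read screen against the per-read reference search; PIC against
brute-force evaluation (1000 random spectra, 1e-12); Tm against a
hand-summed nearest-neighbor table; the primer picker against naive
feasible-set enumeration (100 random 200–400-bp windows). End-to-end
recovery uses a 100-kb reference and 24 samples — large enough that every
stage runs at realistic per-locus statistics while the full suite stays in
the minutes range — at 10× error-free (recovery ≥ 95 %, sizes exact, PIC
recovered exactly wherever all samples are called) and at 3× with 0.5 %
errors (recovery degrades; recovered sizes stay exact).

## Known limitations

* Indels larger than read length − 60 bp (insertions) are invisible;
  deletions larger than the 20-bp spacer destroy primer sites and are seen
  only as missing data or as signal at neighbouring tiles.
* Two overlapping tiles share sequence, so one real variant can surface at
  up to three adjacent loci (once in a spacer, twice under neighbours'
  primers); locus-level counts are therefore not deduplicated variant
  counts.
* At 3× depth a locus is frequently covered by no spanning read in a given
  sample; the ≥ 20-genome gate controls, but does not eliminate, the
  resulting missingness bias toward shorter products.
* The primer picker scores primers on composition and Tm only; hairpin and
  primer-dimer thermodynamics are out of scope.
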
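"""Genomic-region classification of loci and gel-mode-aware marker selection.

Region vocabulary: TSS_up_0.5Kb (500 bp upstream of a transcription start,
strand-aware), 5'/3' UTR, CDS, intron, TES_down_0.5Kb (500 bp downstream of a
transcription end), and intergenic.  A locus is assigned by interval overlap
of its full reference amplicon against every transcript model, so one locus
can carry several categories (alternative transcripts double-count, as they
do in the source accounting); intergenic applies only when nothing else does.

Marker selection keeps loci with PIC >= 0.5 and, per gel mode:
PAGE       — major allele difference >= 3 bp, PCR product 60–100 bp;
agarose    — major allele difference >= 8 bp, PCR product 150–300 bp.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

from intervaltree import IntervalTree

from .io_formats import FeatureSet
from .locus_stats import LocusStats
from .primer_design import PcrPrimerDesign

__all__ = [
    "REGION_CATEGORIES",
    "GEL_MODES",
    "MarkerRecord",
    "RegionAnnotator",
    "classify_locus",
    "region_spans",
    "select_markers",
]

REGION_CATEGORIES = (
    "TSS_up_0.5Kb",
    "UTR5",
    "UTR3",
    "CDS",
    "intron",
    "TES_down_0.5Kb",
    "intergenic",
)

#: mode -> (min major allele difference bp, product range bp)
GEL_MODES: dict[str, tuple[int, tuple[int, int]]] = {
    "PAGE": (3, (60, 100)),
    "agarose": (8, (150, 300)),
}

PIC_THRESHOLD = 0.5
DEFAULT_FLANK = 500


@dataclass
class MarkerRecord:
    """A selected indel marker with its wet-lab primer design."""

    locus_id: str
    chrom: str
    pos: int  # 1-based position of the amplicon start
    mode: str
    left_primer: str
    right_primer: str
    product_len: int
    pic: float
    major_allele_diff: int
    n_alleles: int
    n_products: int
    categories: frozenset[str]


class RegionAnnotator:
    """Interval trees of category footprints, one per chromosome.

    Flanks are clipped at chromosome edges when lengths are provided.
    Upstream/downstream follow transcript strand.
    """

    def __init__(
        self,
        features: FeatureSet,
        flank: int = DEFAULT_FLANK,
        chrom_lengths: Mapping[str, int] | None = None,
    ):
        self.flank = flank
        self.trees: dict[str, dict[str, IntervalTree]] = {}
        for tx in features.transcripts:
            trees = self.trees.setdefault(
                tx.chrom, {cat: IntervalTree() for cat in REGION_CATEGORIES[:-1]}
            )
            limit = chrom_lengths.get(tx.chrom) if chrom_lengths else None
            if tx.strand == "+":
                up = (tx.start - flank, tx.start)
                down = (tx.end, tx.end + flank)
            else:
                up = (tx.end, tx.end + flank)
                down = (tx.start - flank, tx.start)
            for cat, ivals in (
                ("TSS_up_0.5Kb", [up]),
                ("TES_down_0.5Kb", [down]),
                ("UTR5", tx.utr5),
                ("UTR3", tx.utr3),
                ("CDS", tx.cds),
                ("intron", tx.introns()),
            ):
                for s, e in ivals:
                    s = max(s, 0)
                    if limit is not None:
                        e = min(e, limit)
                    if e > s:
                        trees[cat].addi(s, e)

    def classify(self, chrom: str, start: int, end: int) -> set[str]:
        trees = self.trees.get(chrom)
        cats: set[str] = set()
        if trees:
            for cat, tree in trees.items():
                if tree.overlap(start, end):
                    cats.add(cat)
        return cats or {"intergenic"}

    def spans_kb(self, chrom_lengths: Mapping[str, int]) -> dict[str, float]:
        return region_spans(self, chrom_lengths)


def classify_locus(
    interval: tuple[str, int, int],
    features: FeatureSet | RegionAnnotator,
    flank: int = DEFAULT_FLANK,
    chrom_lengths: Mapping[str, int] | None = None,
) -> set[str]:
    """Every region category overlapping the locus interval.

    *interval* is (chrom, start, end), 0-based half-open — normally the
    locus's full 60-bp reference amplicon.  Returns {"intergenic"} iff no
    genic category applies.
    """
    chrom, start, end = interval
    annot = (
        features
        if isinstance(features, RegionAnnotator)
        else RegionAnnotator(features, flank=flank, chrom_lengths=chrom_lengths)
    )
    return annot.classify(chrom, start, end)


def region_spans(
    annot: RegionAnnotator, chrom_lengths: Mapping[str, int]
) -> dict[str, float]:
    """Merged footprint of every category in Kb; intergenic is the rest."""
    spans = {cat: 0.0 for cat in REGION_CATEGORIES}
    genic_bp: dict[str, int] = {}
    for chrom, trees in annot.trees.items():
        union = IntervalTree()
        for cat, tree in trees.items():
            merged = IntervalTree(tree)
            merged.merge_overlaps()
            spans[cat] += sum(iv.end - iv.begin for iv in merged) / 1000.0
            union |= tree
        union.merge_overlaps()
        genic_bp[chrom] = sum(iv.end - iv.begin for iv in union)
    total = sum(chrom_lengths.values())
    covered = sum(genic_bp.get(c, 0) for c in chrom_lengths)
    spans["intergenic"] = (total - covered) / 1000.0
    return spans


def select_markers(
    stats: Iterable[LocusStats],
    designs: Mapping[str, PcrPrimerDesign | None],
    mode: str,
    annotations: Mapping[str, Iterable[str]] | None = None,
    loci: Mapping[str, tuple[str, int]] | None = None,
    pic_threshold: float = PIC_THRESHOLD,
) -> tuple[list[MarkerRecord], dict[str, str]]:
    """Apply one gel mode's thresholds and attach primer designs.

    Returns the selected markers plus a map of rejected locus -> reason
    (loci passing the polymorphism thresholds but lacking a feasible primer
    design are excluded with reason "no_design").
    """
    if mode not in GEL_MODES:
        raise ValueError(f"unknown gel mode {mode!r}; expected one of {sorted(GEL_MODES)}")
    min_diff, (prod_lo, prod_hi) = GEL_MODES[mode]
    selected: list[MarkerRecord] = []
    rejected: dict[str, str] = {}
    for ls in stats:
        if not ls.is_indel:
            rejected[ls.locus_id] = "not_indel"
            continue
        if ls.pic < pic_threshold:
            rejected[ls.locus_id] = "pic_below_threshold"
            continue
        if ls.major_allele_diff < min_diff:
            rejected[ls.locus_id] = "major_allele_diff_below_threshold"
            continue
        design = designs.get(ls.locus_id)
        if design is None:
            rejected[ls.locus_id] = "no_design"
            continue
        if not prod_lo <= design.product_len <= prod_hi:
            rejected[ls.locus_id] = "product_out_of_range"
            continue
        chrom, start = loci[ls.locus_id] if loci else (ls.locus_id.split(":")[0], int(ls.locus_id.split(":")[1]))
        selected.append(
            MarkerRecord(
                locus_id=ls.locus_id,
                chrom=chrom,
                pos=start + 1,
                mode=mode,
                left_primer=design.left_seq,
                right_primer=design.right_seq,
                product_len=design.product_len,
                pic=ls.pic,
                major_allele_diff=ls.major_allele_diff,
                n_alleles=ls.n_alleles,
                n_products=ls.n_genomes,
                categories=frozenset(annotations[ls.locus_id]) if annotations else frozenset(),
            )
        )
    return selected, rejected
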
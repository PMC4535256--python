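"""Allele spectra and polymorphism statistics for e-PCR loci.

A locus's allele spectrum is the tally of modal amplicon lengths across the
genomes with data there.  Its polymorphism information content is

    PIC = 1 - sum_j p_j**2

over allele-length frequencies p_j.  A locus counts as an *indel* when it has
length data in at least ``min_genomes`` genomes (default 20) and PIC > 0; it
is *highly polymorphic* at PIC >= 0.5.  The major allele difference is the
size difference in bp between the most and second most frequent alleles
(frequency ties resolved toward the smaller length).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "AlleleSpectrum",
    "LocusStats",
    "RegionSummary",
    "MISSING",
    "build_spectrum",
    "spectra_from_matrix",
    "pic",
    "major_allele_difference",
    "gate_and_score",
    "summarize_regions",
    "overall_rates",
    "pairwise_polymorphism_rate",
    "percentage",
]

MIN_GENOMES = 20
PIC_HIGH = 0.5
MISSING = "."


@dataclass
class AlleleSpectrum:
    """Allele-length counts over the genomes with data at one locus."""

    locus_id: str
    counts: dict[int, int]
    n_genomes: int = field(init=False)

    def __post_init__(self) -> None:
        if not self.counts:
            raise ValueError(f"locus {self.locus_id}: empty allele spectrum")
        self.n_genomes = sum(self.counts.values())

    def frequencies(self) -> dict[int, float]:
        return {a: c / self.n_genomes for a, c in self.counts.items()}


@dataclass
class LocusStats:
    locus_id: str
    pic: float
    n_alleles: int
    major_allele_diff: int
    size_range: int
    n_genomes: int
    is_indel: bool
    is_high_poly: bool


@dataclass
class RegionSummary:
    region: str
    count: int
    span_kb: float
    density: float  # loci per Kb
    rate: float  # percentage against the stated denominator


def build_spectrum(
    locus_id: str, row: Mapping[str, int | str]
) -> AlleleSpectrum:
    """Tally one length-matrix row (sample -> allele length or ``"."``).

    Missing samples are excluded from both counts and n_genomes; an
    all-missing row is an error.
    """
    counts = Counter(
        int(v) for v in row.values() if v != MISSING and not pd.isna(v)
    )
    if not counts:
        raise ValueError(f"locus {locus_id}: no genotyped samples")
    return AlleleSpectrum(locus_id=locus_id, counts=dict(counts))


def spectra_from_matrix(matrix: pd.DataFrame) -> list[AlleleSpectrum]:
    """Spectra for every row of a locus x sample length matrix.

    Rows with no calls at all are skipped (such loci never reached the
    matrix in normal pipeline runs).
    """
    out = []
    for locus_id, row in matrix.iterrows():
        vals = {s: v for s, v in row.items() if v != MISSING and not pd.isna(v)}
        if vals:
            out.append(build_spectrum(str(locus_id), vals))
    return out


def pic(spectrum: AlleleSpectrum) -> float:
    """Polymorphism information content, 1 - sum of squared frequencies."""
    return 1.0 - sum(f * f for f in spectrum.frequencies().values())


def _ranked_alleles(spectrum: AlleleSpectrum) -> list[int]:
    """Allele lengths by descending count; count ties -> smaller length first."""
    return sorted(spectrum.counts, key=lambda a: (-spectrum.counts[a], a))


def major_allele_difference(spectrum: AlleleSpectrum) -> int:
    """|most frequent length - second most frequent length|; 0 if monomorphic."""
    ranked = _ranked_alleles(spectrum)
    if len(ranked) < 2:
        return 0
    return abs(ranked[0] - ranked[1])


def gate_and_score(
    spectra: Iterable[AlleleSpectrum], min_genomes: int = MIN_GENOMES
) -> list[LocusStats]:
    """Score every spectrum; loci below the genome gate get is_indel=False."""
    out: list[LocusStats] = []
    for sp in spectra:
        p = pic(sp)
        gated = sp.n_genomes >= min_genomes
        out.append(
            LocusStats(
                locus_id=sp.locus_id,
                pic=p,
                n_alleles=len(sp.counts),
                major_allele_diff=major_allele_difference(sp),
                size_range=max(sp.counts) - min(sp.counts),
                n_genomes=sp.n_genomes,
                is_indel=gated and p > 0,
                is_high_poly=gated and p > 0 and p >= PIC_HIGH,
            )
        )
    return out


def percentage(numerator: float, denominator: float) -> float:
    """numerator / denominator as a percentage rounded to 2 decimals."""
    if denominator == 0:
        return 0.0
    return round(100.0 * numerator / denominator, 2)


def overall_rates(
    n_designed: int,
    n_unique: int,
    n_located: int,
    n_indel: int,
    n_high_poly: int,
) -> dict[str, float]:
    """The pipeline's headline rate arithmetic.

    unique-primer rate = unique / designed; located rate = loci with data in
    >= min_genomes genomes / unique; indel rate = indels / located;
    high-poly share = high-poly / indels.  All percentages, 2 decimals.
    """
    return {
        "unique_primer_rate": percentage(n_unique, n_designed),
        "located_rate": percentage(n_located, n_unique),
        "indel_rate": percentage(n_indel, n_located),
        "high_poly_share": percentage(n_high_poly, n_indel),
    }


def summarize_regions(
    stats: Iterable[LocusStats],
    annotations: Mapping[str, Iterable[str]],
    region_spans: Mapping[str, float],
    min_genomes: int = MIN_GENOMES,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Per-region marker accounting plus overall rates.

    *annotations* maps locus_id -> region categories (a locus may carry
    several, so per-region counts can sum past the locus total).  Region
    spans are in Kb; density is loci per Kb.  The per-region ``rate`` column
    is the indel rate: indels / loci with data in >= min_genomes genomes.
    """
    stats = list(stats)
    for ls in stats:
        for cat in annotations[ls.locus_id]:
            if cat not in region_spans:
                raise KeyError(f"unknown region category {cat!r}")
    rows = []
    for region, span_kb in region_spans.items():
        in_region = [
            ls for ls in stats if region in set(annotations[ls.locus_id])
        ]
        located = [ls for ls in in_region if ls.n_genomes >= min_genomes]
        indels = [ls for ls in located if ls.is_indel]
        high = [ls for ls in indels if ls.is_high_poly]
        rows.append(
            {
                "region": region,
                "n_loci": len(in_region),
                "n_located": len(located),
                "n_indel": len(indels),
                "n_high_poly": len(high),
                "span_kb": span_kb,
                "density_loci": len(in_region) / span_kb if span_kb else 0.0,
                "density_indel": len(indels) / span_kb if span_kb else 0.0,
                "rate_indel_pct": percentage(len(indels), len(located)),
            }
        )
    located_all = [ls for ls in stats if ls.n_genomes >= min_genomes]
    indel_all = [ls for ls in located_all if ls.is_indel]
    high_all = [ls for ls in indel_all if ls.is_high_poly]
    rates = {
        "located": float(len(located_all)),
        "indels": float(len(indel_all)),
        "high_poly": float(len(high_all)),
        "indel_rate": percentage(len(indel_all), len(located_all)),
        "high_poly_share": percentage(len(high_all), len(indel_all)),
    }
    return pd.DataFrame(rows), rates


def pairwise_polymorphism_rate(
    calls_a: Mapping[str, int], calls_b: Mapping[str, int]
) -> float:
    """Percentage of loci called in both samples whose allele lengths differ.

    Mirrors the wet-lab accuracy arithmetic: of the loci amplifiable in both
    genomes, the share showing a length polymorphism (2 decimals).
    """
    shared = set(calls_a) & set(calls_b)
    if not shared:
        raise ValueError("no loci called in both samples")
    n_diff = sum(calls_a[k] != calls_b[k] for k in shared)
    return percentage(n_diff, len(shared))
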
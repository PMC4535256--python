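"""Synthetic-data generator: a reference genome, a panel of inbred sample
genomes carrying planted indels, and error-bearing short reads with quality
strings — plus ground-truth bookkeeping so the whole pipeline can be scored.

Defaults emulate the study conditions the pipeline was built for: ~93-bp
reads at ~3x depth with ~0.5 % substitution error over a panel of homozygous
(inbred) samples, indel sizes 1–211 bp biased toward small sizes (truncated
geometric), and carrier frequencies spread over (0, 1).  Variant footprints
never overlap, so the truth table is unambiguous.  Everything is
reproducible bit-for-bit under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

from .io_formats import Read, ReferenceGenome, reverse_complement
from .locus_stats import AlleleSpectrum, pic

__all__ = [
    "SimConfig",
    "Variant",
    "SimTruth",
    "RecoveryReport",
    "simulate_reference",
    "simulate_population",
    "simulate_reads",
    "simulate_annotation",
    "focal_locus",
    "evaluate_recovery",
]

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_LUT = np.zeros(256, dtype=np.uint8)
for _k, _b in enumerate(b"ACGT"):
    _BASE_LUT[_b] = _k
MAX_INDEL = 211


@dataclass
class SimConfig:
    """Study conditions for one synthetic panel."""

    genome_length: int = 100_000
    n_samples: int = 24
    depth: float = 3.0
    read_len: int = 93
    substitution_error_rate: float = 0.005
    indel_density_per_kb: float = 1.0
    size_geometric_p: float = 0.3  # truncated geometric over 1..211, favours small
    placement: str = "uniform"  # or "gap_interior" (strictly inside tile gaps)
    gc_fraction: float = 0.5
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.genome_length < 1 or self.n_samples < 2:
            raise ValueError("need genome_length >= 1 and n_samples >= 2")
        for name in ("substitution_error_rate", "gc_fraction", "size_geometric_p"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.placement not in ("uniform", "gap_interior"):
            raise ValueError(f"unknown placement {self.placement!r}")


@dataclass(frozen=True)
class Variant:
    chrom: str
    pos: int  # 0-based; deletions remove [pos, pos+size), insertions go before pos
    kind: str  # "ins" or "del"
    size: int
    carriers: frozenset[str]
    inserted_seq: str = ""


@dataclass
class SimTruth:
    variants: list[Variant] = field(default_factory=list)

    def __post_init__(self) -> None:
        taken: dict[str, list[tuple[int, int]]] = {}
        for v in self.variants:
            foot = (v.pos, v.pos + (v.size if v.kind == "del" else 1))
            for s, e in taken.setdefault(v.chrom, []):
                if foot[0] < e and s < foot[1]:
                    raise ValueError("variant footprints overlap")
            taken[v.chrom].append(foot)


def _random_bases(rng: np.random.Generator, n: int, gc_fraction: float) -> str:
    p_each = [(1 - gc_fraction) / 2, gc_fraction / 2, gc_fraction / 2, (1 - gc_fraction) / 2]
    idx = rng.choice(4, size=n, p=p_each)
    return BASES[idx].tobytes().decode("ascii")


def simulate_reference(
    length: int, gc_fraction: float = 0.5, seed: int = 0, chrom: str = "chr1"
) -> ReferenceGenome:
    """A single-chromosome reference of i.i.d. bases at the given GC fraction."""
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = np.random.default_rng(seed)
    return ReferenceGenome({chrom: _random_bases(rng, length, gc_fraction)})


def _sample_size(rng: np.random.Generator, p: float, max_size: int) -> int:
    while True:
        s = int(rng.geometric(p))
        if 1 <= s <= max_size:
            return s


def _place_variants(
    ref: ReferenceGenome, config: SimConfig, rng: np.random.Generator
) -> list[tuple[str, int, str, int]]:
    """(chrom, pos, kind, size) placements, footprint-disjoint."""
    placements: list[tuple[str, int, str, int]] = []
    for chrom, seq in ref.sequences.items():
        length = len(seq)
        n_var = int(round(config.indel_density_per_kb * length / 1000.0))
        taken: list[tuple[int, int]] = []
        if config.placement == "gap_interior":
            # one variant at most per 20-bp tile gap, strictly interior, so the
            # planted signal falls in exactly one locus's variable region
            gap_starts = [s + 20 for s in range(0, length - 59, 20)]
            if n_var > len(gap_starts):
                raise ValueError("indel density too high for gap-interior placement")
            chosen = rng.choice(len(gap_starts), size=n_var, replace=False)
            for gi in sorted(int(g) for g in chosen):
                gs = gap_starts[gi]
                size = _sample_size(rng, config.size_geometric_p, 30)
                kind = "del" if (size <= 18 and rng.random() < 0.5) else "ins"
                if kind == "del":
                    pos = int(rng.integers(gs + 1, gs + 20 - size))
                else:
                    pos = int(rng.integers(gs + 1, gs + 20))
                placements.append((chrom, pos, kind, size))
            continue
        attempts = 0
        while len([p for p in placements if p[0] == chrom]) < n_var:
            attempts += 1
            if attempts > 200 * max(n_var, 1):
                raise ValueError(
                    "indel density too high to place variants without overlap"
                )
            size = _sample_size(rng, config.size_geometric_p, MAX_INDEL)
            kind = "del" if rng.random() < 0.5 else "ins"
            span = size if kind == "del" else 1
            pos = int(rng.integers(1, length - span))
            if any(pos < e and s < pos + span for s, e in taken):
                continue
            taken.append((pos, pos + span))
            placements.append((chrom, pos, kind, size))
    return placements


def apply_variants(seq: str, variants: list[Variant]) -> str:
    """Apply one chromosome's variants left-to-right with coordinate shifts."""
    pieces: list[str] = []
    cursor = 0
    for v in sorted(variants, key=lambda v: v.pos):
        pieces.append(seq[cursor : v.pos])
        if v.kind == "del":
            cursor = v.pos + v.size
        else:
            pieces.append(v.inserted_seq)
            cursor = v.pos
    pieces.append(seq[cursor:])
    return "".join(pieces)


def simulate_population(
    ref: ReferenceGenome, config: SimConfig
) -> tuple[dict[str, ReferenceGenome], SimTruth]:
    """Plant indels and build the sample genomes carrying them.

    Each variant's carrier count is uniform on {1, ..., n_samples - 1}, so
    planted allele frequencies (and hence PIC values) spread over (0, 1).
    """
    rng = np.random.default_rng(config.rng_seed)
    sample_ids = [f"s{i:03d}" for i in range(config.n_samples)]
    variants: list[Variant] = []
    for chrom, pos, kind, size in _place_variants(ref, config, rng):
        n_carriers = int(rng.integers(1, config.n_samples))
        carriers = frozenset(
            sample_ids[i]
            for i in rng.choice(config.n_samples, size=n_carriers, replace=False)
        )
        ins_seq = (
            _random_bases(rng, size, config.gc_fraction) if kind == "ins" else ""
        )
        variants.append(Variant(chrom, pos, kind, size, carriers, ins_seq))
    truth = SimTruth(variants)
    genomes: dict[str, ReferenceGenome] = {}
    for sid in sample_ids:
        seqs = {}
        for chrom, seq in ref.sequences.items():
            mine = [v for v in truth.variants if v.chrom == chrom and sid in v.carriers]
            seqs[chrom] = apply_variants(seq, mine)
        genomes[sid] = ReferenceGenome(seqs)
    return genomes, truth


def simulate_reads(
    genome: ReferenceGenome,
    config: SimConfig,
    seed: int | None = None,
    read_prefix: str = "read",
) -> list[Read]:
    """Uniform shotgun reads with i.i.d. substitution errors.

    Read count is ``round(depth * genome_length / read_len)``.  Quality
    strings mark ~95 % of reads as high quality (most bases Q40) and ~5 % as
    low quality (most bases Q10), so the default Q20/70 % read filter retains
    about 95 % of reads.
    """
    rng = np.random.default_rng(config.rng_seed if seed is None else seed)
    chroms = list(genome.sequences)
    lengths = np.array([genome.length(c) for c in chroms], dtype=float)
    total = lengths.sum()
    n_reads = int(round(config.depth * total / config.read_len))
    if config.read_len > lengths.min():
        raise ValueError("read_len exceeds a chromosome length")
    reads: list[Read] = []
    L = config.read_len
    for i in range(n_reads):
        ci = int(rng.choice(len(chroms), p=lengths / total)) if len(chroms) > 1 else 0
        seq_full = genome.sequences[chroms[ci]]
        start = int(rng.integers(0, len(seq_full) - L + 1))
        arr = np.frombuffer(seq_full[start : start + L].encode("ascii"), dtype=np.uint8).copy()
        if config.substitution_error_rate > 0:
            err = rng.random(L) < config.substitution_error_rate
            if err.any():
                # map current base to 0..3, then shift by 1..3 to a different base
                cur = _BASE_LUT[arr[err]]
                shift = rng.integers(1, 4, size=int(err.sum()))
                arr[err] = BASES[(cur + shift) % 4]
        seq = arr.tobytes().decode("ascii")
        if rng.random() < 0.5:
            seq = reverse_complement(seq)
        good_read = rng.random() < 0.95
        hi = rng.random(L) < (0.9 if good_read else 0.1)
        quals = np.where(hi, 40, 10).astype(int).tolist()
        reads.append(Read(read_id=f"{read_prefix}_{i}", seq=seq, quals=quals))
    return reads


def simulate_annotation(
    ref: ReferenceGenome,
    seed: int = 0,
    gene_spacing: int = 10_000,
    path: str | None = None,
):
    """Toy gene models along the reference, optionally written as GFF3.

    Each gene is ~2.4 kb: UTR5 (200 bp) + CDS exon (600) + intron (800) +
    CDS exon (600) + UTR3 (200), alternating strands, one transcript each.
    Returns a :class:`~indelmark.io_formats.FeatureSet`.
    """
    from .io_formats import FeatureSet, Transcript

    rng = np.random.default_rng(seed)
    transcripts: list[Transcript] = []
    lines = ["##gff-version 3"]
    for chrom, seq in ref.sequences.items():
        g = 0
        pos = int(rng.integers(1000, gene_spacing))
        while pos + 2400 + 1000 < len(seq):
            strand = "+" if g % 2 == 0 else "-"
            utr5 = (pos, pos + 200)
            ex1 = (pos, pos + 800)
            cds1 = (pos + 200, pos + 800)
            ex2 = (pos + 1600, pos + 2400)
            cds2 = (pos + 1600, pos + 2200)
            utr3 = (pos + 2200, pos + 2400)
            if strand == "-":
                utr5, utr3 = utr3, utr5
            gid, tid = f"gene{chrom}_{g}", f"mRNA{chrom}_{g}"
            transcripts.append(
                Transcript(
                    chrom=chrom,
                    strand=strand,
                    gene_id=gid,
                    transcript_id=tid,
                    exons=[ex1, ex2],
                    cds=[cds1, cds2],
                    utr5=[utr5],
                    utr3=[utr3],
                )
            )
            feats = [
                ("gene", pos, pos + 2400, gid, None),
                ("mRNA", pos, pos + 2400, tid, gid),
                ("exon", *ex1, f"{tid}.e1", tid),
                ("exon", *ex2, f"{tid}.e2", tid),
                ("CDS", *cds1, f"{tid}.c1", tid),
                ("CDS", *cds2, f"{tid}.c2", tid),
                ("five_prime_UTR", *utr5, f"{tid}.u5", tid),
                ("three_prime_UTR", *utr3, f"{tid}.u3", tid),
            ]
            for ftype, s, e, fid, parent in feats:
                attrs = f"ID={fid}" + (f";Parent={parent}" if parent else "")
                lines.append(
                    f"{chrom}\tsim\t{ftype}\t{s + 1}\t{e}\t.\t{strand}\t.\t{attrs}"
                )
            g += 1
            pos += 2400 + int(rng.integers(gene_spacing // 2, gene_spacing))
    if path is not None:
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")
    return FeatureSet(transcripts)


def focal_locus(
    variant: Variant, primer_len: int = 20, gap: int = 20, step: int = 20
) -> str:
    """locus_id of the tile whose variable gap contains the variant.

    Under default geometry the gap of the tile starting at s is
    [s + 20, s + 40), so position p falls in the gap of s = 20*(p//20 - 1).
    """
    if (primer_len, gap, step) != (20, 20, 20):
        raise NotImplementedError("focal_locus assumes the default tile geometry")
    tile_start = (variant.pos // step - 1) * step
    return f"{variant.chrom}:{tile_start}"


def alt_length(variant: Variant, ref_amplicon_len: int = 60) -> int:
    return ref_amplicon_len + (variant.size if variant.kind == "ins" else -variant.size)


@dataclass
class RecoveryReport:
    n_planted: int
    n_eligible: int  # focal locus unique-retained and alt product read-spannable
    n_recovered: int
    n_size_exact: int  # recovered loci whose every called carrier shows the planted size
    n_all_called: int  # eligible loci where every panel sample was called
    n_pic_exact: int  # of those, loci where call PIC == planted-frequency PIC

    @property
    def recovery_rate(self) -> float:
        return self.n_recovered / self.n_eligible if self.n_eligible else 0.0

    @property
    def size_concordance(self) -> float:
        return self.n_size_exact / self.n_recovered if self.n_recovered else 0.0


def evaluate_recovery(
    truth: SimTruth,
    matrix: Mapping[str, Mapping[str, int]],
    unique_locus_ids: Iterable[str],
    sample_ids: Iterable[str],
    read_len: int = 93,
    ref_amplicon_len: int = 60,
) -> RecoveryReport:
    """Score pipeline calls against the planted truth.

    *matrix* maps locus_id -> {sample_id: modal length} over called samples.
    A planted variant is *eligible* when its focal locus survived uniqueness
    filtering and its alt-allele product fits in a read.  It is *recovered*
    when at least one carrier and one non-carrier are called there and the
    called lengths differ; it is *size-exact* when every called carrier
    reports exactly the planted alt length and every called non-carrier the
    reference length.
    """
    unique_ids = set(unique_locus_ids)
    samples = list(sample_ids)
    n_eligible = n_recovered = n_size_exact = n_all_called = n_pic_exact = 0
    for v in truth.variants:
        locus = focal_locus(v)
        alt = alt_length(v, ref_amplicon_len)
        if locus not in unique_ids or alt > read_len:
            continue
        n_eligible += 1
        calls = matrix.get(locus, {})
        carrier_calls = {s: l for s, l in calls.items() if s in v.carriers}
        other_calls = {s: l for s, l in calls.items() if s not in v.carriers}
        if not carrier_calls or not other_calls:
            continue
        if set(carrier_calls.values()) == set(other_calls.values()):
            continue
        n_recovered += 1
        if all(l == alt for l in carrier_calls.values()) and all(
            l == ref_amplicon_len for l in other_calls.values()
        ):
            n_size_exact += 1
        if len(calls) == len(samples):
            n_all_called += 1
            k = len(carrier_calls)
            n = len(samples)
            planted = pic(
                AlleleSpectrum(locus_id=locus, counts={alt: k, ref_amplicon_len: n - k})
            )
            called = pic(
                AlleleSpectrum(
                    locus_id=locus,
                    counts={
                        length: list(calls.values()).count(length)
                        for length in set(calls.values())
                    },
                )
            )
            if called == planted:
                n_pic_exact += 1
    return RecoveryReport(
        n_planted=len(truth.variants),
        n_eligible=n_eligible,
        n_recovered=n_recovered,
        n_size_exact=n_size_exact,
        n_all_called=n_all_called,
        n_pic_exact=n_pic_exact,
    )
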
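"""Genome-uniqueness filtering of tiled e-PCR primers.

A primer is *unique* when it places at exactly one genomic position across
both strands within a Hamming-distance tolerance (default 3 mismatches,
anywhere in the 20-mer).  Matching is ungapped: an indel inside a primer site
makes the locus undetectable, which is exactly how e-PCR behaves.

The search uses a pigeonhole seed index: a 20-mer within Hamming distance 3
of a genomic window must match at least one of its four disjoint 5-mer seeds
exactly.  Candidate positions from the seed index are then verified with
packed 2-bit Hamming counts, so results equal an exhaustive scan.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kmer
from .io_formats import ReferenceGenome, reverse_complement
from .tiling import EPCRPrimerPair

__all__ = ["PrimerPlacement", "GenomeIndex", "count_placements", "filter_unique_pairs"]

MAX_MISMATCH_GENOME = 3


@dataclass(frozen=True)
class PrimerPlacement:
    chrom: str
    pos: int  # 0-based
    strand: str  # "+" or "-"
    mismatches: int


class GenomeIndex:
    """Seed index of one genome for mismatch-tolerant primer placement."""

    def __init__(self, genome: ReferenceGenome, primer_len: int = 20, n_seeds: int = 4):
        if primer_len % n_seeds:
            raise ValueError("primer_len must be divisible by n_seeds")
        self.primer_len = primer_len
        self.n_seeds = n_seeds
        self.seed_len = primer_len // n_seeds
        self._chroms: dict[str, dict] = {}
        for chrom, seq in genome.sequences.items():
            arr = _kmer.encode(seq)
            seed_codes = _kmer.window_codes(arr, self.seed_len)
            order = np.argsort(seed_codes, kind="stable")
            self._chroms[chrom] = {
                "len": len(seq),
                "codes": _kmer.window_codes(arr, primer_len),
                "seed_sorted": seed_codes[order],
                "seed_pos": order.astype(np.int64),
            }

    def _candidates(self, chrom_data: dict, codes_by_seed: list[int]) -> np.ndarray:
        """Window positions whose seed at some offset matches exactly."""
        sorted_codes = chrom_data["seed_sorted"]
        pos = chrom_data["seed_pos"]
        n_windows = len(chrom_data["codes"])
        hits: list[np.ndarray] = []
        for i, seed_code in enumerate(codes_by_seed):
            lo = np.searchsorted(sorted_codes, np.uint64(seed_code), side="left")
            hi = np.searchsorted(sorted_codes, np.uint64(seed_code), side="right")
            starts = pos[lo:hi] - i * self.seed_len
            hits.append(starts[(starts >= 0) & (starts < n_windows)])
        if not hits:
            return np.empty(0, dtype=np.int64)
        return np.unique(np.concatenate(hits))

    def placements_one_strand(
        self, primer_seq: str, chrom: str, max_mismatch: int
    ) -> list[tuple[int, int]]:
        """(pos, mismatches) for plus-strand windows matching *primer_seq*."""
        data = self._chroms[chrom]
        k = self.primer_len
        if len(primer_seq) != k:
            raise ValueError(f"primer length {len(primer_seq)} != index length {k}")
        if max_mismatch >= self.n_seeds:
            raise ValueError(
                "seed index only complete for max_mismatch < number of seeds"
            )
        seeds = [
            _kmer.pack_seq(primer_seq[i * self.seed_len : (i + 1) * self.seed_len])
            for i in range(self.n_seeds)
        ]
        cand = self._candidates(data, seeds)
        if len(cand) == 0:
            return []
        mism = _kmer.hamming_counts(data["codes"][cand], _kmer.pack_seq(primer_seq), k)
        keep = mism <= max_mismatch
        return list(zip(cand[keep].tolist(), mism[keep].tolist()))


def count_placements(
    primer_seq: str,
    genome: ReferenceGenome,
    max_mismatch: int = MAX_MISMATCH_GENOME,
    index: GenomeIndex | None = None,
) -> list[PrimerPlacement]:
    """All placements of *primer_seq* on both strands at <= *max_mismatch*.

    A minus-strand placement at position ``pos`` means the reverse complement
    of the primer matches the plus-strand window starting at ``pos``.
    """
    if "N" in primer_seq:
        raise ValueError("primer must be N-free")
    if index is None:
        index = GenomeIndex(genome, primer_len=len(primer_seq))
    rc = reverse_complement(primer_seq)
    placements: list[PrimerPlacement] = []
    for chrom in genome.chroms():
        if genome.length(chrom) < len(primer_seq):
            continue
        for pos, mm in index.placements_one_strand(primer_seq, chrom, max_mismatch):
            placements.append(PrimerPlacement(chrom, pos, "+", mm))
        for pos, mm in index.placements_one_strand(rc, chrom, max_mismatch):
            placements.append(PrimerPlacement(chrom, pos, "-", mm))
    return placements


def filter_unique_pairs(
    pairs: list[EPCRPrimerPair],
    genome: ReferenceGenome,
    max_mismatch: int = MAX_MISMATCH_GENOME,
    index: GenomeIndex | None = None,
) -> list[EPCRPrimerPair]:
    """Retain pairs whose forward AND reverse primers are each genome-unique.

    Uniqueness is per-primer: exactly one placement across both strands at
    <= *max_mismatch* (necessarily the design placement).  Order preserved.
    """
    if not pairs:
        return []
    if index is None:
        index = GenomeIndex(genome, primer_len=len(pairs[0].fwd_seq))
    cache: dict[str, bool] = {}

    def is_unique(primer: str) -> bool:
        if primer not in cache:
            n = 0
            rc = reverse_complement(primer)
            for chrom in genome.chroms():
                if genome.length(chrom) < len(primer):
                    continue
                n += len(index.placements_one_strand(primer, chrom, max_mismatch))
                n += len(index.placements_one_strand(rc, chrom, max_mismatch))
                if n > 1:
                    break
            cache[primer] = n == 1
        return cache[primer]

    return [p for p in pairs if is_unique(p.fwd_seq) and is_unique(p.rev_seq)]
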
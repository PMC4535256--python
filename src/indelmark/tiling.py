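"""Tile the reference genome with virtual e-PCR primer pairs.

Each pair is a forward ``primer_len``-mer, a ``gap``-bp spacer, and the
reverse complement of the next ``primer_len``-mer, so the reference amplicon
is ``2 * primer_len + gap`` bp (60 bp under defaults).  Successive pairs start
``step`` bp apart, laid independently per chromosome from offset 0.  Pairs
whose primers overlap an N are dropped, not shifted.
"""

from __future__ import annotations

from dataclasses import dataclass

from .io_formats import ReferenceGenome, reverse_complement

__all__ = ["EPCRPrimerPair", "design_tiled_pairs", "PRIMER_LEN", "GAP", "STEP"]

PRIMER_LEN = 20
GAP = 20
STEP = 20


@dataclass(frozen=True)
class EPCRPrimerPair:
    """A virtual primer pair anchored at a tiled genomic locus."""

    locus_id: str
    chrom: str
    start: int  # 0-based first base of the forward primer
    fwd_seq: str
    rev_seq: str
    ref_amplicon_len: int

    @property
    def gap_interval(self) -> tuple[int, int]:
        """Genomic interval of the variable spacer between the two primers."""
        plen = len(self.fwd_seq)
        return (self.start + plen, self.start + self.ref_amplicon_len - plen)

    @property
    def interval(self) -> tuple[int, int]:
        """Genomic interval of the full reference amplicon."""
        return (self.start, self.start + self.ref_amplicon_len)


def design_tiled_pairs(
    genome: ReferenceGenome,
    primer_len: int = PRIMER_LEN,
    gap: int = GAP,
    step: int = STEP,
) -> list[EPCRPrimerPair]:
    """Generate the genome-covering set of virtual e-PCR primer pairs.

    Starts are ``0, step, 2*step, ...`` with the full amplicon inside the
    chromosome.  On N-free sequence of length L under defaults the count is
    ``floor((L - 60) / 20) + 1`` for L >= 60.
    """
    if min(primer_len, gap, step) < 1:
        raise ValueError("primer_len, gap and step must all be >= 1")
    span = 2 * primer_len + gap
    pairs: list[EPCRPrimerPair] = []
    for chrom, seq in genome.sequences.items():
        for start in range(0, len(seq) - span + 1, step):
            fwd = seq[start : start + primer_len]
            rev_site = seq[start + primer_len + gap : start + span]
            if "N" in fwd or "N" in rev_site:
                continue
            pairs.append(
                EPCRPrimerPair(
                    locus_id=f"{chrom}:{start}",
                    chrom=chrom,
                    start=start,
                    fwd_seq=fwd,
                    rev_seq=reverse_complement(rev_site),
                    ref_amplicon_len=span,
                )
            )
    return pairs
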
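"""Readers/writers for the standard formats the pipeline touches, plus core
sequence utilities.

All coordinates are 0-based half-open in memory; emitted tables use 1-based
inclusive positions (stated in their column headers).  FASTQ qualities are
always Phred+33 — no autodetection.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO

__all__ = [
    "ReferenceGenome",
    "Read",
    "Transcript",
    "FeatureSet",
    "FormatError",
    "read_fasta",
    "write_fasta",
    "read_fastq",
    "write_fastq",
    "read_gff3",
    "reverse_complement",
]

VALID_BASES = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
PHRED_OFFSET = 33


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass
class ReferenceGenome:
    """Chromosome name -> uppercase DNA string (alphabet A,C,G,T,N)."""

    sequences: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, seq in self.sequences.items():
            if not seq:
                raise FormatError(f"empty sequence for chromosome {name!r}")
            bad = set(seq) - VALID_BASES
            if bad:
                raise FormatError(
                    f"chromosome {name!r} contains non-ACGTN characters: {sorted(bad)}"
                )

    def __getitem__(self, chrom: str) -> str:
        return self.sequences[chrom]

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sequences

    def chroms(self) -> list[str]:
        return list(self.sequences)

    def length(self, chrom: str) -> int:
        return len(self.sequences[chrom])

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.sequences.values())


@dataclass
class Read:
    """A sequencing read with per-base Phred qualities."""

    read_id: str
    seq: str
    quals: list[int]

    def __post_init__(self) -> None:
        if len(self.seq) < 1:
            raise FormatError(f"read {self.read_id!r}: empty sequence")
        if len(self.seq) != len(self.quals):
            raise FormatError(
                f"read {self.read_id!r}: sequence length {len(self.seq)} != "
                f"quality length {len(self.quals)}"
            )


@dataclass
class Transcript:
    """One transcript model; all intervals 0-based half-open, sorted."""

    chrom: str
    strand: str
    gene_id: str
    transcript_id: str
    exons: list[tuple[int, int]]
    cds: list[tuple[int, int]]
    utr5: list[tuple[int, int]]
    utr3: list[tuple[int, int]]

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    def introns(self) -> list[tuple[int, int]]:
        return [
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
            if self.exons[i + 1][0] > self.exons[i][1]
        ]


@dataclass
class FeatureSet:
    """Gene annotation as a flat list of transcript models."""

    transcripts: list[Transcript] = field(default_factory=list)

    def by_chrom(self) -> dict[str, list[Transcript]]:
        out: dict[str, list[Transcript]] = {}
        for tx in self.transcripts:
            out.setdefault(tx.chrom, []).append(tx)
        return out


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def reverse_complement(seq: str) -> str:
    """Watson–Crick reverse complement over A,C,G,T,N (N maps to N)."""
    bad = set(seq) - VALID_BASES
    if bad:
        raise ValueError(f"invalid characters for reverse_complement: {sorted(bad)}")
    return seq.translate(_COMPLEMENT)[::-1]


def read_fasta(path: str | Path) -> ReferenceGenome:
    """Load a FASTA file into a :class:`ReferenceGenome` (sequences uppercased).

    Raises :class:`FormatError` on duplicate record names, empty records,
    non-ACGTN characters, or a file that does not start with a header line.
    """
    with _open_text(path) as fh:
        first = fh.readline()
        if first and not first.startswith(">"):
            raise FormatError(f"{path}: line 1: expected FASTA header starting with '>'")
    sequences: dict[str, str] = {}
    with _open_text(path) as fh:
        for record in SeqIO.parse(fh, "fasta"):
            if record.id in sequences:
                raise FormatError(f"{path}: duplicate record name {record.id!r}")
            sequences[record.id] = str(record.seq).upper()
    if not sequences:
        raise FormatError(f"{path}: no FASTA records found")
    return ReferenceGenome(sequences)


def write_fasta(genome: ReferenceGenome, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fastq(path: str | Path) -> Iterator[Read]:
    """Stream reads from a 4-line-record FASTQ file (Phred+33).

    Length mismatches between sequence and quality string surface as a
    :class:`FormatError` naming the offending record.
    """
    with _open_text(path) as fh:
        try:
            for record in SeqIO.parse(fh, "fastq"):
                yield Read(
                    read_id=record.id,
                    seq=str(record.seq).upper(),
                    quals=list(record.letter_annotations["phred_quality"]),
                )
        except ValueError as exc:  # Bio.SeqIO signals truncation/mismatch this way
            raise FormatError(f"{path}: {exc}") from exc


def write_fastq(reads: Iterable[Read], path: str | Path) -> None:
    with open(path, "w") as fh:
        for read in reads:
            qual = "".join(chr(q + PHRED_OFFSET) for q in read.quals)
            fh.write(f"@{read.read_id}\n{read.seq}\n+\n{qual}\n")


def _intervals(features, chrom_len: int | None = None) -> list[tuple[int, int]]:
    ivals = sorted((f.start - 1, f.end) for f in features)
    for s, e in ivals:
        if s < 0 or e <= s:
            raise FormatError(f"invalid feature interval {s + 1}..{e}")
        if chrom_len is not None and e > chrom_len:
            raise FormatError(f"feature interval {s + 1}..{e} exceeds chromosome length")
    return ivals


def read_gff3(path: str | Path, genome: ReferenceGenome | None = None) -> FeatureSet:
    """Parse gene models (gene/mRNA/exon/CDS/UTR features) from a GFF3 file.

    GFF3 1-based inclusive coordinates are converted to 0-based half-open.
    A transcript without a parent gene, an unknown strand, exon overlap, or a
    CDS outside its mRNA span is a :class:`FormatError`.  When *genome* is
    given, intervals are checked against chromosome bounds.
    """
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    transcripts: list[Transcript] = []
    for mrna in db.features_of_type(("mRNA", "transcript")):
        if mrna.strand not in ("+", "-"):
            raise FormatError(f"transcript {mrna.id}: unknown strand {mrna.strand!r}")
        parents = [p.id for p in db.parents(mrna, featuretype="gene")]
        if not parents:
            raise FormatError(f"transcript {mrna.id}: no parent gene feature")
        chrom_len = genome.length(mrna.seqid) if genome and mrna.seqid in genome else None

        def _children(ftype):
            return _intervals(db.children(mrna, featuretype=ftype), chrom_len)

        exons = _children("exon")
        if not exons:
            # fall back to the mRNA span as a single exon
            exons = _intervals([mrna], chrom_len)
        for (s1, e1), (s2, _) in zip(exons, exons[1:]):
            if s2 < e1:
                raise FormatError(f"transcript {mrna.id}: overlapping exons")
        cds = _children("CDS")
        span = (exons[0][0], exons[-1][1])
        for s, e in cds:
            if s < span[0] or e > span[1]:
                raise FormatError(
                    f"transcript {mrna.id}: CDS {s + 1}..{e} outside mRNA span"
                )
        transcripts.append(
            Transcript(
                chrom=mrna.seqid,
                strand=mrna.strand,
                gene_id=parents[0],
                transcript_id=mrna.id,
                exons=exons,
                cds=cds,
                utr5=_children("five_prime_UTR"),
                utr3=_children("three_prime_UTR"),
            )
        )
    return FeatureSet(transcripts)
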
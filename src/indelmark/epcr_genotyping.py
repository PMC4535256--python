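"""In-silico PCR of primer pairs directly against short reads.

For each locus and sample, every quality-filtered read is searched (in both
orientations) for the forward primer site and, downstream of it, the reverse
primer binding site, each within a mismatch tolerance (default 1).  The
spanned distance is the amplicon length; across a sample's reads the most
frequent length is the sample's allele call (ties go to the smaller length,
and within one read the shortest product wins, as the shortest competing PCR
product amplifies preferentially).

Reads are filtered first: a read is kept iff at least ``min_fraction`` of its
bases have Phred quality >= ``q_cutoff`` (defaults 0.7 and Q20).

``epcr_on_read`` is the reference implementation of the per-read search;
``genotype_sample`` runs a vectorised candidate screen (batched 10-mer codes,
pigeonhole-exact for tolerance 1 on 20-mers) that must produce identical
calls — equality is property-tested.  Primer sites overlapping an N never
match in either path.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Iterable, Iterator

import numpy as np

from . import _kmer
from .io_formats import Read, reverse_complement
from .tiling import EPCRPrimerPair

__all__ = [
    "AmpliconCall",
    "filter_reads",
    "epcr_on_read",
    "genotype_sample",
    "modal_length",
]

MAX_MISMATCH_READ = 1
Q_CUTOFF = 20
MIN_FRACTION = 0.7


@dataclass
class AmpliconCall:
    """Per-locus, per-sample modal amplicon length with its read support."""

    locus_id: str
    sample_id: str
    modal_length: int
    support: int
    length_histogram: dict[int, int]


def filter_reads(
    reads: Iterable[Read],
    q_cutoff: int = Q_CUTOFF,
    min_fraction: float = MIN_FRACTION,
) -> Iterator[Read]:
    """Yield reads whose fraction of bases at quality >= q_cutoff meets the
    threshold (boundary inclusive)."""
    if q_cutoff < 0:
        raise ValueError("q_cutoff must be >= 0")
    if not 0 < min_fraction <= 1:
        raise ValueError("min_fraction must be in (0, 1]")
    for read in reads:
        n_good = sum(q >= q_cutoff for q in read.quals)
        if n_good >= min_fraction * len(read.quals):
            yield read


def _hamming_le(a: str, b: str, limit: int) -> bool:
    mism = 0
    for x, y in zip(a, b):
        if x == "N":  # windows overlapping N never match
            return False
        if x != y:
            mism += 1
            if mism > limit:
                return False
    return True


def _products_in_seq(seq: str, fwd: str, rev_site: str, max_mismatch: int) -> list[int]:
    """All product lengths from one orientation of one read.

    A product needs the forward primer at i and the reverse binding site at
    j >= i + primer_len (non-overlapping sites), each at <= max_mismatch;
    length = j + primer_len - i.
    """
    plen = len(fwd)
    n = len(seq)
    fwd_hits = [
        i for i in range(n - plen + 1) if _hamming_le(seq[i : i + plen], fwd, max_mismatch)
    ]
    if not fwd_hits:
        return []
    rev_hits = [
        j for j in range(n - plen + 1) if _hamming_le(seq[j : j + plen], rev_site, max_mismatch)
    ]
    out = []
    for i in fwd_hits:
        for j in rev_hits:
            if j >= i + plen:
                out.append(j + plen - i)
    return out


def epcr_on_read(
    pair: EPCRPrimerPair, read: Read, max_mismatch: int = MAX_MISMATCH_READ
) -> int | None:
    """Amplicon length of *pair* on *read*, or None for no product.

    Both read orientations are searched; with several site combinations the
    shortest product is returned.
    """
    rev_site = reverse_complement(pair.rev_seq)
    products = _products_in_seq(read.seq, pair.fwd_seq, rev_site, max_mismatch)
    products += _products_in_seq(
        reverse_complement(read.seq), pair.fwd_seq, rev_site, max_mismatch
    )
    return min(products) if products else None


def modal_length(histogram: dict[int, int]) -> int:
    """Most frequent length; frequency ties broken by the smaller length."""
    return min(histogram, key=lambda length: (-histogram[length], length))


def _batch_window_codes(arr: np.ndarray, k: int) -> np.ndarray:
    """Packed k-mer codes for every window of every row of a 0..3/255 matrix.

    Windows containing a padding/N value (255) get the bit-63 sentinel.
    """
    n_reads, length = arr.shape
    n_win = length - k + 1
    if n_win <= 0:
        return np.empty((n_reads, 0), dtype=np.uint64)
    bad = arr == 255
    a = np.where(bad, 0, arr).astype(np.uint64)
    codes = np.zeros((n_reads, n_win), dtype=np.uint64)
    bad_any = np.zeros((n_reads, n_win), dtype=bool)
    for j in range(k):
        codes = (codes << np.uint64(2)) | a[:, j : n_win + j]
        bad_any |= bad[:, j : n_win + j]
    codes[bad_any] = np.uint64(1) << np.uint64(63)
    return codes


class _PairScreen:
    """Vectorised candidate screen for all pairs against batches of reads.

    For tolerance <= 1 on a 20-mer, at least one of its two 10-mer halves
    matches exactly, so exact half-site hits are a complete candidate set.
    """

    def __init__(self, pairs: list[EPCRPrimerPair], max_mismatch: int):
        if max_mismatch > 1:
            raise ValueError("half-site screen is only complete for max_mismatch <= 1")
        self.pairs = pairs
        self.max_mismatch = max_mismatch
        self.plen = len(pairs[0].fwd_seq) if pairs else 20
        if self.plen % 2:
            raise ValueError("primer length must be even for the half-site screen")
        self.half = self.plen // 2
        # (half_index, packed half code) -> [(pair_idx, role)], role 0 = fwd
        # primer site, role 1 = reverse-primer binding site (rc of rev_seq)
        self.by_half: dict[tuple[int, int], list[tuple[int, int]]] = defaultdict(list)
        self.site_codes: dict[tuple[int, int], int] = {}
        for idx, pair in enumerate(pairs):
            rev_site = reverse_complement(pair.rev_seq)
            for role, site in enumerate((pair.fwd_seq, rev_site)):
                self.site_codes[(idx, role)] = _kmer.pack_seq(site)
                for h in (0, 1):
                    half_seq = site[h * self.half : (h + 1) * self.half]
                    self.by_half[(h, _kmer.pack_seq(half_seq))].append((idx, role))
        self.half_keys = {
            h: np.sort(np.array(sorted({c for (hh, c) in self.by_half if hh == h}), dtype=np.uint64))
            for h in (0, 1)
        }

    def batch_products(self, seqs: list[str]) -> list[dict[int, int]]:
        """Per sequence: pair_idx -> shortest product (one orientation)."""
        if not seqs or not self.pairs:
            return [dict() for _ in seqs]
        length = max(len(s) for s in seqs)
        arr = np.full((len(seqs), length), 255, dtype=np.uint8)
        for r, s in enumerate(seqs):
            arr[r, : len(s)] = _kmer.encode(s)
        codes_half = _batch_window_codes(arr, self.half)
        codes_full = _batch_window_codes(arr, self.plen)
        n_win = codes_full.shape[1]
        if n_win == 0:
            return [dict() for _ in seqs]
        hit = np.isin(codes_half[:, :n_win], self.half_keys[0])
        hit |= np.isin(codes_half[:, self.half : self.half + n_win], self.half_keys[1])
        rows, cols = np.nonzero(hit)
        # collect verified site hits per read
        site_hits: list[dict[int, dict[int, list[int]]]] = [
            defaultdict(dict) for _ in seqs
        ]
        mask = int(_kmer.base_mask(self.plen))
        for r, p in zip(rows.tolist(), cols.tolist()):
            full_code = int(codes_full[r, p])
            if full_code >> 63:
                continue
            seen: set[tuple[int, int]] = set()
            for h in (0, 1):
                key = (h, int(codes_half[r, p + h * self.half]))
                for idx_role in self.by_half.get(key, ()):
                    if idx_role in seen:
                        continue
                    seen.add(idx_role)
                    x = full_code ^ self.site_codes[idx_role]
                    mm = ((x | (x >> 1)) & mask).bit_count()
                    if mm <= self.max_mismatch:
                        idx, role = idx_role
                        site_hits[r][idx].setdefault(role, []).append(p)
        results: list[dict[int, int]] = []
        for r in range(len(seqs)):
            prods: dict[int, int] = {}
            for idx, roles in site_hits[r].items():
                fwd_pos = roles.get(0)
                rev_pos = roles.get(1)
                if not fwd_pos or not rev_pos:
                    continue
                best = None
                for i in fwd_pos:
                    for j in rev_pos:
                        if j >= i + self.plen:
                            prod = j + self.plen - i
                            if best is None or prod < best:
                                best = prod
                if best is not None:
                    prods[idx] = best
            results.append(prods)
        return results


def genotype_sample(
    pairs: list[EPCRPrimerPair],
    reads: Iterable[Read],
    sample_id: str = "sample",
    max_mismatch: int = MAX_MISMATCH_READ,
    min_support: int = 1,
    batch_size: int = 20000,
) -> list[AmpliconCall]:
    """e-PCR every pair against every read; one modal-length call per locus.

    Emits an :class:`AmpliconCall` for each locus with at least
    *min_support* reads yielding a product (default 1, as in the source
    protocol's no-minimum policy).
    """
    screen = _PairScreen(pairs, max_mismatch)
    histograms: dict[int, Counter] = defaultdict(Counter)
    batch: list[str] = []

    def flush() -> None:
        fwd_res = screen.batch_products(batch)
        rev_res = screen.batch_products([reverse_complement(s) for s in batch])
        for merged, extra in zip(fwd_res, rev_res):
            for idx, length in extra.items():
                if idx not in merged or length < merged[idx]:
                    merged[idx] = length
            for idx, length in merged.items():
                histograms[idx][length] += 1
        batch.clear()

    for read in reads:
        batch.append(read.seq)
        if len(batch) >= batch_size:
            flush()
    flush()

    calls: list[AmpliconCall] = []
    for idx in sorted(histograms):
        hist = dict(histograms[idx])
        mode = modal_length(hist)
        if hist[mode] < min_support:
            continue
        calls.append(
            AmpliconCall(
                locus_id=pairs[idx].locus_id,
                sample_id=sample_id,
                modal_length=mode,
                support=hist[mode],
                length_histogram=hist,
            )
        )
    return calls
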
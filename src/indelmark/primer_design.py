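"""Wet-lab PCR primer design around selected indel loci.

The picker enumerates every (left, right) primer candidate inside a template
window centred on the locus's 20-bp variable region and keeps pairs passing
all hard constraints: primer length 20–28 nt (optimum 23), nearest-neighbor
melting temperature 60–65 °C (optimum 63), GC content 30–70 % (optimum 50),
Tm spread <= 3 °C, product size inside the gel-mode range, and optionally a
3' G/C clamp.  Among feasible pairs it returns the one minimising

    penalty = |Tm_l - Tm_opt| + |Tm_r - Tm_opt|
              + 0.1  * (|len_l - len_opt| + |len_r - len_opt|)
              + 0.05 * (|GC_l - GC_opt| + |GC_r - GC_opt|)

with ties resolved toward the leftmost left primer, then the shortest
product, so identical inputs always give byte-identical designs.  Penalties
are compared at 1e-6 resolution: candidate pairs whose analytic penalties
are equal (e.g. shifted primers with identical nearest-neighbor sums) must
tie deterministically rather than by floating-point summation order.

Tm uses SantaLucia's unified nearest-neighbor parameters with initiation and
symmetry corrections at 50 mM monovalent salt and 50 nM primer (both
configurable; the concentrations are conventions, not measured values).
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.SeqUtils import MeltingTemp as _mt

from .io_formats import ReferenceGenome, reverse_complement

__all__ = [
    "PrimerDesignParams",
    "PcrPrimerDesign",
    "PAGE_PARAMS",
    "AGAROSE_PARAMS",
    "gc_content",
    "melting_temperature",
    "design_pcr_primers",
]

MONOVALENT_MM = 50.0
PRIMER_NM = 50.0
TM_LEN_MIN = 15
TM_LEN_MAX = 36


@dataclass(frozen=True)
class PrimerDesignParams:
    len_min: int = 20
    len_opt: int = 23
    len_max: int = 28
    tm_min: float = 60.0
    tm_opt: float = 63.0
    tm_max: float = 65.0
    gc_min: float = 30.0
    gc_opt: float = 50.0
    gc_max: float = 70.0
    product_min: int = 60
    product_max: int = 100
    max_tm_spread: float = 3.0
    require_gc_clamp: bool = True

    def __post_init__(self) -> None:
        for lo, opt, hi, name in (
            (self.len_min, self.len_opt, self.len_max, "length"),
            (self.tm_min, self.tm_opt, self.tm_max, "Tm"),
            (self.gc_min, self.gc_opt, self.gc_max, "GC"),
            (self.product_min, self.product_min, self.product_max, "product"),
        ):
            if not lo <= opt <= hi:
                raise ValueError(f"{name} triplet must satisfy min <= opt <= max")


#: PAGE markers: short products a polyacrylamide gel resolves.
PAGE_PARAMS = PrimerDesignParams(product_min=60, product_max=100)
#: agarose markers: longer products for lower-resolution gels.
AGAROSE_PARAMS = PrimerDesignParams(product_min=150, product_max=300)
#: template flank beyond the 20-bp variable region needed per mode
DEFAULT_FLANK = {"PAGE": 40, "agarose": 150}


@dataclass(frozen=True)
class PcrPrimerDesign:
    left_seq: str
    right_seq: str
    left_tm: float
    right_tm: float
    left_gc: float
    right_gc: float
    product_len: int
    penalty: float
    left_start: int = 0  # window-relative 0-based start of the left primer


def gc_content(seq: str) -> float:
    """GC percentage of an ACGT string."""
    if not seq:
        raise ValueError("empty sequence")
    if set(seq) - set("ACGT"):
        raise ValueError(f"gc_content requires ACGT only, got {seq!r}")
    return 100.0 * (seq.count("G") + seq.count("C")) / len(seq)


def melting_temperature(
    seq: str,
    monovalent_mM: float = MONOVALENT_MM,
    primer_nM: float = PRIMER_NM,
) -> float:
    """Nearest-neighbor Tm in °C (SantaLucia 1998 unified parameters)."""
    if not TM_LEN_MIN <= len(seq) <= TM_LEN_MAX:
        raise ValueError(
            f"Tm defined for lengths {TM_LEN_MIN}..{TM_LEN_MAX}, got {len(seq)}"
        )
    if set(seq) - set("ACGT"):
        raise ValueError(f"Tm requires ACGT only, got {seq!r}")
    return float(
        _mt.Tm_NN(
            seq,
            nn_table=_mt.DNA_NN3,
            Na=monovalent_mM,
            dnac1=primer_nM,
            dnac2=0,
            saltcorr=5,
        )
    )


def _candidates(window: str, params: PrimerDesignParams) -> list[dict]:
    """All single-primer candidates (as left-primer substrings) that pass the
    hard length/Tm/GC constraints.  Each entry keys on window start/length."""
    out = []
    n = len(window)
    for start in range(n):
        for length in range(params.len_min, params.len_max + 1):
            end = start + length
            if end > n:
                break
            seq = window[start:end]
            if "N" in seq:
                continue
            gc = gc_content(seq)
            if not params.gc_min <= gc <= params.gc_max:
                continue
            tm = melting_temperature(seq)
            if not params.tm_min <= tm <= params.tm_max:
                continue
            out.append({"start": start, "end": end, "seq": seq, "gc": gc, "tm": tm})
    return out


def _single_penalty(cand: dict, params: PrimerDesignParams) -> float:
    return (
        abs(cand["tm"] - params.tm_opt)
        + 0.1 * abs((cand["end"] - cand["start"]) - params.len_opt)
        + 0.05 * abs(cand["gc"] - params.gc_opt)
    )


def design_in_window(
    window: str, params: PrimerDesignParams
) -> PcrPrimerDesign | None:
    """Penalty-minimal feasible primer pair inside a template window.

    The left primer is a window substring; the right primer is the reverse
    complement of a downstream window substring.  Product length is measured
    from the left primer's 5' end to the right primer's 5' end inclusive.
    Returns None when no pair satisfies every hard constraint.
    """
    cands = _candidates(window, params)
    if params.require_gc_clamp:
        lefts = [c for c in cands if c["seq"][-1] in "GC"]
        # right primer's 3' end is the reverse complement of the site's first base
        rights = [c for c in cands if c["seq"][0] in "GC"]
    else:
        lefts, rights = cands, cands
    best: tuple[float, int, int] | None = None
    best_pair: tuple[dict, dict] | None = None
    for lc in lefts:
        lpen = _single_penalty(lc, params)
        for rc in rights:
            if rc["start"] < lc["end"]:
                continue
            product = rc["end"] - lc["start"]
            if not params.product_min <= product <= params.product_max:
                continue
            if abs(lc["tm"] - rc["tm"]) > params.max_tm_spread:
                continue
            key = (round(lpen + _single_penalty(rc, params), 6), lc["start"], product)
            if best is None or key < best:
                best = key
                best_pair = (lc, rc)
    if best_pair is None:
        return None
    lc, rc = best_pair
    return PcrPrimerDesign(
        left_seq=lc["seq"],
        right_seq=reverse_complement(rc["seq"]),
        left_tm=lc["tm"],
        right_tm=rc["tm"],
        left_gc=lc["gc"],
        right_gc=rc["gc"],
        product_len=rc["end"] - lc["start"],
        penalty=best[0],
        left_start=lc["start"],
    )


def design_pcr_primers(
    genome: ReferenceGenome,
    locus: tuple[str, int, int],
    params: PrimerDesignParams = PAGE_PARAMS,
    window_flank: int = 40,
) -> PcrPrimerDesign | None:
    """Design primers around a locus's variable region.

    *locus* is (chrom, start, end) of the 20-bp variable region, 0-based
    half-open.  The template window is the region extended by *window_flank*
    on each side (40 bp for PAGE's 100-bp window; agarose needs ~150 bp to
    reach 300-bp products) and must fit the chromosome.
    """
    chrom, start, end = locus
    if chrom not in genome:
        raise ValueError(f"unknown chromosome {chrom!r}")
    w_start, w_end = start - window_flank, end + window_flank
    if w_start < 0 or w_end > genome.length(chrom):
        raise ValueError(
            f"template window {w_start}..{w_end} outside chromosome {chrom}"
        )
    return design_in_window(genome[chrom][w_start:w_end], params)
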
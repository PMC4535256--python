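import math

import pytest

from indelmark.io_formats import ReferenceGenome, reverse_complement
from indelmark.primer_design import (
    AGAROSE_PARAMS,
    PAGE_PARAMS,
    PrimerDesignParams,
    design_in_window,
    design_pcr_primers,
    gc_content,
    melting_temperature,
)
from indelmark.simulate import simulate_reference

from conftest import random_dna

# SantaLucia unified nearest-neighbor table, typed independently from the
# published parameters: (dH kcal/mol, dS cal/mol/K) per 5'->3' dinucleotide.
NN_TABLE = {
    "AA": (-7.9, -22.2), "AT": (-7.2, -20.4), "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7), "GT": (-8.4, -22.4), "CT": (-7.8, -21.0),
    "GA": (-8.2, -22.2), "CG": (-10.6, -27.2), "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9),
}
_COMP = str.maketrans("ACGT", "TGCA")


def hand_nn_tm(seq: str, Na_mM=50.0, c_nM=50.0) -> float:
    """Hand-summed nearest-neighbor Tm: stacking terms + initiation +
    symmetry correction + salt-adjusted entropy."""
    dH = dS = 0.0
    for i in range(len(seq) - 1):
        pair = seq[i : i + 2]
        if pair not in NN_TABLE:
            pair = pair.translate(_COMP)[::-1]
        h, s = NN_TABLE[pair]
        dH += h
        dS += s
    for terminal in (seq[0], seq[-1]):
        if terminal in "GC":
            dH += 0.1
            dS += -2.8
        else:
            dH += 2.3
            dS += 4.1
    if seq == seq.translate(_COMP)[::-1]:
        dS += -1.4
    dS += 0.368 * (len(seq) - 1) * math.log(Na_mM / 1000.0)
    return dH * 1000.0 / (dS + 1.987 * math.log(c_nM * 1e-9)) - 273.15


class TestGcContent:
    @pytest.mark.parametrize(
        "seq,expected", [("ATGC", 50.0), ("AAAA", 0.0), ("GGGGCCCCAT", 80.0)]
    )
    def test_examples(self, seq, expected):
        assert gc_content(seq) == expected

    def test_n_is_error(self):
        with pytest.raises(ValueError):
            gc_content("ACGN")


class TestMeltingTemperature:
    def test_duplex_symmetry(self, rng):
        for _ in range(20):
            s = random_dna(rng, 20)
            assert melting_temperature(s) == pytest.approx(
                melting_temperature(reverse_complement(s)), abs=1e-9
            )

    def test_gc_beats_at(self):
        assert melting_temperature("GC" * 10) > melting_temperature("AT" * 10)

    def test_frozen_23mer_matches_hand_summed_table(self):
        seq = "GCGACCCCTAAGTAGGAGCGTAT"
        frozen = 59.22421602151559  # computed once with hand_nn_tm
        assert hand_nn_tm(seq) == pytest.approx(frozen, abs=1e-9)
        assert melting_temperature(seq) == pytest.approx(frozen, abs=1e-6)

    def test_random_primers_match_hand_oracle(self, rng):
        for length in (15, 20, 28, 36):
            for _ in range(10):
                s = random_dna(rng, length)
                assert melting_temperature(s) == pytest.approx(hand_nn_tm(s), abs=1e-6)

    @pytest.mark.parametrize("length", [14, 37])
    def test_out_of_range_length(self, length):
        with pytest.raises(ValueError):
            melting_temperature("A" * length)


def oracle_design(window: str, params: PrimerDesignParams):
    """Naive exhaustive feasible-set enumeration + penalty minimisation."""
    singles = []
    n = len(window)
    for s in range(n):
        for ln in range(params.len_min, params.len_max + 1):
            e = s + ln
            if e > n:
                break
            seq = window[s:e]
            if "N" in seq:
                continue
            gc = 100.0 * (seq.count("G") + seq.count("C")) / ln
            if not params.gc_min <= gc <= params.gc_max:
                continue
            tm = hand_nn_tm(seq)
            if not params.tm_min <= tm <= params.tm_max:
                continue
            pen = (
                abs(tm - params.tm_opt)
                + 0.1 * abs(ln - params.len_opt)
                + 0.05 * abs(gc - params.gc_opt)
            )
            singles.append((s, e, seq, gc, tm, pen))
    best = best_pair = None
    for ls, le, lseq, lgc, ltm, lpen in singles:
        if params.require_gc_clamp and lseq[-1] not in "GC":
            continue
        for rs, re, rseq, rgc, rtm, rpen in singles:
            if params.require_gc_clamp and rseq[0] not in "GC":
                continue
            if rs < le:
                continue
            product = re - ls
            if not params.product_min <= product <= params.product_max:
                continue
            if abs(ltm - rtm) > params.max_tm_spread:
                continue
            key = (round(lpen + rpen, 6), ls, product)  # same tie resolution as the picker
            if best is None or key < best:
                best = key
                best_pair = (lseq, reverse_complement(rseq), product)
    return best_pair


def check_hard_constraints(design, params):
    for seq, tm, gc in (
        (design.left_seq, design.left_tm, design.left_gc),
        (design.right_seq, design.right_tm, design.right_gc),
    ):
        assert params.len_min <= len(seq) <= params.len_max
        assert params.tm_min <= tm <= params.tm_max
        assert params.gc_min <= gc <= params.gc_max
    assert abs(design.left_tm - design.right_tm) <= params.max_tm_spread
    assert params.product_min <= design.product_len <= params.product_max
    if params.require_gc_clamp:
        assert design.left_seq[-1] in "GC" and design.right_seq[-1] in "GC"


class TestDesignPicker:
    def test_at_only_window_is_infeasible(self):
        assert design_in_window("AT" * 100, PAGE_PARAMS) is None

    @pytest.mark.parametrize("i", range(8))
    def test_matches_exhaustive_oracle(self, i):
        window = simulate_reference(200 + 25 * i, seed=600 + i)["chr1"]
        params = PAGE_PARAMS if i % 2 == 0 else AGAROSE_PARAMS
        got = design_in_window(window, params)
        expected = oracle_design(window, params)
        if expected is None:
            assert got is None
        else:
            assert (got.left_seq, got.right_seq, got.product_len) == expected
            check_hard_constraints(got, params)

    def test_relaxing_tm_never_loses_feasibility(self):
        for i in range(4):
            window = simulate_reference(220, seed=700 + i)["chr1"]
            strict = design_in_window(window, PAGE_PARAMS)
            relaxed_params = PrimerDesignParams(tm_min=50.0, product_min=60, product_max=100)
            relaxed = design_in_window(window, relaxed_params)
            if strict is not None:
                assert relaxed is not None

    def test_determinism(self):
        window = simulate_reference(300, seed=9)["chr1"]
        a = design_in_window(window, PAGE_PARAMS)
        b = design_in_window(window, PAGE_PARAMS)
        assert a == b

    def test_genome_level_window_bounds(self):
        genome = ReferenceGenome({"c": simulate_reference(500, seed=12)["chr1"]})
        with pytest.raises(ValueError):
            design_pcr_primers(genome, ("c", 10, 30), PAGE_PARAMS, window_flank=40)
        design_pcr_primers(genome, ("c", 200, 220), PAGE_PARAMS, window_flank=40)

    def test_params_validation(self):
        with pytest.raises(ValueError):
            PrimerDesignParams(len_min=25, len_opt=23, len_max=28)
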
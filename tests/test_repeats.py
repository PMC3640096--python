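import numpy as np
import pytest

from plastocomp.records import revcomp
from plastocomp.repeats import (
    Occurrence,
    classify_repeat_set,
    find_maximal_repeats,
    group_hits_into_sets,
    iupac_consensus,
    mask_intervals,
    scan_genome,
)

from .oracles import brute_force_repeat_hits

# printed exemplar sequences of the five structural classes
PALINDROME_30 = "AAATATGAAAAATACGTATTTTTCATATTT"      # atpF-atpH region
REVERSAL_30 = "ATTATAWTATATATAATATATATWATATTA"        # trnT-psbD region
TANDEM_UNIT_18 = "TAGTGACGATATTGATGC"                 # ycf2 duplication unit
DISPERSED_35 = "TGCAATAGCTAAATGATGATGAGCAATATCAGTCA"  # psaB/psaA share
INVERTED_29 = "AATAATCACATTAATAGTTACATTGACAG"         # accD hairpin arms


def _rand_seq(rng, n, gc=0.37):
    p = [(1 - gc) / 2, (1 - gc) / 2, gc / 2, gc / 2]
    return "".join(np.array(list("ATCG"))[rng.choice(4, size=n, p=p)])


def test_no_repeats_in_unrepetitive_sequence():
    rng = np.random.default_rng(0)
    seq = _rand_seq(rng, 400, gc=0.5)
    hits = find_maximal_repeats(seq)
    assert all(h.length < 40 for h in hits)  # nothing planted, only flukes


def test_sequence_shorter_than_min_len_is_empty():
    assert find_maximal_repeats("ACGTACGT") == []


def test_palindrome_detected_as_self_symmetric_hit():
    rng = np.random.default_rng(1)
    seq = _rand_seq(rng, 300, 0.5) + PALINDROME_30 + _rand_seq(rng, 300, 0.5)
    hits = find_maximal_repeats(seq)
    sym = [h for h in hits if h.self_symmetric and h.relation == "inverted"]
    assert any(h.occ1.start <= 301 <= h.occ1.end for h in sym)


def test_exemplar_sequences_classify_into_their_types():
    """The five printed exemplars get P, R, T, D and I respectively."""
    rng = np.random.default_rng(2)
    chunks = [_rand_seq(rng, 250, 0.5) for _ in range(7)]
    seq = (
        chunks[0] + PALINDROME_30.replace("W", "A")
        + chunks[1] + REVERSAL_30.replace("W", "A")
        + chunks[2] + TANDEM_UNIT_18 * 4
        + chunks[3] + DISPERSED_35.replace("R", "G").replace("W", "A")
        + chunks[4] + DISPERSED_35.replace("R", "G").replace("W", "A")
        + chunks[5] + INVERTED_29 + "TTTT" + revcomp(INVERTED_29)
        + chunks[6]
    )
    sets = group_hits_into_sets(find_maximal_repeats(seq), seq)
    types = {s.type for s in sets}
    assert {"P", "R", "T", "D", "I"} <= types


def test_palindrome_exemplar_is_own_reverse_complement():
    assert revcomp(PALINDROME_30) == PALINDROME_30


def test_reversal_exemplar_is_own_reversal_not_palindrome():
    assert REVERSAL_30[::-1] == REVERSAL_30
    assert revcomp(REVERSAL_30) != REVERSAL_30


def test_classification_decision_order():
    occ = lambda s, L, st: Occurrence(s, L, st)
    # single palindromic occurrence
    assert classify_repeat_set([occ(1, 30, "+")], [PALINDROME_30]) == "P"
    # single reversal-symmetric occurrence
    assert classify_repeat_set([occ(1, 30, "+")], [REVERSAL_30]) == "R"
    # adjacent same-strand duplication
    assert classify_repeat_set(
        [occ(1, 18, "+"), occ(19, 18, "+")], [TANDEM_UNIT_18] * 2
    ) == "T"
    # opposite strands, dispersed
    assert classify_repeat_set(
        [occ(1, 29, "+"), occ(500, 29, "-")], [INVERTED_29] * 2
    ) == "I"
    # same strand, dispersed
    assert classify_repeat_set(
        [occ(1, 35, "+"), occ(500, 35, "+")], [DISPERSED_35] * 2
    ) == "D"


def test_iupac_consensus_marks_mismatch_columns():
    assert iupac_consensus(["ACGT", "ACGA"]) == "ACGW"
    assert iupac_consensus(["ACGT", "ACGT"]) == "ACGT"
    assert iupac_consensus(["AC", "GT"]) == "RY"


@pytest.mark.parametrize("seed", range(4))
def test_hit_finder_equals_bruteforce_oracle(seed):
    """Seed-and-extend search returns exactly the oracle's maximal windows
    on instances with planted direct/inverted/palindromic content."""
    rng = np.random.default_rng(seed)
    base = _rand_seq(rng, 900)
    unit = _rand_seq(rng, 40, 0.5)
    mutated = unit[:17] + ("A" if unit[17] != "A" else "C") + unit[18:]
    half = _rand_seq(rng, 14, 0.5)
    seq = (
        base[:150] + unit + base[150:350] + mutated + base[350:550]
        + half + revcomp(half) + base[550:700] + revcomp(unit) + base[700:]
    )
    mine = set(find_maximal_repeats(seq))
    oracle = brute_force_repeat_hits(seq)
    assert mine == oracle


def test_every_hit_meets_length_and_identity(small_record):
    hits = find_maximal_repeats(small_record.sequence[:20_000])
    for h in hits:
        assert h.length >= 26
        assert h.identity >= 0.90


def test_masking_excludes_masked_copies():
    rng = np.random.default_rng(9)
    unit = _rand_seq(rng, 40, 0.5)
    base = _rand_seq(rng, 600)
    seq = base[:100] + unit + base[100:400] + unit + base[400:]
    masked = mask_intervals(seq, [(101, 140)])
    hits = [h for h in find_maximal_repeats(masked) if h.length >= 35]
    assert hits == []


def test_scan_genome_recovers_all_planted_types(small_record, small_truth,
                                                small_partition):
    sets = scan_genome(small_record, small_partition)
    expected = {}
    for t in small_truth.repeats:
        expected.setdefault(t.expected, []).append((t.start, t.end))
    got = {}
    for s in sets:
        for o in s.occurrences:
            got.setdefault(s.type, []).append((o.start, o.end))
    for rtype, intervals in expected.items():
        assert rtype in got, f"type {rtype} not recovered"
        for lo, hi in intervals:
            covered = set()
            for o_lo, o_hi in got[rtype]:
                covered.update(range(max(lo, o_lo), min(hi, o_hi) + 1))
            assert covered >= set(range(lo, hi + 1)), (rtype, lo, hi, got[rtype])


def test_scan_genome_suppresses_whole_ir_self_match(small_record,
                                                    small_partition):
    sets = scan_genome(small_record, small_partition)
    ir_len = small_partition.ir_length
    assert all(s.length < ir_len // 2 for s in sets)


def test_ir_hits_mirrored_parenthetically():
    from plastocomp.synthetic import PlantedRepeat, SynthConfig, generate_plastome
    from plastocomp.junctions import detect_inverted_repeat

    cfg = SynthConfig(
        lsc_len=8_000, irb_len=2_500, ssc_len=3_000, seed=13,
        planted_repeats=[PlantedRepeat("T", 36, 2, ("IRb",))],
    )
    rec, truth = generate_plastome(cfg)
    part = detect_inverted_repeat(rec.sequence)
    sets = scan_genome(rec, part)
    tandems = [s for s in sets if s.type == "T"]
    assert tandems and tandems[0].mirrored_starts
    lo, hi = part.ira
    assert all(lo <= m <= hi for m in tandems[0].mirrored_starts)
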
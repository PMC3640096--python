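import math

import numpy as np
import pandas as pd
import pytest

from plastocomp.divergence import (
    SpacerPair,
    align_pair,
    distance_table,
    pair_spacers,
    pairwise_distance,
    rank_and_select,
)
from plastocomp.synthetic import SynthConfig, evolve_pair, generate_plastome

# Frozen oracle pair: 200 sites, 20 transitions, 10 transversions over a
# base-balanced alignment (P = 0.10, Q = 0.05). Expected distances computed
# independently from the closed forms and cross-checked against ape's
# dist.dna (JC69 / K80 / F84, pairwise deletion) before being frozen here.
def _oracle_pair():
    s1 = "A" * 50 + "C" * 50 + "G" * 50 + "T" * 50
    s2 = list(s1)
    for i in range(0, 10):
        s2[i] = "G"  # A->G transitions
    for i in range(50, 60):
        s2[i] = "T"  # C->T transitions
    for i in range(100, 105):
        s2[i] = "T"  # G->T transversions
    for i in range(150, 155):
        s2[i] = "A"  # T->A transversions
    return s1, "".join(s2)


FROZEN = {"JC": 0.1673576635, "K2P": 0.1701811651, "F84": 0.1702808174}


@pytest.mark.parametrize("model", ["JC", "K2P", "F84"])
def test_closed_form_distances_match_frozen_oracle(model):
    s1, s2 = _oracle_pair()
    res = pairwise_distance(s1, s2, model)
    assert res.distance == pytest.approx(FROZEN[model], abs=1e-9)


@pytest.mark.parametrize("model", ["JC", "K2P", "F84"])
def test_identical_sequences_have_zero_distance(model):
    res = pairwise_distance("ACGTACGTAC", "ACGTACGTAC", model)
    assert res.distance == 0.0 and str(res.distance) == "0.0"


@pytest.mark.parametrize("model", ["JC", "K2P", "F84"])
def test_distance_symmetric_in_operands(model):
    s1, s2 = _oracle_pair()
    assert pairwise_distance(s1, s2, model).distance == pytest.approx(
        pairwise_distance(s2, s1, model).distance
    )


def test_gapped_and_ambiguous_columns_excluded_pairwise():
    res = pairwise_distance("ACGT-NACGT", "ACGTTTACGA", "JC")
    assert res.used_sites == 8  # gap and N columns dropped


def test_saturation_flagged_not_raised():
    # complementary sequences: all transversions, JC log argument <= 0
    res = pairwise_distance("A" * 40, "C" * 20 + "T" * 20, "JC")
    assert res.saturated and res.distance is None


def test_models_agree_to_first_order_at_tiny_divergence():
    n = 100_000
    s1 = ("ACGT" * (n // 4))
    s2 = list(s1)
    s2[17] = "G"  # one A->G transition
    p = 1 / n
    results = [pairwise_distance(s1, "".join(s2), m).distance
               for m in ("JC", "K2P", "F84")]
    for d in results:
        assert d == pytest.approx(p, abs=1e-6)


def test_alignment_of_identical_sequences_has_no_gaps():
    a, b = align_pair(SpacerPair("r", "ACGT" * 25, "ACGT" * 25, 100, 100))
    assert a == b and "-" not in a


def test_alignment_single_deletion():
    a, b = align_pair(SpacerPair("r", "ACGT", "ACT", 4, 3))
    assert (a, b) == ("ACGT", "AC-T")


def test_alignment_score_symmetric_under_swap():
    rng = np.random.default_rng(4)
    x = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 80)])
    y = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 70)])
    a1, b1 = align_pair(SpacerPair("r", x, y, len(x), len(y)))
    a2, b2 = align_pair(SpacerPair("r", y, x, len(y), len(x)))
    score = lambda p, q: sum(
        2 if c == d else (-1 if "-" not in (c, d) else 0) for c, d in zip(p, q)
    )
    assert score(a1, b1) == score(a2, b2)


def test_empty_member_yields_all_gap_alignment():
    a, b = align_pair(SpacerPair("r", "ACGT", "", 4, 0))
    assert b == "----" and a == "ACGT"


# ---------------------------------------------------------------------------
# spacer pairing and marker selection


@pytest.fixture(scope="module")
def trio():
    cfg = SynthConfig(lsc_len=12_000, irb_len=4_000, ssc_len=3_000, seed=21)
    ref, truth = generate_plastome(cfg)
    rng = np.random.default_rng(0)
    rates = np.ones(ref.length)
    # mark two long LSC spacers as fast-evolving in both comparators
    from plastocomp.genome_io import extract_intergenic_regions, unique_regions

    regions = unique_regions(extract_intergenic_regions(ref))
    long_spacers = sorted(
        (r for r in regions if r.length > 500 and r.start < 12_000),
        key=lambda r: -r.length,
    )[:2]
    for r in long_spacers:
        rates[r.start - 1 : r.end] = 6.0
    g2 = evolve_pair(ref, "F84", branch_length=0.03, site_rates=rates, seed=31)
    g3 = evolve_pair(ref, "F84", branch_length=0.03, site_rates=rates, seed=32)
    return ref, g2, g3, [r.name for r in long_spacers]


def test_genome_paired_with_itself_matches_every_unique_spacer(small_record):
    pairs, unmatched = pair_spacers(small_record, small_record)
    assert unmatched == []
    for p in pairs:
        assert p.seq_a == p.seq_b


def test_pair_count_matches_generator_spacers(trio):
    ref, g2, _, _ = trio
    from plastocomp.genome_io import extract_intergenic_regions, unique_regions

    pairs, unmatched = pair_spacers(ref, g2)
    n_unique = len(unique_regions(extract_intergenic_regions(ref)))
    assert len(pairs) == n_unique
    assert unmatched == []


def test_marker_selection_finds_planted_fast_spacers(trio):
    ref, g2, g3, fast_names = trio
    t1 = distance_table(ref, g2)
    t2 = distance_table(ref, g3)
    report = rank_and_select(t1, t2, top_n=10, min_marker_len=500)
    for name in fast_names:
        assert name in report.selected
    # every selected marker is shared-divergent and above the length filter
    assert set(report.selected) <= set(report.most_divergent_shared)
    for name in report.selected:
        assert report.lengths_ref[name] > 500


def test_ranking_invariant_to_row_order(trio):
    ref, g2, g3, _ = trio
    t1 = distance_table(ref, g2)
    t2 = distance_table(ref, g3)
    shuffled = t1.sample(frac=1.0, random_state=5)
    r1 = rank_and_select(t1, t2, top_n=10, min_marker_len=500)
    r2 = rank_and_select(shuffled, t2, top_n=10, min_marker_len=500)
    assert r1.selected == r2.selected
    assert r1.most_divergent_shared == r2.most_divergent_shared


def test_identical_tables_intersect_to_top_list(trio):
    ref, g2, _, _ = trio
    t1 = distance_table(ref, g2)
    report = rank_and_select(t1, t1.copy(), top_n=10, min_marker_len=0)
    assert len(report.most_divergent_shared) == 10
    assert len(report.most_conserved_shared) == 10


def test_fewer_regions_than_top_n_warns(trio):
    ref, g2, _, _ = trio
    t1 = distance_table(ref, g2).head(5)
    with pytest.warns(UserWarning, match="fewer regions"):
        rank_and_select(t1, t1.copy(), top_n=20)
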
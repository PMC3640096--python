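import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from plastocomp.records import GeneFeature, revcomp
from plastocomp.ssr import (
    SSRThresholds,
    annotate_ssr_context,
    find_ssrs,
    is_primitive,
)

from .oracles import brute_force_ssrs


def _rand_seq(rng, n, gc=0.30):
    p = [(1 - gc) / 2, (1 - gc) / 2, gc / 2, gc / 2]
    return "".join(np.array(list("ATCG"))[rng.choice(4, size=n, p=p)])


def test_thresholds_validation():
    with pytest.raises(ValueError):
        SSRThresholds((10, 5, 4, 3, 3))
    with pytest.raises(ValueError):
        SSRThresholds((1, 5, 4, 3, 3, 3))


@pytest.mark.parametrize(
    "motif, expected",
    [("A", True), ("AT", True), ("AA", False), ("ACG", True),
     ("ATAT", False), ("AATAAT", False), ("AATA", True)],
)
def test_motif_primitivity(motif, expected):
    assert is_primitive(motif) == expected


def test_homopolymer_run_called_once_with_phase_motif():
    loci = find_ssrs("G" + "A" * 12 + "G" * 3)
    assert [(l.motif, l.unit_count, l.start) for l in loci] == [("A", 12, 2)]


def test_dinucleotide_run_with_partial_tail():
    # ATATATATATA: five whole AT units plus a dangling A
    loci = find_ssrs("G" + "AT" * 5 + "A" + "GGG", (10, 5, 4, 3, 3, 3))
    assert [(l.motif, l.unit_count, l.start) for l in loci] == [("AT", 5, 2)]


def test_n_breaks_runs():
    assert find_ssrs("A" * 6 + "N" + "A" * 6) == []


def test_periodic_background_yields_no_double_calls():
    # a long (ACGT)-periodic stretch is a single tetranucleotide tract;
    # no dinucleotide or mononucleotide calls can arise from it
    loci = find_ssrs("ACGT" * 20)
    assert [(l.motif, l.unit_count) for l in loci] == [("ACGT", 20)]


@pytest.mark.parametrize("seed", range(8))
def test_scanner_equals_bruteforce_on_random_sequences(seed):
    rng = np.random.default_rng(seed)
    seq = _rand_seq(rng, 8_000, gc=0.25)
    mine = [(l.motif, l.unit_count, l.start) for l in find_ssrs(seq)]
    assert mine == brute_force_ssrs(seq)


def test_scanner_equals_bruteforce_with_ambiguity():
    rng = np.random.default_rng(99)
    seq = list(_rand_seq(rng, 3_000, gc=0.2))
    for pos in rng.integers(0, 3_000, 40):
        seq[pos] = "N"
    seq = "".join(seq)
    mine = [(l.motif, l.unit_count, l.start) for l in find_ssrs(seq)]
    assert mine == brute_force_ssrs(seq)


@settings(max_examples=150, derandomize=True)
@given(st.text(alphabet="ACGT", min_size=30, max_size=120))
def test_reported_runs_are_maximal_and_meet_thresholds(seq):
    thresholds = SSRThresholds((5, 3, 3, 2, 2, 2))
    for l in find_ssrs(seq, thresholds):
        u = l.unit_length
        assert l.unit_count >= thresholds.for_unit(u)
        assert seq[l.start - 1 : l.end] == l.motif * l.unit_count
        # maximal: no whole extra unit on either side
        left = seq[l.start - 1 - u : l.start - 1]
        right = seq[l.end : l.end + u]
        assert left != l.motif
        assert right != l.motif


def test_revcomp_maps_a_runs_to_t_runs():
    rng = np.random.default_rng(5)
    seq = _rand_seq(rng, 5_000, gc=0.25)
    n = len(seq)
    fwd = {(l.motif, l.start, l.length) for l in find_ssrs(seq)}
    rev = {(l.motif, l.start, l.length) for l in find_ssrs(revcomp(seq))}
    mapped = {(revcomp(m), n - (s + length - 1) + 1, length)
              for m, s, length in rev}
    # mirrored loci coincide up to motif phase at the tract start
    assert {(s, length) for _, s, length in fwd} == {
        (s, length) for _, s, length in mapped
    }


def test_planted_ssrs_recovered_exactly(small_record, small_truth):
    found = {(l.motif, l.start, l.end) for l in find_ssrs(small_record.sequence)}
    planted = {(t.name, t.start, t.end) for t in small_truth.ssrs}
    assert planted <= found


def test_context_annotation(small_record, small_truth):
    loci = annotate_ssr_context(
        find_ssrs(small_record.sequence), small_record.features
    )
    genes = [t for t in small_truth.genes]
    by_pos = {l.start: l for l in loci}
    for t in small_truth.ssrs:
        locus = by_pos[t.start]
        inside = [g.name for g in genes if g.start <= t.start <= g.end]
        if inside:
            assert locus.context in inside
        else:
            assert locus.context == "intergenic"


def test_explicitly_planted_genic_ssr_gets_gene_context():
    from plastocomp.synthetic import PlantedSSR, SynthConfig, generate_plastome

    cfg = SynthConfig(
        lsc_len=8_000, irb_len=2_500, ssc_len=3_000, seed=6,
        planted_ssrs=[PlantedSSR("T", 12, "LSC", offset=4_300)],  # inside rbcL
    )
    rec, truth = generate_plastome(cfg)
    loci = annotate_ssr_context(find_ssrs(rec.sequence), rec.features)
    planted = [l for l in loci if l.start == truth.ssrs[0].start]
    assert planted and planted[0].context != "intergenic"
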
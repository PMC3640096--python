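import random

import dendropy
import pandas as pd
import pytest

from plastocomp.genecontent import (
    PresenceMatrix,
    build_presence_matrix,
    build_supermatrix,
    map_losses_fitch,
    min_event_count,
)
from plastocomp.synthetic import SynthConfig, generate_plastome

from .oracles import brute_force_parsimony


def _matrix(states_by_taxon: dict[str, dict[str, int]]) -> PresenceMatrix:
    pres = pd.DataFrame(states_by_taxon).T.astype(bool)
    return PresenceMatrix(pres, pres.map(lambda _: "annotated"))


def test_duplicate_taxon_names_rejected(small_record):
    with pytest.raises(ValueError, match="duplicate"):
        build_presence_matrix([small_record, small_record])


def test_presence_matrix_from_annotations(small_record):
    m = build_presence_matrix([small_record])
    assert m.presence.loc[small_record.identifier, "rbcL"]
    assert "rps19" in m.genes


def test_deleted_gene_shows_as_single_false_column():
    cfg = SynthConfig(lsc_len=8_000, irb_len=2_500, ssc_len=3_000, seed=4)
    rec, _ = generate_plastome(cfg)
    pruned = type(rec)(
        "pruned", rec.sequence, True,
        [f for f in rec.features if f.name != "infA"],
    )
    m = build_presence_matrix([rec, pruned])
    losses = m.losses_relative_to(rec.identifier)
    assert losses["pruned"] == ["infA"]


def test_record_identical_to_reference_has_empty_loss_list(small_record):
    clone = type(small_record)(
        "clone", small_record.sequence, True, list(small_record.features)
    )
    m = build_presence_matrix([small_record, clone])
    assert m.losses_relative_to(small_record.identifier)["clone"] == []


def test_similarity_rescue_recovers_unannotated_gene():
    cfg = SynthConfig(lsc_len=8_000, irb_len=2_500, ssc_len=3_000, seed=4)
    rec, _ = generate_plastome(cfg)
    # same sequence, annotation dropped: rescue must find the gene by alignment
    pruned = type(rec)(
        "pruned", rec.sequence, True,
        [f for f in rec.features if f.name != "rbcL"],
    )
    m = build_presence_matrix([rec, pruned], similarity_rescue=True,
                              reference=rec.identifier)
    assert m.presence.loc["pruned", "rbcL"]
    assert m.evidence.loc["pruned", "rbcL"] == "similarity-rescued"


def test_four_taxon_loss_maps_to_shared_stem():
    tree = dendropy.Tree.get(data="((A,B),(C,D));", schema="newick")
    m = _matrix({t: {"g": 0 if t in "AB" else 1} for t in "ABCD"})
    assert min_event_count(m, tree, "g") == 1
    events = map_losses_fitch(m, tree)
    assert any(e.branch == "{A,B}" and e.direction == "loss" for e in events)


def test_missing_tip_raises():
    tree = dendropy.Tree.get(data="((A,B),(C,E));", schema="newick")
    m = _matrix({t: {"g": 1} for t in "ABCD"})
    with pytest.raises(ValueError, match="missing"):
        map_losses_fitch(m, tree)


def test_constant_character_yields_no_events():
    tree = dendropy.Tree.get(data="((A,B),(C,D));", schema="newick")
    m = _matrix({t: {"g": 1} for t in "ABCD"})
    assert map_losses_fitch(m, tree) == []


def test_three_independent_losses_on_eight_taxa():
    tree = dendropy.Tree.get(
        data="(((A,B),(C,D)),((E,F),(G,H)));", schema="newick"
    )
    absent = {"A", "D", "G"}  # three separated tips
    m = _matrix({t: {"ycf15": 0 if t in absent else 1} for t in "ABCDEFGH"})
    assert min_event_count(m, tree, "ycf15") == 3
    events = map_losses_fitch(m, tree)
    losses = [e for e in events if e.direction == "loss"]
    assert {e.branch for e in losses} == absent


@pytest.mark.parametrize("trial_block", range(4))
def test_fitch_count_equals_exhaustive_minimum(trial_block):
    rng = random.Random(trial_block)
    for _ in range(50):
        nleaf = rng.randint(3, 6)
        taxa = [f"t{i}" for i in range(nleaf)]
        tns = dendropy.TaxonNamespace(taxa)
        tree = dendropy.simulate.treesim.birth_death_tree(
            birth_rate=1.0, death_rate=0.0, num_extant_tips=nleaf,
            taxon_namespace=tns, rng=rng,
        )
        states = {t: rng.randint(0, 1) for t in taxa}
        if len(set(states.values())) == 1:
            continue
        m = _matrix({t: {"g": states[t]} for t in taxa})
        assert min_event_count(m, tree, "g") == brute_force_parsimony(tree, states)


def test_event_count_bounded_by_absent_taxa():
    tree = dendropy.Tree.get(
        data="(((A,B),(C,D)),((E,F),(G,H)));", schema="newick"
    )
    rng = random.Random(42)
    for _ in range(30):
        absent = {t for t in "ABCDEFGH" if rng.random() < 0.4}
        if not absent or len(absent) == 8:
            continue
        m = _matrix({t: {"g": 0 if t in absent else 1} for t in "ABCDEFGH"})
        assert min_event_count(m, tree, "g") <= len(absent)


# ---------------------------------------------------------------------------
# supermatrix


def test_supermatrix_widths_and_partitions():
    aln = {
        "g1": {"A": "A" * 90, "B": "C" * 90, "C": "G" * 90, "D": "T" * 90},
        "g2": {"A": "A" * 60, "B": "C" * 60, "C": "G" * 60, "D": "T" * 60},
        "g3": {"A": "A" * 30, "B": "C" * 30, "C": "G" * 30, "D": "T" * 30},
    }
    sm = build_supermatrix(aln)
    assert sm.width == 180
    assert len(sm.partitions) == 3
    spans = sorted(sm.partitions.values())
    assert spans[0][0] == 1 and spans[-1][1] == 180
    covered = sum(e - s + 1 for s, e in spans)
    assert covered == 180  # partitions tile exactly


def test_intersection_rule_drops_incomplete_genes():
    aln = {
        "shared": {"A": "ACGT", "B": "ACGT"},
        "partial": {"A": "ACGT"},
    }
    sm = build_supermatrix(aln, taxa=["A", "B"])
    assert list(sm.partitions) == ["shared"]


def test_unequal_row_lengths_rejected():
    with pytest.raises(ValueError, match="differ in length"):
        build_supermatrix({"g": {"A": "ACGT", "B": "ACG"}}, taxa=["A", "B"])


def test_phylip_export_shape():
    sm = build_supermatrix({"g": {"A": "ACGT", "B": "AGGT"}}, taxa=["A", "B"])
    lines = sm.to_phylip().strip().splitlines()
    assert lines[0].split() == ["2", "4"]
    assert sm.partition_file() == "DNA, g = 1-4\n"
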
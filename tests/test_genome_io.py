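import io
import warnings

import pytest

from plastocomp.genome_io import (
    count_genes,
    extract_intergenic_regions,
    normalize_gene_name,
    read_genbank,
    unique_regions,
    write_genbank,
)
from plastocomp.records import GeneFeature, PlastomeRecord

MINIMAL_GENBANK = """LOCUS       test                 120 bp    DNA     circular PLN 01-JAN-2000
DEFINITION  minimal record.
ACCESSION   test
FEATURES             Location/Qualifiers
     source          1..120
     gene            10..69
                     /gene="psbA"
     CDS             10..69
                     /gene="psbA"
ORIGIN
        1 atgcatgcat gcatgcatgc atgcatgcat gcatgcatgc atgcatgcat gcatgcatgc
       61 atgcatgcat gcatgcatgc atgcatgcat gcatgcatgc atgcatgcat gcatgcatgc
//
"""


@pytest.mark.parametrize(
    "raw, expected",
    [
        ("trnL-UAG", "trnL-UAG"),
        ("trnL_UAG", "trnL-UAG"),
        ("trnL(uag)", "trnL-UAG"),
        ("trnl-uag", "trnL-UAG"),
        ("RPS19", "rps19"),
        ("Ycf1", "ycf1"),
        ("rps12_5", "rps12_5'"),
        ("rrn16S", "rrn16"),
    ],
)
def test_gene_name_normalization(raw, expected):
    assert normalize_gene_name(raw) == expected


def test_minimal_genbank_single_cds(tmp_path):
    p = tmp_path / "min.gb"
    p.write_text(MINIMAL_GENBANK)
    rec = read_genbank(p)
    assert rec.length == 120
    assert len(rec.features) == 1
    f = rec.features[0]
    assert (f.name, f.kind, f.parts) == ("psbA", "protein", [(10, 69)])


def test_roundtrip_preserves_sequence_and_features(small_record, tmp_path):
    p = tmp_path / "rt.gb"
    write_genbank(small_record, p)
    back = read_genbank(p)
    assert back.sequence == small_record.sequence
    key = lambda f: (f.name, f.kind, f.strand, tuple(f.parts))
    assert sorted(map(key, back.features)) == sorted(map(key, small_record.features))


def test_synthetic_features_match_truth(small_record, small_truth):
    annotated = {(f.name, f.start, f.end) for f in small_record.features
                 if f.kind != "pseudogene"}
    for t in small_truth.genes:
        assert (t.name, t.start, t.end) in annotated


def test_count_genes_by_kind(small_record, small_truth):
    res = count_genes(small_record, include_ir_duplicates=True,
                      include_pseudogenes=False)
    expected = {"protein": 0, "tRNA": 0, "rRNA": 0, "pseudogene": 0}
    for t in small_truth.genes:
        expected[t.expected.split()[0]] += 1
    for kind in ("protein", "tRNA", "rRNA"):
        assert res["counts"][kind] == expected[kind]
    assert 0 < res["genic_fraction"] < 1


def test_count_genes_zero_features():
    rec = PlastomeRecord("empty", "ACGT" * 30, True, [])
    res = count_genes(rec)
    assert all(v == 0 for v in res["counts"].values())


def test_intergenic_regions_arithmetic_small_circle():
    # 5 genes on a 1000 bp circle; spacer lengths must complement gene union
    seq = "ACGT" * 250
    genes = [
        GeneFeature(f"g{i}", "protein", "+", [(s, e)])
        for i, (s, e) in enumerate([(10, 99), (200, 299), (400, 449),
                                    (500, 699), (800, 899)])
    ]
    rec = PlastomeRecord("mini", seq, True, genes)
    regions = extract_intergenic_regions(rec)
    assert len(regions) == 5
    gene_union = sum(f.length for f in genes)
    assert sum(r.length for r in regions) == 1000 - gene_union


def test_abutting_genes_give_empty_spacer():
    seq = "A" * 200
    genes = [
        GeneFeature("g1", "protein", "+", [(10, 50)]),
        GeneFeature("g2", "protein", "+", [(51, 90)]),
    ]
    rec = PlastomeRecord("mini", seq, True, genes)
    regions = extract_intergenic_regions(rec)
    between = [r for r in regions if (r.left_gene, r.right_gene) == ("g1", "g2")]
    assert len(between) == 1 and between[0].length == 0


def test_overlapping_genes_warn_not_raise():
    seq = "A" * 200
    genes = [
        GeneFeature("g1", "protein", "+", [(10, 60)]),
        GeneFeature("g2", "protein", "+", [(50, 90)]),
    ]
    rec = PlastomeRecord("mini", seq, True, genes)
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        regions = extract_intergenic_regions(rec)
    assert any("overlapping" in str(w.message) for w in caught)
    assert len(regions) == 2


def test_rotation_preserves_spacer_multiset(small_record):
    regions = extract_intergenic_regions(small_record)
    rotated = small_record.rotate(4321)
    regions_rot = extract_intergenic_regions(rotated)
    key = lambda rs: sorted((r.left_gene, r.right_gene, r.length) for r in rs)
    assert key(regions) == key(regions_rot)


def test_ir_duplicate_regions_flagged(small_record, small_partition):
    regions = extract_intergenic_regions(small_record, small_partition)
    dup = [r for r in regions if r.in_ir_duplicate]
    # spacers between the mirrored IRb gene pairs reappear inside IRa
    assert len(dup) >= 5
    assert len(unique_regions(regions)) == len(regions) - len(dup)
    for r in dup:
        lo, hi = small_partition.ira
        assert lo <= r.start and (r.length == 0 or r.end <= hi)
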
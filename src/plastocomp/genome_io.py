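"""Reading/writing annotated plastomes and deriving gene and spacer inventories.

Supports GenBank flat files (via Biopython) and a FASTA + tab-separated
feature table as a plain-text alternative. Gene names are normalized to
canonical plastid symbols so spacers can be paired across genomes.
"""

from __future__ import annotations

import csv
import re
import warnings
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional

import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

from .records import GeneFeature, IntergenicRegion, PlastomeRecord, revcomp

_TRNA_RE = re.compile(r"^(trn[A-Za-z]+)[-_(]?([ACGUacgu]{3})?\)?$")


class GenomeFormatError(ValueError):
    """Raised when an input file cannot be parsed as an annotated genome."""


@lru_cache(maxsize=1)
def _alias_tables() -> tuple[dict, dict]:
    text = resources.files("plastocomp.data").joinpath("gene_aliases.yaml").read_text()
    cfg = yaml.safe_load(text)
    aliases = {str(k).lower(): v for k, v in (cfg.get("aliases") or {}).items()}
    canonical = {name.lower(): name for name in cfg.get("canonical") or []}
    return aliases, canonical


def normalize_gene_name(raw: str) -> str:
    """Map annotation variants (trnL_UAG, trnL(uag), RPS19 ...) to one symbol.

    tRNA anticodon suffixes are retained in upper case with a hyphen
    (trnL-UAG); other genes get canonical casing from the bundled table.
    """
    name = raw.strip().replace(" ", "")
    aliases, canonical = _alias_tables()
    if name.lower() in aliases:
        return aliases[name.lower()]
    m = _TRNA_RE.match(name)
    if m and name.lower().startswith("trn"):
        body = m.group(1)
        body = "trn" + body[3:].upper()
        anticodon = m.group(2)
        if anticodon:
            return f"{body}-{anticodon.upper().replace('T', 'U')}"
        return body
    # unify separators, then restore canonical casing if known
    name = name.replace("_", "-")
    if name.lower() in canonical:
        return canonical[name.lower()]
    if name.lower() in aliases:
        return aliases[name.lower()]
    return name


def _kind_from_biopython(feature_type: str, qualifiers: dict) -> Optional[str]:
    if "pseudo" in qualifiers or "pseudogene" in qualifiers:
        return "pseudogene"
    if feature_type == "tRNA":
        return "tRNA"
    if feature_type == "rRNA":
        return "rRNA"
    if feature_type == "CDS":
        return "protein"
    return None


def _parts_from_location(loc) -> tuple[list[tuple[int, int]], str]:
    strand = "-" if (loc.strand or 1) < 0 else "+"
    parts = [(int(p.start) + 1, int(p.end)) for p in loc.parts]
    parts.sort()
    return parts, strand


def _split_trans_spliced_rps12(feats: list[GeneFeature], genome_len: int) -> list[GeneFeature]:
    """Represent the two portions of trans-spliced rps12 as separate genic regions."""
    out = []
    for f in feats:
        if f.name == "rps12" and len(f.parts) >= 2 and (f.end - f.start) > genome_len // 4:
            parts = sorted(f.parts)
            # exon 1 (5' portion) is distant from the 3' exon cluster
            gaps = [parts[i + 1][0] - parts[i][1] for i in range(len(parts) - 1)]
            cut = gaps.index(max(gaps)) + 1
            out.append(GeneFeature("rps12_5'", f.kind, f.strand, parts[:cut], f.copy_tag))
            out.append(GeneFeature("rps12_3'", f.kind, f.strand, parts[cut:], f.copy_tag))
        else:
            out.append(f)
    return out


def read_genbank(path) -> PlastomeRecord:
    """Read one annotated plastome from a GenBank flat file.

    Gene features are preferred; CDS/tRNA/rRNA features supply the kind for
    the same-named gene. Pseudogenes are flagged via ``/pseudo`` qualifiers.
    """
    path = Path(path)
    try:
        seqrec = next(SeqIO.parse(str(path), "genbank"))
    except StopIteration:
        raise GenomeFormatError(f"{path}: no GenBank records found")
    except Exception as exc:  # Biopython raises assorted ValueErrors
        raise GenomeFormatError(f"{path}: cannot parse GenBank file ({exc})")
    sequence = str(seqrec.seq).upper()
    circular = seqrec.annotations.get("topology", "circular") == "circular"

    # kind lookup from typed features; pseudo status is per-location (the
    # same gene name can exist as a functional copy and an IR pseudo fragment)
    kinds: dict[str, str] = {}
    pseudo_locs: set[tuple] = set()
    for feat in seqrec.features:
        if feat.type not in ("CDS", "tRNA", "rRNA", "gene"):
            continue
        name = feat.qualifiers.get("gene", feat.qualifiers.get("locus_tag", [None]))[0]
        if name is None:
            continue
        name = normalize_gene_name(name)
        parts, _ = _parts_from_location(feat.location)
        kind = _kind_from_biopython(feat.type, feat.qualifiers)
        if kind == "pseudogene":
            pseudo_locs.add((name, tuple(parts)))
        elif kind is not None:
            kinds.setdefault(name, kind)

    feats: list[GeneFeature] = []
    seen: set[tuple] = set()
    gene_feats = [f for f in seqrec.features if f.type == "gene"]
    source = gene_feats or [
        f for f in seqrec.features if f.type in ("CDS", "tRNA", "rRNA")
    ]
    for feat in source:
        name = feat.qualifiers.get("gene", feat.qualifiers.get("locus_tag", [None]))[0]
        if name is None:
            continue
        name = normalize_gene_name(name)
        parts, strand = _parts_from_location(feat.location)
        key = (name, tuple(parts))
        if key in seen:
            continue
        seen.add(key)
        if (name, tuple(parts)) in pseudo_locs or "pseudo" in feat.qualifiers:
            kind = "pseudogene"
        else:
            kind = kinds.get(name) or ("tRNA" if name.startswith("trn") else "protein")
        feats.append(GeneFeature(name, kind, strand, parts))
    if not feats:
        warnings.warn(f"{path}: record has no gene features")
    feats = _split_trans_spliced_rps12(feats, len(sequence))
    return PlastomeRecord(seqrec.id or path.stem, sequence, circular, feats)


def write_genbank(record: PlastomeRecord, path) -> None:
    """Write a PlastomeRecord as a GenBank flat file (round-trip safe)."""
    seqrec = SeqRecord(
        Seq(record.sequence),
        id=record.identifier,
        name=record.identifier[:16].replace(" ", "_"),
        description="synthetic quadripartite plastome"
        if record.identifier.startswith("synth")
        else "",
    )
    seqrec.annotations["molecule_type"] = "DNA"
    seqrec.annotations["topology"] = "circular" if record.circular else "linear"
    type_map = {"protein": "CDS", "tRNA": "tRNA", "rRNA": "rRNA", "pseudogene": "gene"}
    for f in record.features:
        strand = -1 if f.strand == "-" else 1
        locs = [FeatureLocation(s - 1, e, strand=strand) for s, e in f.parts]
        loc = locs[0] if len(locs) == 1 else CompoundLocation(locs)
        quals = {"gene": [f.name]}
        if f.kind == "pseudogene":
            quals["pseudo"] = [""]
        seqrec.features.append(SeqFeature(loc, type="gene", qualifiers=dict(quals)))
        if f.kind != "pseudogene":
            seqrec.features.append(
                SeqFeature(loc, type=type_map[f.kind], qualifiers=dict(quals))
            )
    SeqIO.write([seqrec], str(path), "genbank")


def read_fasta_table(fasta_path, table_path) -> PlastomeRecord:
    """Read a genome from FASTA plus a feature TSV.

    Table columns: name, kind, strand, start, end, pseudo (0/1); one row per
    part, repeated names merged into multi-part features.
    """
    seqrec = next(SeqIO.parse(str(fasta_path), "fasta"))
    rows: dict[tuple[str, str], list[tuple[int, int]]] = {}
    pseudo_names: set[str] = set()
    kind_by_name: dict[str, str] = {}
    with open(table_path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            name = normalize_gene_name(row["name"])
            kind_by_name[name] = row["kind"]
            if row.get("pseudo", "0") in ("1", "true", "True"):
                pseudo_names.add(name)
            rows.setdefault((name, row["strand"]), []).append(
                (int(row["start"]), int(row["end"]))
            )
    feats = []
    for (name, strand), parts in rows.items():
        kind = "pseudogene" if name in pseudo_names else kind_by_name[name]
        feats.append(GeneFeature(name, kind, strand, sorted(parts)))
    return PlastomeRecord(seqrec.id, str(seqrec.seq), True, feats)


def count_genes(
    record: PlastomeRecord,
    include_ir_duplicates: bool = True,
    include_pseudogenes: bool = False,
) -> dict:
    """Count genes by kind, plus the genome fraction each kind covers.

    With ``include_ir_duplicates=False``, genes annotated more than once
    (the IR-duplicated set) are counted a single time by name.
    """
    feats = record.genic_features(include_pseudogenes=include_pseudogenes)
    if not include_ir_duplicates:
        seen: set[str] = set()
        unique = []
        for f in feats:
            if f.name not in seen:
                seen.add(f.name)
                unique.append(f)
        feats = unique
    counts = {"protein": 0, "tRNA": 0, "rRNA": 0, "pseudogene": 0}
    cover: dict[str, set[int]] = {k: set() for k in counts}
    for f in feats:
        counts[f.kind] += 1
        for s, e in f.parts:
            cover[f.kind].update(range(s, e + 1))
    fractions = {k: len(v) / record.length for k, v in cover.items()}
    all_positions = set().union(*cover.values()) if feats else set()
    return {
        "counts": counts,
        "fractions": fractions,
        "genic_fraction": len(all_positions) / record.length,
    }


def _merge_genic_intervals(feats: list[GeneFeature]) -> list[tuple[int, int, str]]:
    """Per-feature overall intervals (min start, max end), sorted; one per feature.

    Trans-spliced portions are separate features by construction, so the
    overall span per feature is contiguous on the circle (wrap-around
    features excepted; their span is treated as starting at part one).
    """
    spans = []
    for f in feats:
        spans.append((f.start, f.end, f.name))
    spans.sort()
    return spans


def extract_intergenic_regions(
    record: PlastomeRecord, partition=None
) -> list[IntergenicRegion]:
    """One spacer per adjacent gene pair around the circle.

    Overlapping genes yield a zero-length region (with a warning). When a
    quadripartite ``partition`` is supplied, regions lying wholly inside IRa
    with an isomorphic (left,right) pair inside IRb are flagged
    ``in_ir_duplicate`` (the IRb copy is kept as the unique representative);
    without a partition, repeated name pairs are flagged positionally.
    """
    feats = record.genic_features(include_pseudogenes=True)
    if not feats:
        return []
    spans = _merge_genic_intervals(feats)
    n = record.length
    regions: list[IntergenicRegion] = []
    for i, (s, e, name) in enumerate(spans):
        ns, ne, nname = spans[(i + 1) % len(spans)]
        if i == len(spans) - 1:
            # wrap around the origin
            start, end = e + 1, ns - 1 + n
            if start > end:
                warnings.warn(f"overlapping genes {name}/{nname}; empty spacer")
                seq = ""
                start, end = e + 1, e
            else:
                seq = (record.sequence * 2)[start - 1 : end]
                end_mod = (end - 1) % n + 1
                regions.append(
                    IntergenicRegion(name, nname, start, end_mod, seq)
                )
                continue
        else:
            start, end = e + 1, ns - 1
            if start > end:
                if ns <= e:  # genuine overlap, not mere abutment
                    warnings.warn(f"overlapping genes {name}/{nname}; empty spacer")
                seq = ""
                start, end = e + 1, e
            else:
                seq = record.sequence[start - 1 : end]
        regions.append(IntergenicRegion(name, nname, start, end, seq))

    _flag_ir_duplicates(regions, partition, n)
    return regions


def _flag_ir_duplicates(regions: list[IntergenicRegion], partition, n: int) -> None:
    if partition is not None:
        ira_s, ira_e = partition.ira
        irb_s, irb_e = partition.irb

        def inside(r: IntergenicRegion, lo: int, hi: int) -> bool:
            if r.length == 0:
                return lo <= r.start <= hi
            return lo <= r.start and r.end <= hi

        irb_pairs = {
            frozenset((r.left_gene, r.right_gene))
            for r in regions
            if inside(r, irb_s, irb_e)
        }
        for r in regions:
            if inside(r, ira_s, ira_e) and frozenset((r.left_gene, r.right_gene)) in irb_pairs:
                r.in_ir_duplicate = True
    else:
        seen: set[frozenset] = set()
        for r in regions:  # regions are in genomic order; later copy flagged
            key = frozenset((r.left_gene, r.right_gene))
            if key in seen:
                r.in_ir_duplicate = True
            seen.add(key)


def unique_regions(regions: Iterable[IntergenicRegion]) -> list[IntergenicRegion]:
    return [r for r in regions if not r.in_ir_duplicate]


def genes_to_bed(record: PlastomeRecord) -> str:
    """BED6 (0-based half-open) of all gene features."""
    lines = []
    for f in record.features:
        for s, e in f.parts:
            lines.append(
                f"{record.identifier}\t{s - 1}\t{e}\t{f.name}\t0\t{f.strand}"
            )
    return "\n".join(lines) + "\n"


def regions_to_bed(record: PlastomeRecord, regions: Iterable[IntergenicRegion]) -> str:
    lines = []
    for r in regions:
        if r.length == 0:
            continue
        end = r.start - 1 + r.length  # handles wrap regions as linearized length
        lines.append(f"{record.identifier}\t{r.start - 1}\t{end}\t{r.name}\t0\t+")
    return "\n".join(lines) + "\n"


def gene_inventory_tsv(record: PlastomeRecord) -> str:
    lines = ["name\tkind\tstrand\tstart\tend\tlength"]
    for f in record.features:
        lines.append(
            f"{f.name}\t{f.kind}\t{f.strand}\t{f.start}\t{f.end}\t{f.length}"
        )
    return "\n".join(lines) + "\n"
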
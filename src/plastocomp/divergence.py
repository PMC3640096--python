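"""Spacer pairing, alignment, substitution-model distances, marker selection.

Homologous intergenic spacers are paired across genomes by their normalized
flanking gene names, globally aligned, and converted into evolutionary
distances (substitutions per site) under JC, K2P or F84. Ranking the
distances across two genome pairs against a common reference yields the
shared most-divergent spacer set, filtered by a minimum length to produce
candidate phylogenetic markers.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd
from Bio import Align

from .genome_io import extract_intergenic_regions, unique_regions
from .records import IntergenicRegion, PlastomeRecord, revcomp

MODELS = ("JC", "K2P", "F84")

PURINES = {"A", "G"}
PYRIMIDINES = {"C", "T"}


@dataclass
class SpacerPair:
    name: str  # leftGene-rightGene in reference orientation
    seq_a: str
    seq_b: str
    len_a: int
    len_b: int
    flipped_b: bool = False  # comparator spacer was reverse-complemented


@dataclass
class DistanceResult:
    region: str
    model: str
    distance: Optional[float]  # substitutions/site; None when saturated/undefined
    aligned_length: int
    used_sites: int
    saturated: bool = False

    @property
    def defined(self) -> bool:
        return self.distance is not None


def pair_spacers(
    genome_a: PlastomeRecord,
    genome_b: PlastomeRecord,
    partition_a=None,
    partition_b=None,
) -> tuple[list[SpacerPair], list[str]]:
    """Pair unique spacers with matching flanking genes in both genomes.

    Spacer names are canonical to genome A's strand/orientation; a spacer
    annotated in the opposite gene order in genome B is reverse-complemented
    before pairing. Returns (pairs, names unmatched in B).
    """
    regs_a = unique_regions(extract_intergenic_regions(genome_a, partition_a))
    regs_b = extract_intergenic_regions(genome_b, partition_b)
    by_key: dict[frozenset, IntergenicRegion] = {}
    for r in regs_b:
        by_key.setdefault(frozenset((r.left_gene, r.right_gene)), r)
    pairs: list[SpacerPair] = []
    unmatched: list[str] = []
    for ra in regs_a:
        key = frozenset((ra.left_gene, ra.right_gene))
        rb = by_key.get(key)
        if rb is None:
            unmatched.append(ra.name)
            continue
        seq_b = rb.sequence
        flipped = False
        if (rb.left_gene, rb.right_gene) != (ra.left_gene, ra.right_gene) and len(key) == 2:
            seq_b = revcomp(seq_b)
            flipped = True
        pairs.append(
            SpacerPair(ra.name, ra.sequence, seq_b, ra.length, rb.length, flipped)
        )
    return pairs, unmatched


def _aligner(gap_open: float = -10.0, gap_extend: float = -0.5) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner


def align_pair(
    pair: SpacerPair, gap_open: float = -10.0, gap_extend: float = -0.5
) -> tuple[str, str]:
    """Global affine alignment of the two spacer sequences.

    Ties are broken deterministically by taking the first optimal alignment
    in Biopython's canonical traversal order. An empty member yields an
    all-gap alignment.
    """
    a, b = pair.seq_a.upper(), pair.seq_b.upper()
    if not a or not b:
        return (a or "-" * len(b), b or "-" * len(a))
    aln = _aligner(gap_open, gap_extend).align(a, b)[0]
    return aln[0], aln[1]


def _count_site_patterns(aligned_a: str, aligned_b: str):
    matches = transitions = transversions = 0
    counts = {b: 0 for b in "ACGT"}
    for x, y in zip(aligned_a.upper(), aligned_b.upper()):
        if x not in "ACGT" or y not in "ACGT":
            continue  # pairwise deletion of gapped/ambiguous columns
        counts[x] += 1
        counts[y] += 1
        if x == y:
            matches += 1
        elif (x in PURINES) == (y in PURINES):
            transitions += 1
        else:
            transversions += 1
    used = matches + transitions + transversions
    return matches, transitions, transversions, used, counts


def pairwise_distance(
    aligned_a: str, aligned_b: str, model: str = "F84", region: str = ""
) -> DistanceResult:
    """Evolutionary distance from an aligned pair under JC, K2P or F84.

    Sites with a gap or ambiguity in either row are excluded (pairwise
    deletion). F84 uses empirical base frequencies pooled over both rows.
    A non-positive logarithm argument (saturation) flags the result and
    leaves the distance undefined.
    """
    model = model.upper()
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}")
    if len(aligned_a) != len(aligned_b):
        raise ValueError("aligned sequences differ in length")
    matches, ts, tv, used, counts = _count_site_patterns(aligned_a, aligned_b)
    aligned_length = len(aligned_a)
    if used == 0:
        return DistanceResult(region, model, None, aligned_length, 0, saturated=False)
    p = ts / used
    q = tv / used

    try:
        if model == "JC":
            d = -0.75 * _ln(1.0 - 4.0 / 3.0 * (p + q))
        elif model == "K2P":
            d = -0.5 * _ln((1.0 - 2.0 * p - q) * math.sqrt(1.0 - 2.0 * q))
        else:
            d = _f84_distance(p, q, counts)
    except _Saturated:
        return DistanceResult(region, model, None, aligned_length, used, saturated=True)
    return DistanceResult(region, model, max(d, 0.0) + 0.0, aligned_length, used)


class _Saturated(ArithmeticError):
    pass


def _ln(x: float) -> float:
    if x <= 0.0:
        raise _Saturated
    return math.log(x)


def _f84_distance(p: float, q: float, counts: dict[str, int]) -> float:
    """F84 distance with empirical frequencies (Felsenstein's formulation)."""
    total = sum(counts.values())
    if total == 0:
        raise _Saturated
    pi = {b: counts[b] / total for b in "ACGT"}
    pi_r = pi["A"] + pi["G"]
    pi_y = pi["C"] + pi["T"]
    if pi_r == 0 or pi_y == 0:
        raise _Saturated
    a = pi["C"] * pi["T"] / pi_y + pi["A"] * pi["G"] / pi_r
    b = pi["C"] * pi["T"] + pi["A"] * pi["G"]
    c = pi_r * pi_y
    if a == 0 or c == 0:
        # degenerate composition (e.g. a two-base spacer alignment): the
        # F84 transition term is undefined
        raise _Saturated
    d = -2.0 * a * _ln(1.0 - p / (2.0 * a) - (a - b) * q / (2.0 * a * c))
    d += 2.0 * (a - b - c) * _ln(1.0 - q / (2.0 * c))
    return d


def distance_table(
    genome_a: PlastomeRecord,
    genome_b: PlastomeRecord,
    model: str = "F84",
    partition_a=None,
    partition_b=None,
) -> pd.DataFrame:
    """Per-spacer distances for one genome pair, as a tidy DataFrame."""
    pairs, unmatched = pair_spacers(genome_a, genome_b, partition_a, partition_b)
    rows = []
    for pair in pairs:
        if not pair.seq_a or not pair.seq_b:
            continue
        aligned_a, aligned_b = align_pair(pair)
        res = pairwise_distance(aligned_a, aligned_b, model, region=pair.name)
        rows.append(
            {
                "region": pair.name,
                "model": res.model,
                "distance": res.distance,
                "aligned_length": res.aligned_length,
                "used_sites": res.used_sites,
                "saturated": res.saturated,
                "length_ref": pair.len_a,
                "length_other": pair.len_b,
            }
        )
    df = pd.DataFrame(rows)
    if unmatched:
        df.attrs["unmatched"] = unmatched
    return df


@dataclass
class MarkerReport:
    most_divergent_shared: list[str]
    most_conserved_shared: list[str]
    selected: list[str]  # shared divergent regions above the length filter
    lengths_ref: dict[str, int] = field(default_factory=dict)


def rank_and_select(
    table_ab: pd.DataFrame,
    table_ac: pd.DataFrame,
    top_n: int = 20,
    min_marker_len: int = 500,
) -> MarkerReport:
    """Shared most-conserved / most-divergent spacers across two comparisons
    with a common reference; divergent intersection filtered by the spacer
    length in the reference genome.

    Ranking uses a stable sort on (distance, region name), so the result is
    invariant to input row order.
    """

    def prep(df: pd.DataFrame) -> pd.DataFrame:
        out = df[df["distance"].notna()].copy()
        return out.sort_values(["distance", "region"], kind="stable")

    ab, ac = prep(table_ab), prep(table_ac)
    n_ab, n_ac = len(ab), len(ac)
    if min(n_ab, n_ac) < top_n:
        warnings.warn(
            f"fewer regions ({min(n_ab, n_ac)}) than top_n={top_n}; using all"
        )
    top = min(top_n, n_ab, n_ac)
    con_ab = list(ab.head(top)["region"])
    con_ac = list(ac.head(top)["region"])
    div_ab = list(ab.tail(top)["region"])[::-1]  # most divergent first
    div_ac = set(ac.tail(top)["region"])
    conserved_shared = [r for r in con_ab if r in set(con_ac)]
    divergent_shared = [r for r in div_ab if r in div_ac]
    lengths = dict(zip(table_ab["region"], table_ab["length_ref"]))
    selected = [r for r in divergent_shared if lengths.get(r, 0) > min_marker_len]
    return MarkerReport(divergent_shared, conserved_shared, selected, lengths)
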
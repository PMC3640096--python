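"""Quadripartite partition discovery and IR/SC boundary typing.

The canonical angiosperm plastome is a circle tiled by four regions: a
large single-copy region (LSC), inverted repeat b (IRb), a small
single-copy region (SSC), and inverted repeat a (IRa), with IRa the
reverse complement of IRb. The four junctions are named for the regions
they separate: JLB (LSC|IRb), JSB (IRb|SSC), JSA (SSC|IRa), JLA (IRa|LSC).
Because published junction nomenclature is used inconsistently, the typing
rules are expressed against gene anchors (rps19/rpl2 at the LSC-IRb side,
ndhF/trnN-GUU at the IR-SSC side, ycf1 at the SSC-IR side, trnH at the
IRa-LSC side) rather than against the J labels themselves.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Optional

import numpy as np
import yaml

from .records import PlastomeRecord, revcomp


class NoIRFound(ValueError):
    """No inverted repeat at or above the minimum length (IR-lacking lineages)."""


def _interval_len(lo: int, hi: int, n: int) -> int:
    """Length of the circular 1-based inclusive interval [lo, hi]."""
    return (hi - lo) % n + 1


@dataclass
class QuadripartitePartition:
    """Four 1-based inclusive intervals tiling the genome once.

    Intervals may wrap the circular origin (lo > hi).
    """

    lsc: tuple[int, int]
    irb: tuple[int, int]
    ssc: tuple[int, int]
    ira: tuple[int, int]
    genome_length: int

    def __post_init__(self) -> None:
        n = self.genome_length
        total = sum(
            _interval_len(lo, hi, n)
            for lo, hi in (self.lsc, self.irb, self.ssc, self.ira)
        )
        if total != n:
            raise ValueError(f"partition does not tile genome: {total} != {n}")
        if _interval_len(*self.irb, n) != _interval_len(*self.ira, n):
            raise ValueError("IRa and IRb lengths differ")
        # adjacency in canonical order LSC -> IRb -> SSC -> IRa -> (LSC)
        order = (self.lsc, self.irb, self.ssc, self.ira)
        for (_, hi), (lo, _) in zip(order, order[1:] + order[:1]):
            if (hi % n) + 1 != lo and not (hi == n and lo == 1):
                raise ValueError("regions are not adjacent in LSC,IRb,SSC,IRa order")

    @property
    def ir_length(self) -> int:
        return _interval_len(*self.irb, self.genome_length)

    def lengths(self) -> dict[str, int]:
        return {
            name.upper(): _interval_len(*getattr(self, name), self.genome_length)
            for name in ("lsc", "irb", "ssc", "ira")
        }

    def region_sequence(self, genome: str, label: str) -> str:
        lo, hi = getattr(self, label.lower())
        if lo <= hi:
            return genome[lo - 1 : hi]
        return genome[lo - 1 :] + genome[:hi]

    def region_of(self, pos: int) -> str:
        n = self.genome_length
        for name in ("lsc", "irb", "ssc", "ira"):
            lo, hi = getattr(self, name)
            if (pos - lo) % n < _interval_len(lo, hi, n):
                return name.upper()
        raise ValueError(f"position {pos} outside genome")

    @property
    def junctions(self) -> dict[str, int]:
        """Position of the last base before each boundary."""
        return {
            "JLB": self.lsc[1],
            "JSB": self.irb[1],
            "JSA": self.ssc[1],
            "JLA": self.ira[1],
        }


def detect_inverted_repeat(
    sequence: str, min_ir: int = 1000, anchor_len: int = 20
) -> QuadripartitePartition:
    """Find the longest pair of disjoint reverse-complement segments.

    Exact-match cores are reported (deposited plastome IRs are perfect or
    nearly so). The search treats the genome as circular, so the result is
    invariant to rotation of the origin. Raises :class:`NoIRFound` when no
    pair reaches ``min_ir``.
    """
    seq = sequence.upper()
    n = len(seq)
    if n < 2 * min_ir:
        raise NoIRFound(f"genome of {n} bp cannot hold two IRs of {min_ir} bp")
    rc = revcomp(seq)
    comp = rc[::-1]  # comp[i] = complement of seq[i]

    # Anchors: exact k-mer of seq matching a k-mer of revcomp(seq). Along an
    # ungapped reverse-complement match the pairing constant
    # c = i + j_end (mod n) is invariant, where j_end is the genome position
    # of the partner base. Candidate constants are voted on by anchors.
    index: dict[str, list[int]] = {}
    for j in range(0, n - anchor_len + 1):
        index.setdefault(rc[j : j + anchor_len], []).append(j)
    step = max(1, min_ir // 8)
    votes: dict[int, int] = {}
    for i in range(0, n - anchor_len + 1, step):
        for j in index.get(seq[i : i + anchor_len], ()):
            # seq[i+t] == rc[j+t]; rc[j+t] = comp(seq[n-1-j-t])
            c = (i + (n - 1 - j)) % n
            votes[c] = votes.get(c, 0) + 1
    if not votes:
        raise NoIRFound("no reverse-complement anchors found")

    s_arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    c_arr = np.frombuffer(comp.encode(), dtype=np.uint8)
    best = None  # (length, a_start0, c)
    for c in sorted(votes, key=votes.get, reverse=True)[:20]:
        cand = _best_disjoint_pair(s_arr, c_arr, c, n)
        if cand and (best is None or cand[0] > best[0]):
            best = (cand[0], cand[1], c)
    if best is None or best[0] < min_ir:
        raise NoIRFound(f"longest disjoint inverted match below {min_ir} bp")
    length, a0, c = best
    return _partition_from_pair(a0, length, c, n)


def _best_disjoint_pair(s_arr, c_arr, c: int, n: int):
    """Longest circular match run pairing with a disjoint partner run.

    Match condition at position t: seq[t] == comp(seq[(c - t) mod n]). The
    map t -> (c - t) mod n is an involution, so maximal runs come in pairs
    (or map onto themselves when palindromic; those are skipped).
    """
    idx = (c - np.arange(n)) % n
    match = s_arr == c_arr[idx]
    if match.all():
        return None
    m2 = np.concatenate([match, match]).astype(np.int8)
    diff = np.diff(np.concatenate([[0], m2, [0]]))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)  # exclusive
    best = None
    for st, en in zip(starts, ends):
        if st >= n:
            continue
        L = min(en - st, n)
        a1, a2 = st % n, (st + L - 1) % n
        b_lo, b_hi = (c - a2) % n, (c - a1) % n
        gap_ab = (b_lo - a2 - 1) % n
        gap_ba = (a1 - b_hi - 1) % n
        if 2 * L + gap_ab + gap_ba != n:
            continue  # partner overlaps the run itself (palindromic stretch)
        if best is None or L > best[0]:
            best = (L, a1)
    return best


def _partition_from_pair(a0: int, length: int, c: int, n: int) -> QuadripartitePartition:
    """Build the labelled partition from segment A (0-based start) and its partner."""
    a1, a2 = a0, (a0 + length - 1) % n
    b_lo, b_hi = (c - a2) % n, (c - a1) % n
    gap_ab = (b_lo - a2 - 1) % n  # single-copy arc following A
    gap_ba = (a1 - b_hi - 1) % n  # single-copy arc following B

    def iv(lo0: int, hi0: int) -> tuple[int, int]:
        return (int(lo0) % n + 1, int(hi0) % n + 1)

    seg_a = iv(a1, a2)
    seg_b = iv(b_lo, b_hi)
    sc_after_a = iv(a2 + 1, a2 + gap_ab)
    sc_after_b = iv(b_hi + 1, b_hi + gap_ba)
    if gap_ab >= gap_ba:
        # arc after A is the LSC; the IR following it (B) is IRb
        lsc, irb, ssc, ira = sc_after_a, seg_b, sc_after_b, seg_a
    else:
        lsc, irb, ssc, ira = sc_after_b, seg_a, sc_after_a, seg_b
    return QuadripartitePartition(lsc, irb, ssc, ira, n)


# ---------------------------------------------------------------------------
# junction context and boundary typing

ANCHORS = {
    "rps19_side": ("rps19", "rpl2"),
    "ndhF_side": ("ndhF", "trnN-GUU"),
    "ycf1_side": ("ycf1",),
    "trnH_side": ("trnH-GUG", "trnH"),
}


@dataclass
class JunctionContext:
    junction: str  # JLB / JSB / JSA / JLA
    position: int  # last base before the boundary
    feature: str  # gene name, or "leftGene-rightGene" spacer
    in_gene: bool
    anchor_side: str  # which anchor group this junction is nearest to
    anchor_offsets: dict[str, int] = field(default_factory=dict)


@dataclass
class JunctionProfile:
    contexts: dict[str, JunctionContext]
    complete: bool
    missing_anchors: list[str] = field(default_factory=list)

    def context_of_side(self, side: str) -> Optional[JunctionContext]:
        for ctx in self.contexts.values():
            if ctx.anchor_side == side:
                return ctx
        return None


def _feature_at(
    record: PlastomeRecord, pos: int, include_pseudogenes: bool = False
) -> tuple[str, bool]:
    """Gene containing pos (inclusive at both ends), else flanking spacer name.

    Junction typing asks where the junction falls among *functional* genes;
    IR-mirror pseudogene fragments (e.g. the ycf1 fragment at the IRb|SSC
    boundary) are excluded by default.
    """
    feats = record.genic_features(include_pseudogenes=include_pseudogenes)
    for f in feats:
        if f.contains(pos):
            return f.name, True
    # flanking spacer: nearest gene end before and nearest gene start after
    n = record.length
    best_left, best_right = None, None
    dl = dr = n + 1
    for f in feats:
        d_left = (pos - f.end) % n
        d_right = (f.start - pos) % n
        if d_left < dl:
            dl, best_left = d_left, f.name
        if d_right < dr:
            dr, best_right = d_right, f.name
    if best_left is None:
        return "no-features", False
    return f"{best_left}-{best_right}", False


def _signed_distance(pos: int, target: int, n: int) -> int:
    """Signed circular distance from pos to target (shortest way)."""
    d = (target - pos) % n
    return d if d <= n // 2 else d - n


def locate_junctions(
    partition: QuadripartitePartition, record: PlastomeRecord
) -> JunctionProfile:
    """Assign each junction to its containing gene or spacer, with offsets
    to the anchor genes of its side."""
    n = record.length
    feats = record.genic_features(include_pseudogenes=False)
    by_name: dict[str, list] = {}
    for f in feats:
        by_name.setdefault(f.name, []).append(f)

    side_of = {
        "JLB": "rps19_side",
        "JSB": None,  # decided by proximity to ndhF vs ycf1 anchors
        "JSA": None,
        "JLA": "trnH_side",
    }
    # decide which SSC-flanking junction is the ndhF side: the one whose
    # nearest ndhF copy is closer
    missing: list[str] = []
    contexts: dict[str, JunctionContext] = {}

    def nearest(gene: str, pos: int) -> Optional[int]:
        copies = by_name.get(gene)
        if not copies:
            return None
        dists = []
        for f in copies:
            if f.contains(pos):
                return 0
            for ref in (f.start, f.end):
                dists.append(_signed_distance(pos, ref, n))
        return min(dists, key=abs)

    junctions = partition.junctions
    jsb, jsa = junctions["JSB"], junctions["JSA"]
    d_ndhf_jsb = nearest("ndhF", jsb)
    d_ndhf_jsa = nearest("ndhF", jsa)
    if d_ndhf_jsb is None and d_ndhf_jsa is None:
        side_of["JSB"], side_of["JSA"] = "ndhF_side", "ycf1_side"
        missing.append("ndhF")
    elif d_ndhf_jsa is None or (
        d_ndhf_jsb is not None and abs(d_ndhf_jsb) <= abs(d_ndhf_jsa)
    ):
        side_of["JSB"], side_of["JSA"] = "ndhF_side", "ycf1_side"
    else:
        side_of["JSB"], side_of["JSA"] = "ycf1_side", "ndhF_side"

    for name, pos in junctions.items():
        side = side_of[name]
        feature, in_gene = _feature_at(record, pos)
        offsets: dict[str, int] = {}
        for anchor in ANCHORS[side]:
            d = nearest(anchor, pos)
            if d is None:
                if anchor not in missing:
                    missing.append(anchor)
            else:
                offsets[anchor] = d
        contexts[name] = JunctionContext(name, pos, feature, in_gene, side, offsets)
    # trnH commonly absent from reduced annotation sets; completeness is
    # judged on the three typing-relevant sides
    relevant = {"rps19", "rpl2", "ndhF", "ycf1"}
    complete = not (relevant & set(missing))
    return JunctionProfile(contexts, complete, missing)


# ---------------------------------------------------------------------------
# rule table


@dataclass
class BoundaryTypeRule:
    label: str
    rps19_context: Optional[str] = None  # "gene" | "spacer" | gene name
    ndhf_context: Optional[str] = None
    ycf1_context: Optional[str] = None
    note: str = ""

    def matches(self, profile: JunctionProfile) -> bool:
        checks = (
            ("rps19_side", self.rps19_context, "rps19"),
            ("ndhF_side", self.ndhf_context, "ndhF"),
            ("ycf1_side", self.ycf1_context, "ycf1"),
        )
        for side, want, gene in checks:
            if want is None:
                continue
            ctx = profile.context_of_side(side)
            if ctx is None:
                return False
            if want == "gene":
                if not (ctx.in_gene and ctx.feature.startswith(gene)):
                    return False
            elif want == "spacer":
                if ctx.in_gene:
                    return False
            elif want == "other":
                # junction inside a gene that is not this side's anchor:
                # signal of IR expansion/contraction past the anchor
                if not (ctx.in_gene and not ctx.feature.startswith(gene)):
                    return False
            else:  # explicit feature name
                if ctx.feature != want:
                    return False
        return True


def default_rules() -> list[BoundaryTypeRule]:
    text = resources.files("plastocomp.data").joinpath("boundary_rules.yaml").read_text()
    return load_rules_yaml(text)


def load_rules_yaml(text: str) -> list[BoundaryTypeRule]:
    cfg = yaml.safe_load(text)
    rules = []
    for entry in cfg["rules"]:
        rules.append(
            BoundaryTypeRule(
                label=entry["label"],
                rps19_context=entry.get("rps19_context"),
                ndhf_context=entry.get("ndhf_context"),
                ycf1_context=entry.get("ycf1_context"),
                note=entry.get("note", ""),
            )
        )
    return rules


def rules_to_yaml(rules: list[BoundaryTypeRule]) -> str:
    return yaml.safe_dump(
        {
            "rules": [
                {
                    "label": r.label,
                    **{
                        k: v
                        for k, v in (
                            ("rps19_context", r.rps19_context),
                            ("ndhf_context", r.ndhf_context),
                            ("ycf1_context", r.ycf1_context),
                            ("note", r.note),
                        )
                        if v
                    },
                }
                for r in rules
            ]
        },
        sort_keys=False,
    )


def assign_boundary_type(
    profile: JunctionProfile, rules: Optional[list[BoundaryTypeRule]] = None
) -> str:
    """First matching label from the ordered rule table; 'Unclassified' if
    none match or the profile lacks the anchors the rules consult."""
    if rules is None:
        rules = default_rules()
    if not profile.complete:
        missing = ", ".join(profile.missing_anchors)
        return f"Unclassified (incomplete profile: missing {missing})"
    for rule in rules:
        if rule.matches(profile):
            return rule.label
    return "Unclassified"
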
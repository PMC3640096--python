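"""Long-repeat detection and five-way structural classification.

A repeat hit is an ungapped pairing of two genome windows of equal length
under one of three relations: direct (both forward), inverted (one window
matches the reverse complement of the other), or reversed (one window
matches the plain character reversal of the other). Hits are *maximal
bounded-mismatch windows*: on each alignment diagonal, for every mismatch
budget j up to ``max_mismatches``, the windows containing exactly j
mismatches that cannot be extended without adding another are enumerated;
windows shorter than ``min_len`` or below ``min_identity`` are discarded,
and windows contained in a surviving window on the same diagonal are
pruned. This reproduces the behaviour of classical maximal-repeat finders
with a Hamming-distance option.

Grouped hits are classified into five structural types:
  D  dispersed direct repeat            T  tandem repeat (gap 0-2 bp)
  I  inverted repeat (opposite strands) P  palindrome (own reverse complement)
  R  sequence matching its own reversal
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .records import revcomp

RELATIONS = ("direct", "inverted", "reversed")

# minimal IUPAC code covering a set of bases
_IUPAC = {
    frozenset("A"): "A", frozenset("C"): "C", frozenset("G"): "G", frozenset("T"): "T",
    frozenset("AG"): "R", frozenset("CT"): "Y", frozenset("CG"): "S",
    frozenset("AT"): "W", frozenset("GT"): "K", frozenset("AC"): "M",
    frozenset("CGT"): "B", frozenset("AGT"): "D", frozenset("ACT"): "H",
    frozenset("ACG"): "V", frozenset("ACGT"): "N",
}


@dataclass(frozen=True)
class Occurrence:
    start: int  # 1-based
    length: int
    strand: str  # '+' forward; '-' reverse-complement orientation

    @property
    def end(self) -> int:
        return self.start + self.length - 1

    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass(frozen=True)
class RepeatHit:
    """One ungapped pairing of two windows (may coincide for P/R hits)."""

    occ1: Occurrence
    occ2: Occurrence
    relation: str
    mismatches: int

    @property
    def length(self) -> int:
        return self.occ1.length

    @property
    def identity(self) -> float:
        return 1.0 - self.mismatches / self.length

    @property
    def self_symmetric(self) -> bool:
        return self.occ1.interval() == self.occ2.interval()


@dataclass
class RepeatSet:
    set_id: int
    consensus: str
    occurrences: list[Occurrence]
    type: str  # D / T / I / P / R
    secondary: str = ""  # parenthetical type from IR-induced duplication
    mirrored_starts: list[int] = field(default_factory=list)

    @property
    def length(self) -> int:
        return len(self.consensus)

    @property
    def type_label(self) -> str:
        return f"{self.type}({self.secondary})" if self.secondary else self.type


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    return arr


_VALID = np.zeros(256, dtype=bool)
for _b in b"ACGT":
    _VALID[_b] = True


def _maximal_windows(mismatch_pos: np.ndarray, seg_len: int, budget: int):
    """Maximal <=budget-mismatch windows over a 0..seg_len-1 match array.

    ``mismatch_pos``: sorted positions of mismatches (invalid bases count as
    mismatches). Yields (a, b, n_mm) windows, inclusive ends, whose flanks
    are mismatches or segment boundaries and whose own ends are matches.
    """
    p = mismatch_pos
    t = len(p)
    out = []
    for j in range(0, min(budget, t) + 1):
        # windows containing exactly the mismatches p[i .. i+j-1]
        for i in range(0, t - j + 1):
            a = (p[i - 1] + 1) if i > 0 else 0
            b = (p[i + j] - 1) if i + j < t else seg_len - 1
            if a <= b:
                out.append((a, b, j))
    return out


def _windows_from_match_array(match: np.ndarray, budget: int, min_len: int,
                              min_identity: float):
    """Filtered, containment-pruned maximal windows from a boolean match array."""
    seg_len = len(match)
    if seg_len == 0:
        return []
    mm = np.flatnonzero(~match)
    raw = _maximal_windows(mm, seg_len, budget)
    cand = []
    for a, b, n_mm in raw:
        # shrink ends onto matches
        while a <= b and not match[a]:
            a += 1
            n_mm -= 1
        while b >= a and not match[b]:
            b -= 1
            n_mm -= 1
        if a > b:
            continue
        length = b - a + 1
        if length < min_len:
            continue
        ident = 1.0 - n_mm / length
        if ident < min_identity:
            continue
        cand.append((a, b, n_mm))
    return sorted(set(cand), key=lambda w: (w[0], -w[1]))


def find_maximal_repeats(
    sequence: str,
    min_len: int = 26,
    min_identity: float = 0.90,
    max_mismatches: int = 3,
    relations: Sequence[str] = RELATIONS,
    seed_len: int = 8,
    max_repeat_len: int = 2000,
) -> list[RepeatHit]:
    """All maximal bounded-mismatch repeat hits in a sequence.

    Masked positions (N or any non-ACGT character) never match; masking SSR
    loci and one IR copy before calling is the caller's responsibility (see
    :func:`scan_genome`). Self-trivial direct hits (a window against itself)
    are excluded; inverted and reversed self-symmetric hits (palindromes and
    reversal-symmetric loci) are kept as single-occurrence hits.

    Search is seed-and-extend: exact ``seed_len``-mers anchor candidate
    diagonals, a vectorized match-density prefilter discards diagonals that
    cannot host a valid window, and surviving diagonal segments (up to
    ``max_repeat_len`` each side of the anchors) are scanned exhaustively
    for maximal windows.
    """
    seq = sequence.upper()
    n = len(seq)
    if n < min_len:
        return []
    fwd = _encode(seq)
    hits: set[RepeatHit] = set()

    for relation in relations:
        if relation == "direct":
            other = fwd
        elif relation == "inverted":
            other = _encode(revcomp(seq))
        else:
            other = fwd[::-1].copy()
        pairs = _anchor_pairs(fwd, other, seed_len, relation == "direct")
        if pairs is None or len(pairs[0]) == 0:
            continue
        ii, jj = _density_prefilter(
            fwd, other, pairs, seed_len, min_len, max_mismatches, min_identity
        )
        for lo, hi, d in _diagonal_segments(ii, jj, max_repeat_len):
            _scan_diagonal_segment(
                fwd, other, d, lo, hi, relation, n, min_len, min_identity,
                max_mismatches, hits,
            )
    return sorted(
        hits, key=lambda h: (-h.length, h.occ1.start, h.occ2.start, h.relation)
    )


def _kmer_codes(arr: np.ndarray, k: int) -> np.ndarray:
    """Integer code of each k-mer; -1 where any base is not A/C/G/T."""
    n = len(arr)
    if n < k:
        return np.empty(0, dtype=np.int64)
    base = np.full(n, -1, dtype=np.int64)
    for v, b in enumerate(b"ACGT"):
        base[arr == b] = v
    codes = np.zeros(n - k + 1, dtype=np.int64)
    ok = np.ones(n - k + 1, dtype=bool)
    for t in range(k):
        sl = base[t : t + n - k + 1]
        codes = codes * 4 + np.where(sl < 0, 0, sl)
        ok &= sl >= 0
    codes[~ok] = -1
    return codes


def _anchor_pairs(fwd, other, k, is_self):
    """(i, j) arrays of positions sharing an exact k-mer between fwd and other."""
    ca = _kmer_codes(fwd, k)
    cb = ca if is_self else _kmer_codes(other, k)
    va = np.flatnonzero(ca >= 0)
    vb = np.flatnonzero(cb >= 0)
    if len(va) == 0 or len(vb) == 0:
        return None
    sa = va[np.argsort(ca[va], kind="stable")]
    sb = vb[np.argsort(cb[vb], kind="stable")]
    keys_a, keys_b = ca[sa], cb[sb]
    shared = np.intersect1d(keys_a, keys_b)
    out_i, out_j = [], []
    for code in shared:
        ia0, ia1 = np.searchsorted(keys_a, [code, code + 1])
        ib0, ib1 = np.searchsorted(keys_b, [code, code + 1])
        grp_a, grp_b = sa[ia0:ia1], sb[ib0:ib1]
        gi = np.repeat(grp_a, len(grp_b))
        gj = np.tile(grp_b, len(grp_a))
        out_i.append(gi)
        out_j.append(gj)
    ii = np.concatenate(out_i)
    jj = np.concatenate(out_j)
    if is_self:
        keep = ii != jj
        ii, jj = ii[keep], jj[keep]
    return ii, jj


def _density_prefilter(fwd, other, pairs, seed_len, min_len, budget,
                       min_identity=0.90, chunk=200_000, reach=40):
    """Keep anchor pairs whose seed extends into a plausible valid window.

    For each anchor the ungapped extension is measured left of the seed
    start and right of the seed end, tracking how far one can go before
    accumulating 1..budget+1 mismatches. The pair survives when some split
    of the mismatch budget yields a window of at least
    max(min_len, mismatches / (1 - min_identity)) columns -- a necessary
    condition for the anchor to lie inside any reported window.
    """
    ii_all, jj_all = pairs
    n, m = len(fwd), len(other)
    keep_masks = []
    # a valid window with m mismatches has at least m/(1-identity) columns
    min_ident_div = int(np.ceil(1.0 / max(1e-9, 1.0 - min_identity)))
    for s0 in range(0, len(ii_all), chunk):
        ii = ii_all[s0 : s0 + chunk]
        jj = jj_all[s0 : s0 + chunk]
        npairs = len(ii)
        ext_l = np.zeros((budget + 1, npairs), dtype=np.int32)
        ext_r = np.zeros((budget + 1, npairs), dtype=np.int32)
        for sign, ext, base_i, base_j in (
            (-1, ext_l, ii, jj),
            (+1, ext_r, ii + seed_len - 1, jj + seed_len - 1),
        ):
            cnt = np.zeros(npairs, dtype=np.int32)
            for step in range(1, reach + 1):
                ai = base_i + sign * step
                bj = base_j + sign * step
                ok = (ai >= 0) & (ai < n) & (bj >= 0) & (bj < m)
                aic = np.clip(ai, 0, n - 1)
                bjc = np.clip(bj, 0, m - 1)
                fa = fwd[aic]
                fb = other[bjc]
                matched = ok & (fa == fb) & _VALID[fa] & _VALID[fb]
                cnt = np.where(ok, cnt + (~matched).astype(np.int32), budget + 1)
                for a in range(budget + 1):
                    ext[a] += (cnt <= a).astype(np.int32)
        keep = np.zeros(npairs, dtype=bool)
        for a in range(budget + 1):
            for b in range(budget + 1 - a):
                win = seed_len + ext_l[a] + ext_r[b]
                need = np.maximum(min_len, min_ident_div * (a + b))
                keep |= win >= need
        keep_masks.append(keep)
    keep = np.concatenate(keep_masks) if keep_masks else np.zeros(0, dtype=bool)
    return ii_all[keep], jj_all[keep]


def _diagonal_segments(ii, jj, margin):
    """Merge surviving anchors per diagonal into scan segments (lo, hi, d)."""
    if len(ii) == 0:
        return []
    diags = jj - ii
    order = np.lexsort((ii, diags))
    ii, diags = ii[order], diags[order]
    segments = []
    cur_d, lo, hi = None, 0, 0
    for i, d in zip(ii, diags):
        if cur_d is None or d != cur_d or i - hi > 2 * margin:
            if cur_d is not None:
                segments.append((lo - margin, hi + margin, cur_d))
            cur_d, lo, hi = d, int(i), int(i)
        else:
            hi = int(i)
    segments.append((lo - margin, hi + margin, cur_d))
    return segments


def _scan_diagonal_segment(fwd, other, d, seg_lo, seg_hi, relation, n,
                           min_len, min_identity, budget, hits):
    """Enumerate maximal windows on one diagonal segment, emit canonical hits.

    Coordinates: i in fwd, j = i + d in other; segment bounds are in i.
    """
    m = len(other)
    i_min = max(0, -d, seg_lo)
    i_max = min(n - 1, m - 1 - d, seg_hi)
    if i_max - i_min + 1 < min_len:
        return
    a_slice = fwd[i_min : i_max + 1]
    b_slice = other[i_min + d : i_max + 1 + d]
    match = (a_slice == b_slice) & _VALID[a_slice] & _VALID[b_slice]
    windows = []
    for a, b, n_mm in _windows_from_match_array(match, budget, min_len, min_identity):
        length = b - a + 1
        i_start = i_min + a
        j_start = i_min + d + a
        hit = _canonical_hit(i_start, j_start, length, n_mm, relation, n)
        if hit is not None:
            windows.append((a, b, hit))
    # prune windows contained in a larger window on this diagonal, except
    # that a self-symmetric window (exact palindrome / reversal core) is
    # never sacrificed to a non-self-symmetric superwindow
    for a, b, hit in windows:
        contained = any(
            (a2 <= a and b <= b2 and (a2, b2) != (a, b)
             and (hit2.self_symmetric or not hit.self_symmetric))
            for a2, b2, hit2 in windows
        )
        if not contained:
            hits.add(hit)


def _canonical_hit(i_start, j_start, length, n_mm, relation, n) -> Optional[RepeatHit]:
    if relation == "direct":
        if i_start == j_start:
            return None  # trivial self-match
        p, q = sorted((i_start, j_start))
        return RepeatHit(
            Occurrence(p + 1, length, "+"),
            Occurrence(q + 1, length, "+"),
            "direct",
            n_mm,
        )
    # map `other` (reversed-axis) coordinates back to genome coordinates
    g_start = n - (j_start + length)  # start of the matched genome window
    p, q = sorted((i_start, g_start))
    if p == q:
        # self-symmetric single occurrence (palindrome / reversal-symmetric)
        return RepeatHit(
            Occurrence(p + 1, length, "+"), Occurrence(p + 1, length, "+"),
            relation, n_mm,
        )
    # inverted pairs: same motif on opposite strands (earlier copy kept '+');
    # reversed pairs carry no strand semantics and stay '+'
    qs = "-" if relation == "inverted" else "+"
    return RepeatHit(
        Occurrence(p + 1, length, "+"), Occurrence(q + 1, length, qs),
        relation, n_mm,
    )

# ---------------------------------------------------------------------------
# grouping and classification


def _overlap_frac(a: Occurrence, b: Occurrence) -> float:
    lo = max(a.start, b.start)
    hi = min(a.end, b.end)
    if hi < lo:
        return 0.0
    return (hi - lo + 1) / min(a.length, b.length)


class _UnionFind:
    def __init__(self) -> None:
        self.parent: dict = {}

    def find(self, x):
        self.parent.setdefault(x, x)
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def iupac_consensus(seqs: Sequence[str]) -> str:
    """Column-wise consensus; any column with >1 residue gets the minimal
    covering ambiguity code."""
    if not seqs:
        return ""
    L = min(len(s) for s in seqs)
    cols = []
    for t in range(L):
        residues = frozenset(s[t] for s in seqs if s[t] in "ACGT")
        cols.append(_IUPAC.get(residues, "N") if residues else "N")
    return "".join(cols)


def group_hits_into_sets(
    hits: Sequence[RepeatHit],
    genome: str,
    min_merge_overlap: float = 0.8,
) -> list[RepeatSet]:
    """Transitive closure of pairwise hits merged into repeat families.

    Occurrences from different hits are identified when they overlap by at
    least ``min_merge_overlap`` of the shorter occurrence. Sets are sorted
    by decreasing consensus length; IUPAC ambiguity codes mark mismatch
    columns.
    """
    if not hits:
        return []
    # collapse near-identical occurrences onto representative nodes
    nodes: list[Occurrence] = []
    node_of: dict[Occurrence, int] = {}

    def node_for(occ: Occurrence) -> int:
        if occ in node_of:
            return node_of[occ]
        for idx, rep in enumerate(nodes):
            if _overlap_frac(occ, rep) >= min_merge_overlap:
                node_of[occ] = idx
                # keep the longer occurrence as representative
                if occ.length > rep.length:
                    nodes[idx] = occ
                return idx
        nodes.append(occ)
        node_of[occ] = len(nodes) - 1
        return len(nodes) - 1

    uf = _UnionFind()
    hit_nodes: list[tuple[RepeatHit, int, int]] = []
    for h in hits:
        n1 = node_for(h.occ1)
        n2 = node_for(h.occ2)
        uf.union(n1, n2)
        hit_nodes.append((h, n1, n2))

    clusters: dict[int, list[int]] = {}
    for idx in range(len(nodes)):
        clusters.setdefault(uf.find(idx), []).append(idx)

    sets: list[RepeatSet] = []
    for root, members in clusters.items():
        member_set = set(members)
        occs = sorted({nodes[i] for i in members}, key=lambda o: o.start)
        cluster_hits = [h for h, n1, n2 in hit_nodes
                        if n1 in member_set or n2 in member_set]
        oriented = []
        for o in occs:
            s = genome[o.start - 1 : o.end]
            oriented.append(revcomp(s) if o.strand == "-" else s)
        consensus = iupac_consensus(oriented)
        rtype = classify_repeat_set(occs, oriented, cluster_hits)
        sets.append(RepeatSet(0, consensus, list(occs), rtype))
    sets.sort(key=lambda s: (-s.length, s.occurrences[0].start))
    for i, s in enumerate(sets, start=1):
        s.set_id = i
    return sets


def classify_repeat_set(
    occurrences: Sequence[Occurrence],
    oriented_seqs: Sequence[str],
    member_hits: Sequence[RepeatHit] = (),
) -> str:
    """Five-way structural type under a fixed decision order.

    1. single occurrence equal to its own reverse complement -> P
    2. single occurrence equal to its own plain reversal     -> R
    3. >=2 same-strand occurrences abutting or overlapping
       (gap <= 2 bp)                                         -> T
    4. >=2 occurrences on opposite strands                   -> I
    5. otherwise                                             -> D

    The self-symmetry checks also consult the member hits: a family whose
    exact core is a palindrome may be reported with a slightly longer,
    asymmetric bounded-mismatch window, and the symmetric core hit then
    carries the evidence.
    """
    occs = sorted(occurrences, key=lambda o: o.start)
    if len(occs) == 1:
        for h in member_hits:
            if h.self_symmetric and h.relation == "inverted":
                return "P"
        for h in member_hits:
            if h.self_symmetric and h.relation == "reversed":
                return "R"
        s = oriented_seqs[0]
        if revcomp(s) == s:
            return "P"
        if s[::-1] == s:
            return "R"
        return "D"
    same_strand_adjacent = False
    for a, b in zip(occs, occs[1:]):
        gap = b.start - (a.end + 1)
        if a.strand == b.strand and gap <= 2:
            same_strand_adjacent = True
    if same_strand_adjacent:
        return "T"
    if len({o.strand for o in occs}) > 1:
        return "I"
    return "D"


# ---------------------------------------------------------------------------
# genome-level scan# ---------------------------------------------------------------------------
# genome-level scan


def mask_intervals(sequence: str, intervals: Iterable[tuple[int, int]]) -> str:
    """Replace 1-based inclusive intervals with N; intervals may wrap the
    circular origin (start > end)."""
    arr = bytearray(sequence.encode())
    n = len(arr)
    for s, e in intervals:
        if s <= e:
            arr[s - 1 : e] = b"N" * (e - s + 1)
        else:
            arr[s - 1 : n] = b"N" * (n - s + 1)
            arr[0:e] = b"N" * e
    return arr.decode()


def scan_genome(
    record,
    partition=None,
    min_len: int = 26,
    min_identity: float = 0.90,
    max_mismatches: int = 3,
    ssr_thresholds=None,
) -> list[RepeatSet]:
    """Long-repeat families of a plastome, in published-table form.

    SSR loci are masked first (they are reported separately by the SSR
    scanner), and one IR copy (IRa) is masked to suppress the genome-scale
    IRa/IRb self-match; hits inside IRb are afterwards mirrored into IRa as
    parenthetical positions.
    """
    from .ssr import DEFAULT_MIN_UNITS, find_ssrs

    seq = record.sequence
    loci = find_ssrs(seq, ssr_thresholds or DEFAULT_MIN_UNITS)
    masked = mask_intervals(seq, [(l.start, l.end) for l in loci])
    ira = irb = None
    if partition is not None:
        ira, irb = partition.ira, partition.irb
        masked = mask_intervals(masked, [ira])
    hits = find_maximal_repeats(
        masked, min_len=min_len, min_identity=min_identity,
        max_mismatches=max_mismatches,
    )
    sets = group_hits_into_sets(hits, seq)
    if ira and irb:
        for s in sets:
            for o in s.occurrences:
                if irb[0] <= o.start and o.end <= irb[1]:
                    mirror = ira[0] + (irb[1] - o.end)
                    s.mirrored_starts.append(mirror)
    return sets


def region_label(pos: int, partition) -> str:
    if partition is None:
        return ""
    for name in ("lsc", "irb", "ssc", "ira"):
        lo, hi = getattr(partition, name)
        if lo <= pos <= hi:
            return name.upper()
    return ""


def repeat_table(sets: Sequence[RepeatSet], partition=None) -> str:
    """TSV shaped like a published long-repeat distribution table."""
    lines = ["no\tlength(bp)\ttype\tstarts\tconsensus\tregions"]
    for s in sets:
        starts = "; ".join(
            f"{o.start}" + (f" ({m})" if i < len(s.mirrored_starts)
                            and (m := s.mirrored_starts[i]) else "")
            for i, o in enumerate(s.occurrences)
        )
        regions = "; ".join(
            sorted({region_label(o.start, partition) for o in s.occurrences} - {""})
        )
        lines.append(
            f"{s.set_id}\t{s.length}\t{s.type_label}\t{starts}\t{s.consensus}\t{regions}"
        )
    return "\n".join(lines) + "\n"
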
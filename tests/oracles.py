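"""Independent reference implementations used only to validate the package.

These deliberately re-derive each quantity from its definition with a
different algorithmic structure than the library (per-position checks and
explicit window recounts instead of scanning/seed-and-extend), so that
agreement is meaningful.
"""

from __future__ import annotations

import itertools

import numpy as np

from plastocomp.records import revcomp
from plastocomp.repeats import Occurrence, RepeatHit

# ---------------------------------------------------------------------------
# SSR oracle


def _is_primitive(motif: str) -> bool:
    n = len(motif)
    return not any(
        n % p == 0 and motif == motif[:p] * (n // p) for p in range(1, n)
    )


def brute_force_ssrs(seq: str, thresholds=(10, 5, 4, 3, 3, 3)):
    """Every maximal period-u tract, checked position by position."""
    seq = seq.upper()
    n = len(seq)
    valid = [c in "ACGT" for c in seq]
    out = []
    for u in range(1, 7):
        need = thresholds[u - 1]
        for i in range(n):
            # tract start: period holds at i, not at i-1
            if i + u >= n or not (valid[i] and valid[i + u] and seq[i] == seq[i + u]):
                continue
            if i > 0 and valid[i - 1] and seq[i - 1] == seq[i - 1 + u]:
                continue
            j = i
            while j + u < n and valid[j + u] and seq[j] == seq[j + u]:
                j += 1
            count = ((j - i) + u) // u
            motif = seq[i : i + u]
            if count >= need and all(valid[i : i + u]) and _is_primitive(motif):
                out.append((motif, count, i + 1))
    # cross-unit suppression: shorter-unit locus wholly inside a longer one
    kept = []
    for motif, count, start in out:
        end = start + len(motif) * count - 1
        nested = any(
            len(m2) > len(motif) and s2 <= start and end <= s2 + len(m2) * c2 - 1
            for m2, c2, s2 in out
        )
        if not nested:
            kept.append((motif, count, start))
    return sorted(kept, key=lambda t: (t[2], len(t[0])))


# ---------------------------------------------------------------------------
# repeat-hit oracle


def _window_valid(x: str, y: str, min_len: int, min_identity: float, budget: int):
    if len(x) < min_len:
        return None
    mm = sum(1 for a, b in zip(x, y) if a != b or a not in "ACGT" or b not in "ACGT")
    if mm > budget:
        return None
    if x[0] != y[0] or x[-1] != y[-1] or x[0] not in "ACGT" or x[-1] not in "ACGT":
        return None
    if 1.0 - mm / len(x) < min_identity:
        return None
    return mm


def brute_force_repeat_hits(
    seq: str, min_len: int = 26, min_identity: float = 0.90, budget: int = 3
):
    """All maximal bounded-mismatch window pairs, by explicit re-count.

    Candidate windows are delimited by match-run boundaries on every
    diagonal of every relation; each candidate's mismatch count, identity
    and flanks are re-checked by direct string comparison, and containment
    pruning protects self-symmetric windows.
    """
    seq = seq.upper()
    n = len(seq)
    valid_lut = np.zeros(256, dtype=bool)
    for ch in b"ACGT":
        valid_lut[ch] = True
    others = {
        "direct": seq,
        "inverted": revcomp(seq),
        "reversed": seq[::-1],
    }
    hits = set()
    for relation, other in others.items():
        arr_a = np.frombuffer(seq.encode(), dtype=np.uint8)
        arr_b = np.frombuffer(other.encode(), dtype=np.uint8)
        per_diag: dict[int, list] = {}
        for d in range(-(n - 1), n):
            i0 = max(0, -d)
            seg = min(n, n - d) - i0
            if seg < min_len:
                continue
            a = arr_a[i0 : i0 + seg]
            b = arr_b[i0 + d : i0 + d + seg]
            match = (a == b) & valid_lut[a] & valid_lut[b]
            if not match.any():
                continue
            starts = np.flatnonzero(match & ~np.roll(match, 1))
            if match[0]:
                starts = np.union1d(starts, [0])
            ends = np.flatnonzero(match & ~np.roll(match, -1))
            if match[-1]:
                ends = np.union1d(ends, [seg - 1])
            # prefix mismatch counts for O(1) window recounts
            pref = np.concatenate([[0], np.cumsum(~match)])
            windows = []
            for s in starts:
                if s > 0 and match[s - 1]:
                    continue  # not a run start (roll artefact at boundary)
                for e in ends[np.searchsorted(ends, s + min_len - 1) :]:
                    mm_fast = int(pref[e + 1] - pref[s])
                    if mm_fast > budget:
                        break  # mismatches only grow with e
                    if e < seg - 1 and match[e + 1]:
                        continue
                    x = seq[i0 + s : i0 + e + 1]
                    y = other[i0 + d + s : i0 + d + e + 1]
                    mm = _window_valid(x, y, min_len, min_identity, budget)
                    if mm is None:
                        continue
                    windows.append((int(i0 + s), int(i0 + e), mm))
            if windows:
                per_diag[d] = windows
        for d, windows in per_diag.items():
            for a0, b0, mm in windows:
                length = b0 - a0 + 1
                hit = _oracle_canonical(a0, d + a0, length, mm, relation, n)
                if hit is None:
                    continue
                contained = any(
                    a2 <= a0 and b0 <= b2 and (a2, b2) != (a0, b0)
                    and (
                        _oracle_canonical(a2, d + a2, b2 - a2 + 1, m2, relation, n)
                        is not None
                        and (
                            _oracle_canonical(
                                a2, d + a2, b2 - a2 + 1, m2, relation, n
                            ).self_symmetric
                            or not hit.self_symmetric
                        )
                    )
                    for a2, b2, m2 in windows
                )
                if not contained:
                    hits.add(hit)
    return hits


def _oracle_canonical(i_start, j_start, length, mm, relation, n):
    if relation == "direct":
        if i_start == j_start:
            return None
        p, q = sorted((i_start, j_start))
        return RepeatHit(
            Occurrence(p + 1, length, "+"), Occurrence(q + 1, length, "+"),
            "direct", mm,
        )
    g_start = n - (j_start + length)
    p, q = sorted((i_start, g_start))
    if p == q:
        return RepeatHit(
            Occurrence(p + 1, length, "+"), Occurrence(p + 1, length, "+"),
            relation, mm,
        )
    qs = "-" if relation == "inverted" else "+"
    return RepeatHit(
        Occurrence(p + 1, length, "+"), Occurrence(q + 1, length, qs),
        relation, mm,
    )


# ---------------------------------------------------------------------------
# parsimony oracle


def brute_force_parsimony(tree, states: dict[str, int]) -> int:
    """Minimum changes over all internal labelings (exhaustive)."""
    internal = [nd for nd in tree.preorder_node_iter() if not nd.is_leaf()]
    best = 10**9
    for assign in itertools.product((0, 1), repeat=len(internal)):
        lab = dict(zip(internal, assign))
        cost = 0
        for nd in tree.preorder_node_iter():
            if nd.parent_node is None:
                continue
            s = states[nd.taxon.label] if nd.is_leaf() else lab[nd]
            cost += s != lab[nd.parent_node]
        best = min(best, cost)
    return best
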
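"""Maximal perfect microsatellite (SSR) detection.

A locus is a maximal run of a primitive 1–6 bp motif meeting a per-unit-size
minimum unit count. Runs are counted in whole units on the given strand,
with the motif reported in the phase at which the run starts (so A-runs and
T-runs, or AT- and TA-runs, are distinct loci). N and ambiguity codes break
runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .records import GeneFeature

DEFAULT_MIN_UNITS = (10, 5, 4, 3, 3, 3)


@dataclass(frozen=True)
class SSRThresholds:
    """Minimum unit counts for motif sizes 1..6."""

    min_units: tuple[int, ...] = DEFAULT_MIN_UNITS

    def __post_init__(self) -> None:
        if len(self.min_units) != 6 or any(m < 2 for m in self.min_units):
            raise ValueError("need six thresholds, all >= 2")

    def for_unit(self, unit_length: int) -> int:
        return self.min_units[unit_length - 1]


@dataclass
class SSRLocus:
    motif: str
    unit_count: int
    start: int  # 1-based
    context: str = "intergenic"

    @property
    def unit_length(self) -> int:
        return len(self.motif)

    @property
    def length(self) -> int:
        return self.unit_length * self.unit_count

    @property
    def end(self) -> int:
        return self.start + self.length - 1

    def __str__(self) -> str:
        ctx = "" if self.context == "intergenic" else f" ({self.context})"
        return f"{self.motif}x{self.unit_count}@{self.start}{ctx}"


def is_primitive(motif: str) -> bool:
    """True when the motif is not a whole-number repetition of a shorter one."""
    n = len(motif)
    for p in range(1, n):
        if n % p == 0 and motif == motif[:p] * (n // p):
            return False
    return True


def find_ssrs(
    sequence: str,
    thresholds: SSRThresholds | Sequence[int] = DEFAULT_MIN_UNITS,
) -> list[SSRLocus]:
    """All maximal primitive-motif runs meeting the unit-count thresholds.

    For each unit size u the sequence decomposes into maximal period-u
    tracts (runs of positions x with seq[x] == seq[x+u]); each tract yields
    at most one locus, anchored at the tract start with the motif in
    starting phase and the count in whole units. Tracts whose starting
    motif is non-primitive belong to a smaller unit size and are skipped.
    A shorter-unit locus wholly inside a reported longer-unit locus is
    suppressed unless it independently meets its threshold outside that
    locus. Output sorted by start, then unit length.
    """
    if not isinstance(thresholds, SSRThresholds):
        thresholds = SSRThresholds(tuple(thresholds))
    seq = sequence.upper()
    n = len(seq)
    valid = [c in "ACGT" for c in seq]
    loci: list[SSRLocus] = []
    for u in range(1, 7):
        need = thresholds.for_unit(u)
        i = 0
        while i + u * need <= n:
            # tract start: period-u holds at i but not at i-1
            if not (
                valid[i]
                and valid[i + u]
                and seq[i] == seq[i + u]
                and (i == 0 or not valid[i - 1] or seq[i - 1] != seq[i - 1 + u])
            ):
                i += 1
                continue
            j = i
            while j + u < n and valid[j + u] and seq[j] == seq[j + u]:
                j += 1
            # tract covers bases i .. (j-1)+u  (j is first non-continuing pos)
            tract_len = (j - i) + u
            count = tract_len // u
            motif = seq[i : i + u]
            if count >= need and all(valid[i : i + u]) and is_primitive(motif):
                loci.append(SSRLocus(motif, count, i + 1))
            i = j + 1
    loci = _suppress_nested(loci, thresholds)
    loci.sort(key=lambda l: (l.start, l.unit_length))
    return loci


def _suppress_nested(loci: list[SSRLocus], thresholds: SSRThresholds) -> list[SSRLocus]:
    kept: list[SSRLocus] = []
    for l in loci:
        nested = False
        for other in loci:
            if other is l or other.unit_length <= l.unit_length:
                continue
            if other.start <= l.start and l.end <= other.end:
                # portion of l outside `other` is empty: keep only if l meets
                # its threshold outside, which it cannot here
                nested = True
                break
        if not nested:
            kept.append(l)
    return kept


def annotate_ssr_context(
    loci: Iterable[SSRLocus], features: Sequence[GeneFeature]
) -> list[SSRLocus]:
    """Set each locus context to the genic feature overlapping its start."""
    out = []
    for l in loci:
        context = "intergenic"
        for f in features:
            if f.contains(l.start):
                context = f.name if f.kind != "pseudogene" else f"Ψ{f.name}"
                break
        out.append(SSRLocus(l.motif, l.unit_count, l.start, context))
    return out


def ssr_table(loci: Sequence[SSRLocus]) -> str:
    """TSV shaped like a published SSR distribution table."""
    lines = ["motif\tunit_length\tunit_count\tlength(bp)\tstart\tcontext"]
    for l in sorted(loci, key=lambda x: (x.unit_length, x.motif, x.length, x.start)):
        lines.append(
            f"{l.motif}\t{l.unit_length}\t{l.unit_count}\t{l.length}\t{l.start}\t{l.context}"
        )
    return "\n".join(lines) + "\n"


def ssr_summary(loci: Sequence[SSRLocus]) -> dict[int, int]:
    """Locus counts by motif size 1..6."""
    out = {u: 0 for u in range(1, 7)}
    for l in loci:
        out[l.unit_length] += 1
    return out


def ssrs_to_bed(identifier: str, loci: Sequence[SSRLocus]) -> str:
    lines = [
        f"{identifier}\t{l.start - 1}\t{l.end}\t{l.motif}x{l.unit_count}\t0\t+"
        for l in loci
    ]
    return "\n".join(lines) + "\n"
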
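"""Base composition by whole genome, quadripartite region, and codon position.

Percentages are reported to two decimals with round-half-up, matching the
conventions of published plastome composition tables. IUPAC ambiguity codes
count toward length but are excluded from base fractions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

from .records import PlastomeRecord


def _pct(x: float) -> float:
    """Percentage rounded half-up to 2 decimals."""
    return float(Decimal(x * 100).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass
class CompositionStats:
    scope: str
    length: int
    a: int
    t: int
    c: int
    g: int

    @property
    def counted(self) -> int:
        return self.a + self.t + self.c + self.g

    @property
    def ambiguous(self) -> int:
        return self.length - self.counted

    def fraction(self, base: str) -> float:
        return getattr(self, base.lower()) / self.counted if self.counted else 0.0

    @property
    def gc(self) -> float:
        return (self.c + self.g) / self.counted if self.counted else 0.0

    def percentages(self) -> dict[str, float]:
        return {
            "G/C": _pct(self.gc),
            "A": _pct(self.fraction("a")),
            "T": _pct(self.fraction("t")),
            "C": _pct(self.fraction("c")),
            "G": _pct(self.fraction("g")),
        }


def base_composition(sequence: str, scope: str = "total") -> CompositionStats:
    """Count A/T/C/G in a sequence; ambiguity codes excluded from fractions."""
    if not sequence:
        raise ValueError("empty sequence")
    s = sequence.upper()
    return CompositionStats(
        scope, len(s), s.count("A"), s.count("T"), s.count("C"), s.count("G")
    )


def composition_by_region(record: PlastomeRecord, partition) -> list[CompositionStats]:
    """Composition of LSC, IRb, SSC and IRa under a quadripartite partition.

    The partition must tile the genome exactly once.
    """
    stats = []
    total = 0
    for label in ("lsc", "irb", "ssc", "ira"):
        seq = partition.region_sequence(record.sequence, label)
        total += len(seq)
        stats.append(base_composition(seq, scope=label.upper().replace("IR", "IR")))
    if total != record.length:
        raise ValueError(
            f"partition does not tile the genome: {total} != {record.length}"
        )
    return stats


def codon_position_composition(
    record: PlastomeRecord,
    include_ir_duplicates: bool = True,
    include_pseudogenes: bool = False,
) -> list[CompositionStats]:
    """Composition at codon positions 1–3 over all protein-coding genes.

    Gene parts are concatenated in translation order (strand-aware). Genes
    whose coding length is not a multiple of three are skipped with a
    warning. Both IR copies of duplicated genes are included by default.
    """
    feats = [
        f
        for f in record.genic_features(include_pseudogenes=include_pseudogenes)
        if f.kind == "protein"
    ]
    if not include_ir_duplicates:
        seen: set[str] = set()
        feats = [f for f in feats if not (f.name in seen or seen.add(f.name))]
    buckets = [[0, 0, 0, 0] for _ in range(3)]  # A T C G per position
    idx = {"A": 0, "T": 1, "C": 2, "G": 3}
    codons = 0
    for f in feats:
        seq = f.sequence(record.sequence)
        if len(seq) % 3 != 0:
            warnings.warn(f"CDS {f.name} length {len(seq)} not divisible by 3; skipped")
            continue
        codons += len(seq) // 3
        for pos in range(3):
            sub = seq[pos::3]
            for base, i in idx.items():
                buckets[pos][i] += sub.count(base)
    out = []
    for pos in range(3):
        a, t, c, g = buckets[pos]
        out.append(CompositionStats(f"codon position {pos + 1}", codons, a, t, c, g))
    return out


def composition_table(record: PlastomeRecord, partition=None) -> str:
    """TSV shaped like a published base-composition table."""
    rows = [base_composition(record.sequence, "Total")]
    if partition is not None:
        rows += composition_by_region(record, partition)
    rows += codon_position_composition(record)
    lines = ["scope\tG/C(%)\tA(%)\tT(%)\tC(%)\tG(%)\tlength(bp)"]
    for st in rows:
        p = st.percentages()
        lines.append(
            f"{st.scope}\t{p['G/C']:.2f}\t{p['A']:.2f}\t{p['T']:.2f}"
            f"\t{p['C']:.2f}\t{p['G']:.2f}\t{st.length}"
        )
    return "\n".join(lines) + "\n"
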
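"""Core in-memory containers for annotated circular plastomes.

Coordinates follow the GenBank convention everywhere a position is exposed:
1-based, inclusive at both ends. Algorithms convert to 0-based half-open
slices internally but never leak them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def revcomp(seq: str) -> str:
    """Reverse complement with IUPAC ambiguity support."""
    return seq.translate(COMPLEMENT)[::-1]


GENE_KINDS = ("protein", "tRNA", "rRNA", "pseudogene")


@dataclass
class GeneFeature:
    """One named, stranded gene.

    ``parts`` is a list of (start, end) 1-based inclusive intervals in
    genomic order of transcription on the given strand; a feature spanning
    the circular origin is split into two parts.
    """

    name: str
    kind: str
    strand: str
    parts: list[tuple[int, int]]
    copy_tag: Optional[str] = None  # {"IRa", "IRb", "single"} when assigned

    def __post_init__(self) -> None:
        if self.kind not in GENE_KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.parts:
            raise ValueError(f"feature {self.name} has no parts")
        for s, e in self.parts:
            if s > e:
                raise ValueError(f"feature {self.name}: part start {s} > end {e}")

    @property
    def start(self) -> int:
        return min(s for s, _ in self.parts)

    @property
    def end(self) -> int:
        return max(e for _, e in self.parts)

    @property
    def length(self) -> int:
        return sum(e - s + 1 for s, e in self.parts)

    def contains(self, pos: int) -> bool:
        return any(s <= pos <= e for s, e in self.parts)

    def sequence(self, genome: str) -> str:
        """Feature sequence in translation order (strand-aware)."""
        chunks = [genome[s - 1 : e] for s, e in self.parts]
        seq = "".join(chunks)
        return revcomp(seq) if self.strand == "-" else seq


@dataclass
class PlastomeRecord:
    """A circular genome sequence plus its named, stranded gene features."""

    identifier: str
    sequence: str
    circular: bool = True
    features: list[GeneFeature] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("empty genome sequence")
        self.sequence = self.sequence.upper()
        self.features.sort(key=lambda f: (f.start, f.end, f.name))
        n = len(self.sequence)
        for f in self.features:
            for s, e in f.parts:
                if not (1 <= s <= e <= n):
                    raise ValueError(
                        f"feature {f.name} part ({s},{e}) outside [1,{n}]"
                    )

    @property
    def length(self) -> int:
        return len(self.sequence)

    def genic_features(self, include_pseudogenes: bool = True) -> list[GeneFeature]:
        if include_pseudogenes:
            return list(self.features)
        return [f for f in self.features if f.kind != "pseudogene"]

    def rotate(self, offset: int) -> "PlastomeRecord":
        """Move the circular origin so old position ``offset+1`` becomes base 1."""
        n = self.length
        offset %= n
        seq = self.sequence[offset:] + self.sequence[:offset]

        def shift(p: int) -> int:
            return (p - 1 - offset) % n + 1

        feats = []
        for f in self.features:
            parts: list[tuple[int, int]] = []
            for s, e in f.parts:
                s2, e2 = shift(s), shift(e)
                if s2 <= e2:
                    parts.append((s2, e2))
                else:  # now wraps the new origin: split
                    parts.append((s2, n))
                    parts.append((1, e2))
            feats.append(GeneFeature(f.name, f.kind, f.strand, parts, f.copy_tag))
        return PlastomeRecord(self.identifier, seq, self.circular, feats)


@dataclass
class IntergenicRegion:
    """Spacer between two genes adjacent on the circle.

    The interval may be empty (abutting or overlapping genes), in which
    case ``start > end`` and ``length == 0``.
    """

    left_gene: str
    right_gene: str
    start: int
    end: int
    sequence: str
    in_ir_duplicate: bool = False

    @property
    def name(self) -> str:
        return f"{self.left_gene}-{self.right_gene}"

    @property
    def length(self) -> int:
        return len(self.sequence)

    def __post_init__(self) -> None:
        # a region spanning the circular origin has start > end; its length
        # is carried by the concatenated sequence itself
        if self.sequence and self.start <= self.end:
            if len(self.sequence) != self.end - self.start + 1:
                raise ValueError(
                    f"region {self.name}: sequence length {len(self.sequence)} "
                    f"!= interval {self.start}-{self.end}"
                )
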
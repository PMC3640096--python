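"""Synthetic quadripartite plastomes with planted, truth-tabled features.

The generator emulates the canonical circular plastome layout — LSC, IRb,
SSC and IRa with IRa the exact reverse complement of IRb — with region-
specific background GC, named stranded gene annotations (IRb genes
duplicated into IRa), and planted SSR and long-repeat loci of every
structural class. Every planted locus is recorded in a truth table so each
downstream scanner can be validated against known ground truth. Background
sequence is i.i.d. within each region and screened post hoc so that no
accidental SSR reaches the reporting thresholds.

Defaults mirror a 156.5 kb asterid plastome: region lengths 86,078 /
26,050 / 18,328 / 26,050 bp and GC 34.9 / 43.0 / 30.2 % in LSC / IR / SSC.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.linalg import expm

from .records import GeneFeature, PlastomeRecord, revcomp
from .ssr import DEFAULT_MIN_UNITS, find_ssrs

class ConfigurationError(ValueError):
    """A planted locus or gene cannot be placed as configured."""


@dataclass(frozen=True)
class GeneTemplate:
    name: str
    kind: str  # protein | tRNA | rRNA | pseudogene
    length: int
    strand: str
    region: str  # LSC | IRb | SSC
    offset: int  # 0-based offset of the gene start within its region


@dataclass(frozen=True)
class PlantedSSR:
    motif: str
    unit_count: int
    region: str
    offset: Optional[int] = None  # auto-placed when None


@dataclass(frozen=True)
class PlantedRepeat:
    type: str  # D | T | I | P | R
    length: int
    copies: int = 2
    regions: tuple[str, ...] = ("LSC", "LSC")


@dataclass
class SynthConfig:
    lsc_len: int = 86_078
    irb_len: int = 26_050
    ssc_len: int = 18_328
    gc_lsc: float = 0.349
    gc_ir: float = 0.430
    gc_ssc: float = 0.302
    gene_templates: Optional[Sequence[GeneTemplate]] = None
    planted_ssrs: Optional[Sequence[PlantedSSR]] = None
    planted_repeats: Optional[Sequence[PlantedRepeat]] = None
    junction_type: str = "I-2"  # I-1 .. I-4 anchor arrangements
    ssr_thresholds: tuple[int, ...] = DEFAULT_MIN_UNITS
    seed: int = 0

    @property
    def ira_len(self) -> int:
        return self.irb_len

    @property
    def genome_len(self) -> int:
        return self.lsc_len + 2 * self.irb_len + self.ssc_len


@dataclass
class TruthLocus:
    category: str  # "ssr" | "repeat" | "gene"
    name: str  # motif, repeat label, or gene name
    start: int  # 1-based
    end: int
    expected: str = ""  # expected classification / context


@dataclass
class SyntheticTruth:
    partition_intervals: dict[str, tuple[int, int]]
    genes: list[TruthLocus]
    ssrs: list[TruthLocus]
    repeats: list[TruthLocus]
    junction_type: str

    def all_planted_intervals(self) -> list[tuple[int, int]]:
        return [
            (t.start, t.end)
            for group in (self.genes, self.ssrs, self.repeats)
            for t in group
        ]


# ---------------------------------------------------------------------------
# default study conditions


def default_planted_ssrs() -> list[PlantedSSR]:
    """A representative plastome SSR complement: mostly A/T homopolymers,
    a few dinucleotide AT/TA runs, tetra- and pentanucleotide loci."""
    return [
        PlantedSSR("A", 10, "LSC"),
        PlantedSSR("A", 12, "LSC"),
        PlantedSSR("A", 15, "LSC"),
        PlantedSSR("T", 10, "LSC"),
        PlantedSSR("T", 11, "LSC"),
        PlantedSSR("T", 14, "LSC"),
        PlantedSSR("C", 10, "LSC"),
        PlantedSSR("G", 12, "LSC"),
        PlantedSSR("T", 13, "SSC"),
        PlantedSSR("T", 15, "SSC"),
        PlantedSSR("AT", 5, "LSC"),
        PlantedSSR("AT", 6, "LSC"),
        PlantedSSR("TA", 5, "SSC"),
        PlantedSSR("AATA", 3, "SSC"),
        PlantedSSR("ATAA", 3, "LSC"),
        PlantedSSR("TTCT", 4, "LSC"),
        PlantedSSR("TAAAT", 3, "LSC"),
    ]


def default_planted_repeats() -> list[PlantedRepeat]:
    """One family of each structural class, at published-table scale."""
    return [
        PlantedRepeat("D", 42, 2, ("LSC", "SSC")),
        PlantedRepeat("T", 36, 2, ("LSC",)),
        PlantedRepeat("I", 29, 2, ("LSC", "LSC")),
        PlantedRepeat("P", 30, 1, ("LSC",)),
        PlantedRepeat("R", 30, 1, ("LSC",)),
    ]


def default_gene_templates(config: "SynthConfig") -> list[GeneTemplate]:
    """A miniature plastome gene complement with junction anchors.

    Positions scale with the configured region lengths; the rps19 / ndhF
    arrangements follow ``config.junction_type`` (the 2x2 subtype grid over
    whether the LSC-IR junction sits in rps19 or the rps19-rpl2 spacer and
    whether the IR-SSC-side junction sits in ndhF or the trnN-ndhF spacer).
    """
    L, I, S = config.lsc_len, config.irb_len, config.ssc_len
    jt = config.junction_type
    if jt not in ("I-1", "I-2", "I-3", "I-4"):
        raise ConfigurationError(f"unsupported junction_type {jt!r}")

    # gene lengths scale down with the region so that miniature test genomes
    # keep the full gene complement and junction geometry
    def scaled(length: int, region_len: int, full: int) -> int:
        if region_len >= full:
            return length
        out = max(60, int(length * region_len / full))
        return out - out % 3  # keep protein lengths codon-aligned

    sL = lambda x: scaled(x, L, 86_078)
    sI = lambda x: scaled(x, I, 26_050)
    sS = lambda x: scaled(x, S, 18_328)
    lsc_frac = [
        # (name, kind, length, strand, fraction of LSC)
        ("trnH-GUG", "tRNA", 74, "-", 0.0005),
        ("psbA", "protein", 1062, "-", 0.004),
        ("matK", "protein", 1530, "-", 0.025),
        ("rps16", "protein", 261, "-", 0.055),
        ("trnQ-UUG", "tRNA", 72, "-", 0.085),
        ("psbK", "protein", 186, "+", 0.095),
        ("atpA", "protein", 1524, "-", 0.12),
        ("atpF", "protein", 555, "-", 0.145),
        ("atpH", "protein", 246, "-", 0.165),
        ("rpoB", "protein", 3213, "-", 0.2),
        ("rpoC1", "protein", 2052, "-", 0.24),
        ("trnS-GCU", "tRNA", 88, "-", 0.28),
        ("trnG-UCC", "tRNA", 71, "+", 0.30),
        ("psbD", "protein", 1062, "+", 0.33),
        ("psbC", "protein", 1386, "+", 0.345),
        ("trnF-GAA", "tRNA", 73, "+", 0.38),
        ("ndhJ", "protein", 477, "-", 0.40),
        ("ndhC", "protein", 363, "-", 0.42),
        ("trnV-UAC", "tRNA", 73, "-", 0.45),
        ("atpB", "protein", 1497, "-", 0.47),
        ("rbcL", "protein", 1428, "+", 0.50),
        ("psaA", "protein", 2253, "-", 0.55),
        ("psaB", "protein", 2205, "-", 0.59),
        ("trnS-GGA", "tRNA", 87, "-", 0.63),
        ("rps4", "protein", 606, "-", 0.65),
        ("accD", "protein", 1461, "+", 0.68),
        ("psbE", "protein", 252, "-", 0.72),
        ("psbF", "protein", 120, "-", 0.725),
        ("psbL", "protein", 117, "-", 0.73),
        ("infA", "protein", 234, "+", 0.76),
        ("rps8", "protein", 405, "-", 0.78),
        ("rpl14", "protein", 369, "-", 0.80),
        ("rpl16", "protein", 408, "-", 0.82),
        ("rps3", "protein", 657, "-", 0.85),
        ("rpl22", "protein", 375, "-", 0.88),
    ]
    genes: list[GeneTemplate] = []
    cursor = {"LSC": 0, "IRb": 0, "SSC": 0}

    def add(name, kind, length, strand, region, offset):
        offset = max(offset, cursor[region])
        genes.append(GeneTemplate(name, kind, length, strand, region, offset))
        cursor[region] = offset + length + 20

    for name, kind, length, strand, frac in lsc_frac:
        length = sL(length)
        add(name, kind, length, strand, "LSC", int(frac * (L - length)))
    # LSC-IR anchors
    rps19_len = sL(279)
    if jt in ("I-2", "I-4"):
        # JLB inside rps19: gene spans the LSC|IRb boundary
        incursion = min(120, rps19_len // 2)
        genes.append(GeneTemplate("rps19", "protein", rps19_len, "-", "LSC",
                                  L - rps19_len + incursion))
    else:
        # JLB in the rps19-rpl2 spacer
        incursion = 0
        genes.append(GeneTemplate("rps19", "protein", rps19_len, "-", "LSC",
                                  L - rps19_len - 60))
    # rpl2 sits just inside IRb, downstream of any rps19 incursion
    add("rpl2", "protein", sI(1491), "-", "IRb", incursion + 40)
    irb = [
        ("rpl23", "protein", 282, "-", 0.07),
        ("ycf2", "protein", 6834, "+", 0.1),
        ("ndhB", "protein", 1533, "-", 0.45),
        ("rrn16", "rRNA", 1491, "+", 0.55),
        ("trnI-GAU", "tRNA", 72, "+", 0.62),
        ("trnA-UGC", "tRNA", 73, "+", 0.64),
        ("rrn23", "rRNA", 2810, "+", 0.67),
        ("rrn4.5", "rRNA", 103, "+", 0.82),
        ("rrn5", "rRNA", 121, "+", 0.84),
    ]
    for name, kind, length, strand, frac in irb:
        length = sI(length)
        add(name, kind, length, strand, "IRb", int(frac * (I - length)))
    # trnN-GUU sits in the IR a few hundred bp from the IR|SSC boundary
    add("trnN-GUU", "tRNA", 72, "-", "IRb", I - min(500, I // 6))
    # SSC genes; ndhF is the IR|SSC-side anchor
    ndhf_len = 2241 if S > 6000 else max(300, S // 6)
    ndhf_len -= ndhf_len % 3
    if jt in ("I-3", "I-4"):
        # junction inside ndhF: gene starts inside IRb and runs into SSC
        genes.append(GeneTemplate("ndhF", "protein", ndhf_len, "-", "IRb", I - 60))
        cursor["SSC"] = ndhf_len - 60 + 20
    else:
        add("ndhF", "protein", ndhf_len, "-", "SSC", 80)
    # ycf1 spans the SSC|IRa boundary (Type I hallmark); SSC gene offsets
    # are distributed over the room left before it
    ycf1_len = min(5000, max(600, S // 3))
    ycf1_len -= ycf1_len % 3
    ycf1_into_ir = min(420, ycf1_len // 4)
    ycf1_offset = S - (ycf1_len - ycf1_into_ir)
    ssc = [
        ("rpl32", "protein", 174, "+", 0.30),
        ("trnL-UAG", "tRNA", 80, "+", 0.38),
        ("ccsA", "protein", 969, "+", 0.44),
        ("ndhD", "protein", 1503, "-", 0.52),
        ("ndhE", "protein", 306, "-", 0.62),
        ("ndhA", "protein", 1092, "-", 0.68),
        ("ndhH", "protein", 1182, "-", 0.78),
        ("rps15", "protein", 273, "-", 0.88),
    ]
    for name, kind, length, strand, frac in ssc:
        length = sS(length)
        room = ycf1_offset - 30 - length
        add(name, kind, length, strand, "SSC", int(frac * max(room, 0)))
    if ycf1_offset < cursor["SSC"]:
        raise ConfigurationError("SSC too small for the default gene complement")
    genes.append(GeneTemplate("ycf1", "protein", ycf1_len, "+", "SSC", ycf1_offset))
    return genes


# ---------------------------------------------------------------------------
# generation


def _region_bounds(config: SynthConfig) -> dict[str, tuple[int, int]]:
    """1-based inclusive intervals of the four regions."""
    L, I, S = config.lsc_len, config.irb_len, config.ssc_len
    return {
        "LSC": (1, L),
        "IRb": (L + 1, L + I),
        "SSC": (L + I + 1, L + I + S),
        "IRa": (L + I + S + 1, L + 2 * I + S),
    }


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, (1 - gc) / 2, gc / 2, gc / 2])  # A T C G
    draws = rng.choice(4, size=length, p=p)
    lut = np.frombuffer(b"ATCG", dtype=np.uint8)
    return lut[draws]


def _compose_unit(rng: np.random.Generator, length: int) -> str:
    """A balanced random unit free of internal SSR-threshold runs."""
    for _ in range(100):
        unit = "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))
        if not find_ssrs(unit, (5, 3, 2, 2, 2, 2)):
            return unit
    raise ConfigurationError("could not compose a low-complexity-free unit")


class _Placer:
    """Tracks occupied intervals per region and hands out free slots.

    Gene intervals and planted loci are tracked separately: auto-placement
    avoids both, while explicitly positioned loci may deliberately sit
    inside a gene (for genic-context plantings) but never inside another
    planted locus.
    """

    def __init__(self, config: SynthConfig, rng: np.random.Generator):
        self.bounds = _region_bounds(config)
        self.rng = rng
        self.genes: list[tuple[int, int]] = []
        self.planted: list[tuple[int, int]] = []

    def reserve(self, start: int, end: int, gene: bool = False) -> None:
        (self.genes if gene else self.planted).append((start, end))

    def conflicts(self, start: int, end: int, pad: int = 12, genes_too: bool = True) -> bool:
        pools = self.planted + (self.genes if genes_too else [])
        return any(s - pad <= end and start <= e + pad for s, e in pools)

    def place(self, region: str, length: int, what: str, pad: int = 12) -> int:
        lo, hi = self.bounds[region]
        span = hi - lo + 1 - length - 2 * pad
        if span <= 0:
            raise ConfigurationError(f"{what}: no room in {region}")
        for _ in range(2000):
            start = lo + pad + int(self.rng.integers(0, span))
            if not self.conflicts(start, start + length - 1, pad):
                self.reserve(start, start + length - 1)
                return start
        raise ConfigurationError(f"{what}: could not place in {region}")


def _write(arr: np.ndarray, start: int, text: str) -> None:
    arr[start - 1 : start - 1 + len(text)] = np.frombuffer(text.encode(), dtype=np.uint8)


def generate_plastome(config: SynthConfig) -> tuple[PlastomeRecord, SyntheticTruth]:
    """Deterministically generate a genome and its planted-locus truth table."""
    rng = np.random.default_rng(config.seed)
    bounds = _region_bounds(config)
    L, I, S = config.lsc_len, config.irb_len, config.ssc_len
    n = config.genome_len
    ira_lo, ira_hi = bounds["IRa"]
    irb_lo, irb_hi = bounds["IRb"]

    # background: LSC + IRb + SSC drawn i.i.d. per region, IRa mirrored later
    core = np.concatenate([
        _random_seq(rng, L, config.gc_lsc),
        _random_seq(rng, I, config.gc_ir),
        _random_seq(rng, S, config.gc_ssc),
    ])

    templates = list(config.gene_templates if config.gene_templates is not None
                     else default_gene_templates(config))
    planted_ssrs = list(config.planted_ssrs if config.planted_ssrs is not None
                        else default_planted_ssrs())
    planted_repeats = list(config.planted_repeats if config.planted_repeats is not None
                           else default_planted_repeats())

    placer = _Placer(config, rng)
    genes: list[TruthLocus] = []
    features: list[GeneFeature] = []

    region_offsets = {"LSC": 0, "IRb": L, "SSC": L + I}
    for t in templates:
        if t.region not in region_offsets:
            raise ConfigurationError(f"gene {t.name}: region must be LSC/IRb/SSC")
        start = region_offsets[t.region] + t.offset + 1
        end = start + t.length - 1
        if end > n:
            raise ConfigurationError(f"gene {t.name}: extends past genome end")
        if placer.conflicts(start, end, pad=2):
            raise ConfigurationError(f"gene {t.name}: overlaps another gene")
        placer.reserve(start, end, gene=True)
        features.append(GeneFeature(t.name, t.kind, t.strand, [(start, end)]))
        genes.append(TruthLocus("gene", t.name, start, end, t.kind))

    ssr_truth: list[TruthLocus] = []
    for p in planted_ssrs:
        motif = p.motif.upper()
        length = len(motif) * p.unit_count
        if p.offset is not None:
            lo, _ = bounds[p.region]
            start = lo + p.offset
            if placer.conflicts(start, start + length - 1, genes_too=False):
                raise ConfigurationError(f"SSR {motif}x{p.unit_count}: placement conflict")
            placer.reserve(start, start + length - 1)
        else:
            start = placer.place(p.region, length, f"SSR {motif}x{p.unit_count}")
        if p.region == "IRa":
            raise ConfigurationError("plant SSRs in IRb; IRa mirrors automatically")
        _write(core, start, motif * p.unit_count)
        _fix_ssr_flanks(core, start, motif, p.unit_count, rng)
        ssr_truth.append(
            TruthLocus("ssr", motif, start, start + length - 1, f"x{p.unit_count}")
        )
        if p.region == "IRb":
            m_start = ira_lo + (irb_hi - (start + length - 1))
            ssr_truth.append(
                TruthLocus("ssr", revcomp(motif), m_start,
                           m_start + length - 1, f"x{p.unit_count} (IR mirror)")
            )

    repeat_truth: list[TruthLocus] = []
    for pr in planted_repeats:
        repeat_truth.extend(_plant_repeat(core, pr, placer, rng))

    _pin_ir_boundaries(core, config, rng)

    # post hoc screening: destroy accidental SSRs reaching the thresholds
    protected = {pos for t in ssr_truth + repeat_truth
                 for pos in range(max(1, t.start - 1), t.end + 2)}
    core = _screen_ssrs(core, config, ssr_truth, protected, rng)
    _pin_ir_boundaries(core, config, rng)

    genome_arr = np.concatenate([core, _rc_arr(core[L : L + I])])
    sequence = genome_arr.tobytes().decode()

    # mirror IRb gene annotations into IRa
    mirrored: list[GeneFeature] = []
    for f in list(features):
        s, e = f.parts[0]
        if irb_lo <= s and e <= irb_hi:
            f.copy_tag = "IRb"
            ms = ira_lo + (irb_hi - e)
            me = ira_lo + (irb_hi - s)
            mirrored.append(GeneFeature(
                f.name, f.kind, "-" if f.strand == "+" else "+", [(ms, me)], "IRa"
            ))
            genes.append(TruthLocus("gene", f.name, ms, me, f.kind + " (IR copy)"))
        elif s <= irb_hi < e or s < irb_lo <= e:
            # gene spanning an IR boundary: mirror only the IR-internal part,
            # annotated as a pseudogene fragment
            ov_lo, ov_hi = max(s, irb_lo), min(e, irb_hi)
            ms = ira_lo + (irb_hi - ov_hi)
            me = ira_lo + (irb_hi - ov_lo)
            mirrored.append(GeneFeature(
                f.name, "pseudogene", "-" if f.strand == "-" else "+", [(ms, me)], "IRa"
            ))
        elif ira_lo <= e and s >= bounds["SSC"][0] and e > ira_lo:
            pass  # handled below (genes running from SSC into IRa)
    for f in list(features):
        s, e = f.parts[0]
        if s < ira_lo <= e:  # e.g. ycf1 running from SSC into IRa
            ov_lo, ov_hi = ira_lo, e
            ms = irb_lo + (ira_hi - ov_hi)
            me = irb_lo + (ira_hi - ov_lo)
            mirrored.append(GeneFeature(
                f.name, "pseudogene", "-" if f.strand == "-" else "+", [(ms, me)], "IRb"
            ))
    features.extend(mirrored)

    record = PlastomeRecord(f"synth-{config.seed}", sequence, True, features)
    truth = SyntheticTruth(
        partition_intervals={k.upper(): v for k, v in bounds.items()},
        genes=genes,
        ssrs=sorted(ssr_truth, key=lambda t: t.start),
        repeats=sorted(repeat_truth, key=lambda t: t.start),
        junction_type=config.junction_type,
    )
    return record, truth


def _rc_arr(arr: np.ndarray) -> np.ndarray:
    comp = np.zeros(256, dtype=np.uint8)
    for x, y in zip(b"ACGTN", b"TGCAN"):
        comp[x] = y
    return comp[arr][::-1]


def _pin_ir_boundaries(core: np.ndarray, config: SynthConfig, rng) -> None:
    """Force mismatches at the IR boundaries so that the maximal exact
    reverse-complement match equals the planted IR exactly.

    The IR match extends left of IRb by pairing the last LSC base with the
    first LSC base, and past the SSC by pairing the first SSC base with the
    last SSC base; both pairings are broken here.
    """
    comp = {ord("A"): "T", ord("T"): "A", ord("C"): "G", ord("G"): "C"}
    L, I, S = config.lsc_len, config.irb_len, config.ssc_len
    for pos, partner in ((L - 1, 0), (L + I, L + I + S - 1)):
        if chr(core[pos]) == comp.get(int(core[partner]), "?"):
            banned = {comp[int(core[partner])]}
            choices = [b for b in "ACGT" if b not in banned]
            core[pos] = ord(choices[int(rng.integers(0, len(choices)))])


def _fix_ssr_flanks(core, start, motif, count, rng):
    """Ensure the planted run is maximal: break period continuation at both flanks."""
    u = len(motif)
    length = u * count
    left = start - 2  # 0-based index of base before the run
    if left >= 0:
        if chr(core[left]) == motif[u - 1]:
            core[left] = ord(_different_base(motif[u - 1], rng))
    right = start - 1 + length  # 0-based index of base after the run
    if right < len(core):
        if chr(core[right]) == motif[0]:
            core[right] = ord(_different_base(motif[0], rng))


def _different_base(base: str, rng) -> str:
    choices = [b for b in "ACGT" if b != base]
    return choices[int(rng.integers(0, len(choices)))]


def _plant_repeat(core, pr: PlantedRepeat, placer: _Placer, rng) -> list[TruthLocus]:
    out: list[TruthLocus] = []
    t = pr.type.upper()
    if t == "P":
        half = _compose_unit(rng, pr.length // 2)
        unit = half + revcomp(half)
        start = placer.place(pr.regions[0], len(unit), "palindrome")
        _write(core, start, unit)
        out.append(TruthLocus("repeat", unit, start, start + len(unit) - 1, "P"))
    elif t == "R":
        for _ in range(50):
            half = _compose_unit(rng, pr.length // 2)
            unit = half + half[::-1]
            if revcomp(unit) != unit:
                break
        else:
            raise ConfigurationError("could not compose a non-palindromic R unit")
        start = placer.place(pr.regions[0], len(unit), "reversal-symmetric repeat")
        _write(core, start, unit)
        out.append(TruthLocus("repeat", unit, start, start + len(unit) - 1, "R"))
    elif t == "T":
        # four tandem copies of a half-length unit: the reported repeat is
        # the duplicated block (unit x2), observed as two abutting
        # occurrences, each pr.length bp long
        unit = _compose_unit(rng, pr.length // 2)
        block = unit * 4
        start = placer.place(pr.regions[0], len(block), "tandem repeat")
        _write(core, start, block)
        out.append(TruthLocus("repeat", unit * 2, start, start + len(block) - 1, "T"))
    elif t == "D":
        unit = _compose_unit(rng, pr.length)
        regions = list(pr.regions) or ["LSC"] * pr.copies
        while len(regions) < pr.copies:
            regions.append(regions[-1])
        for i in range(pr.copies):
            start = placer.place(regions[i], len(unit), "dispersed repeat")
            _write(core, start, unit)
            out.append(TruthLocus("repeat", unit, start, start + len(unit) - 1, "D"))
    elif t == "I":
        unit = _compose_unit(rng, pr.length)
        regions = list(pr.regions) or ["LSC", "LSC"]
        s1 = placer.place(regions[0], len(unit), "inverted repeat copy 1")
        _write(core, s1, unit)
        s2 = placer.place(regions[min(1, len(regions) - 1)], len(unit), "inverted repeat copy 2")
        _write(core, s2, revcomp(unit))
        out.append(TruthLocus("repeat", unit, s1, s1 + len(unit) - 1, "I"))
        out.append(TruthLocus("repeat", revcomp(unit), s2, s2 + len(unit) - 1, "I"))
    else:
        raise ConfigurationError(f"unknown repeat type {pr.type!r}")
    return out


def _screen_ssrs(core, config, ssr_truth, protected, rng) -> np.ndarray:
    """Resample bases inside accidental SSR runs until none reach thresholds."""
    L, I = config.lsc_len, config.irb_len
    bounds = _region_bounds(config)
    ira_lo = bounds["IRa"][0]
    irb_hi = bounds["IRb"][1]
    truth_keys = {(t.start, t.end) for t in ssr_truth}
    for _ in range(40):
        genome = np.concatenate([core, _rc_arr(core[L : L + I])])
        loci = find_ssrs(genome.tobytes().decode(), config.ssr_thresholds)
        bad = [
            l for l in loci
            if (l.start, l.end) not in truth_keys
        ]
        if not bad:
            return core
        for l in bad:
            mid = l.start + l.length // 2
            half = l.length // 2
            if mid >= ira_lo:  # map IRa position back to IRb
                mid = bounds["IRb"][0] + (bounds["IRa"][1] - mid)
            # editable position near the run centre but outside truth loci
            pos = None
            for delta in range(0, half + 1):
                for cand in (mid + delta, mid - delta):
                    if 1 <= cand <= len(core) and cand not in protected:
                        pos = cand
                        break
                if pos is not None:
                    break
            if pos is None:
                continue
            cur = chr(core[pos - 1])
            core[pos - 1] = ord(_different_base(cur if cur in "ACGT" else "A", rng))
    raise ConfigurationError("background screening did not converge")


# ---------------------------------------------------------------------------
# sequence evolution


def _rate_matrix(model: str, kappa: float, freqs: Sequence[float]) -> np.ndarray:
    """Normalized instantaneous rate matrix (expected 1 substitution/site)."""
    model = model.upper()
    pi = np.asarray(freqs, dtype=float)
    pi = pi / pi.sum()
    # order A T C G to match BASE_INDEX? use A C G T ordering internally
    Q = np.zeros((4, 4))
    purine = {0, 2}  # indices in A C G T order: A=0 C=1 G=2 T=3
    for i in range(4):
        for j in range(4):
            if i == j:
                continue
            transition = (i in purine) == (j in purine)
            if model == "JC":
                Q[i, j] = 0.25
            elif model == "K2P":
                Q[i, j] = (kappa if transition else 1.0) * 0.25
            elif model == "F84":
                cls = pi[0] + pi[2] if j in purine else pi[1] + pi[3]
                Q[i, j] = pi[j] * (1.0 + kappa / cls) if transition else pi[j]
            else:
                raise ValueError(f"unknown model {model!r}")
    np.fill_diagonal(Q, -Q.sum(axis=1))
    if model in ("JC", "K2P"):
        pi = np.full(4, 0.25)
    mu = -(pi * np.diag(Q)).sum()
    return Q / mu


_ACGT = "ACGT"
_ACGT_IDX = {c: i for i, c in enumerate(_ACGT)}


def evolve_pair(
    record: PlastomeRecord,
    subst_model: str = "K2P",
    branch_length: float = 0.1,
    kappa: float = 2.0,
    base_freqs: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
    indel_rate: float = 0.0,
    mean_indel_len: float = 2.0,
    seed: int = 0,
    site_rates: Optional[np.ndarray] = None,
) -> PlastomeRecord:
    """Evolve a copy of the genome along a branch of the given expected
    substitutions/site under JC, K2P or F84.

    ``site_rates`` optionally scales the branch length per site (e.g. to
    create fast- and slow-evolving spacers). Indels (geometric lengths,
    mean ``mean_indel_len``) are applied only outside annotated features
    and shift downstream feature coordinates.
    """
    if branch_length < 0:
        raise ValueError("branch_length must be >= 0")
    rng = np.random.default_rng(seed)
    seq = record.sequence
    n = len(seq)
    idx = np.fromiter((_ACGT_IDX.get(c, -1) for c in seq), dtype=np.int64, count=n)
    out = idx.copy()
    if branch_length > 0:
        Q = _rate_matrix(subst_model, kappa, base_freqs)
        if site_rates is None:
            groups = {1.0: np.arange(n)}
        else:
            site_rates = np.asarray(site_rates, dtype=float)
            groups = {r: np.flatnonzero(site_rates == r) for r in np.unique(site_rates)}
        for rate, positions in groups.items():
            if rate <= 0 or len(positions) == 0:
                continue
            P = expm(Q * branch_length * rate)
            P = np.clip(P, 0, None)
            P /= P.sum(axis=1, keepdims=True)
            for b in range(4):
                sel = positions[idx[positions] == b]
                if len(sel) == 0:
                    continue
                out[sel] = rng.choice(4, size=len(sel), p=P[b])
    chars = np.frombuffer(b"ACGT", dtype=np.uint8)
    new_arr = np.where(out >= 0, chars[np.clip(out, 0, 3)],
                       np.frombuffer(seq.encode(), dtype=np.uint8))
    new_seq = new_arr.tobytes().decode()

    feats = [GeneFeature(f.name, f.kind, f.strand, list(f.parts), f.copy_tag)
             for f in record.features]
    if indel_rate > 0:
        new_seq, feats = _apply_indels(
            new_seq, feats, indel_rate, mean_indel_len, rng
        )
    return PlastomeRecord(record.identifier + "-derived", new_seq, record.circular, feats)


def _apply_indels(seq, feats, rate, mean_len, rng):
    n = len(seq)
    genic = np.zeros(n + 1, dtype=bool)
    for f in feats:
        for s, e in f.parts:
            genic[s - 1 : e] = True
    count = rng.poisson(rate * n)
    positions = sorted(
        (int(p) for p in rng.integers(0, n, size=count) if not genic[p]),
        reverse=True,
    )
    p_geom = 1.0 / max(mean_len, 1.0)
    seq_list = seq
    for pos in positions:
        length = int(rng.geometric(p_geom))
        is_del = bool(rng.integers(0, 2))
        if is_del:
            end = min(pos + length, n)
            if genic[pos:end].any():
                end = pos + int(np.argmax(genic[pos:end]))
            if end <= pos:
                continue
            seq_list = seq_list[:pos] + seq_list[end:]
            shift = -(end - pos)
            cut_lo, cut_hi = pos + 1, end
        else:
            ins = "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))
            seq_list = seq_list[:pos] + ins + seq_list[pos:]
            shift = length
            cut_lo = cut_hi = pos + 1
        new_feats = []
        for f in feats:
            parts = []
            for s, e in f.parts:
                if is_del and s >= cut_lo and e < cut_hi:
                    continue  # feature deleted entirely (cannot happen: genic guard)
                s2 = s + shift if s >= cut_hi else s
                e2 = e + shift if e >= cut_hi else e
                parts.append((s2, e2))
            if parts:
                new_feats.append(GeneFeature(f.name, f.kind, f.strand, parts, f.copy_tag))
        feats = new_feats
        n = len(seq_list)
        genic = np.zeros(n + 1, dtype=bool)
        for f in feats:
            for s, e in f.parts:
                genic[s - 1 : e] = True
    return seq_list, feats


def truth_to_tsv(truth: SyntheticTruth) -> str:
    lines = ["category\tname\tstart\tend\texpected"]
    for group in (truth.genes, truth.ssrs, truth.repeats):
        for t in group:
            lines.append(f"{t.category}\t{t.name}\t{t.start}\t{t.end}\t{t.expected}")
    return "\n".join(lines) + "\n"
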
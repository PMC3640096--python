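"""Gene presence/absence matrices, Fitch loss mapping, supermatrix export.

Orthology across plastomes is resolved by normalized gene name (plastid
genes are single-copy and name-stable), optionally backed by a similarity
rescue that realigns a reference gene against an apparently-lacking genome
to catch misannotation. Binary presence characters are mapped onto a fixed
species tree by small parsimony (unit cost), with every branch that can
carry a change in some minimal reconstruction reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import dendropy
import pandas as pd
from Bio import Align

from .records import PlastomeRecord


@dataclass
class PresenceMatrix:
    presence: pd.DataFrame  # taxa x genes, bool
    evidence: pd.DataFrame  # taxa x genes, {"annotated","similarity-rescued","absent"}

    @property
    def taxa(self) -> list[str]:
        return list(self.presence.index)

    @property
    def genes(self) -> list[str]:
        return list(self.presence.columns)

    def losses_relative_to(self, reference: str) -> dict[str, list[str]]:
        """Per-taxon list of genes present in the reference but absent here."""
        ref = self.presence.loc[reference]
        out = {}
        for taxon in self.taxa:
            if taxon == reference:
                continue
            row = self.presence.loc[taxon]
            out[taxon] = sorted(g for g in self.genes if ref[g] and not row[g])
        return out


@dataclass
class LossEvent:
    gene: str
    branch: str  # label of the child node of the branch (taxon or clade label)
    direction: str  # "loss" | "gain"
    ambiguous: bool = False
    alternatives: list[str] = field(default_factory=list)


def _local_identity(query: str, genome: str) -> tuple[float, float]:
    """(identity over aligned query, aligned fraction of query length)."""
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 1.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -2.0
    aligner.extend_gap_score = -0.5
    try:
        aln = aligner.align(genome, query)[0]
    except (IndexError, ValueError):
        return 0.0, 0.0
    a, b = aln[0], aln[1]
    matches = sum(1 for x, y in zip(a, b) if x == y and x != "-")
    aligned_query = sum(1 for y in b if y != "-")
    if aligned_query == 0:
        return 0.0, 0.0
    return matches / aligned_query, aligned_query / len(query)


def build_presence_matrix(
    records: Sequence[PlastomeRecord],
    similarity_rescue: bool = False,
    reference: Optional[str] = None,
    min_identity: float = 0.60,
    min_coverage: float = 0.60,
    kinds: Sequence[str] = ("protein", "rRNA", "tRNA"),
) -> PresenceMatrix:
    """Taxa x gene presence with evidence tags.

    With ``similarity_rescue``, genes annotated in the reference but not in
    a comparator are locally aligned against that comparator's genome
    sequence; >= ``min_identity`` identity over >= ``min_coverage`` of the
    gene length counts as present ("similarity-rescued").
    """
    names = [r.identifier for r in records]
    if len(set(names)) != len(names):
        raise ValueError("duplicate taxon names")
    genes: list[str] = []
    seen: set[str] = set()
    for rec in records:
        for f in rec.genic_features(include_pseudogenes=False):
            if f.kind in kinds and f.name not in seen:
                seen.add(f.name)
                genes.append(f.name)
    presence = pd.DataFrame(False, index=names, columns=genes)
    evidence = pd.DataFrame("absent", index=names, columns=genes)
    for rec in records:
        for f in rec.genic_features(include_pseudogenes=False):
            if f.kind in kinds:
                presence.loc[rec.identifier, f.name] = True
                evidence.loc[rec.identifier, f.name] = "annotated"
    if similarity_rescue:
        ref_rec = None
        if reference is not None:
            ref_rec = next(r for r in records if r.identifier == reference)
        else:
            ref_rec = records[0]
        ref_seqs = {
            f.name: f.sequence(ref_rec.sequence)
            for f in ref_rec.genic_features(include_pseudogenes=False)
            if f.kind in kinds
        }
        for rec in records:
            if rec is ref_rec:
                continue
            for gene, qseq in ref_seqs.items():
                if presence.loc[rec.identifier, gene]:
                    continue
                ident, cov = _local_identity(qseq, rec.sequence)
                if ident >= min_identity and cov >= min_coverage:
                    presence.loc[rec.identifier, gene] = True
                    evidence.loc[rec.identifier, gene] = "similarity-rescued"
    return PresenceMatrix(presence, evidence)


# ---------------------------------------------------------------------------
# small parsimony


def _node_label(node: dendropy.Node) -> str:
    if node.taxon is not None:
        return node.taxon.label
    leaves = sorted(l.taxon.label for l in node.leaf_iter())
    return "{" + ",".join(leaves) + "}"


def _sankoff(tree: dendropy.Tree, states: dict[str, int]):
    """Unit-cost small parsimony. Returns (min_cost, inside, outside) tables.

    inside[node][s]: minimal cost of the subtree below node given node=s.
    outside[node][s]: minimal cost of everything outside the subtree given
    node=s (computed by a pre-order pass), enabling per-branch queries.
    """
    INF = 10**9
    inside: dict = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            s = states[node.taxon.label]
            inside[node] = [0 if s == 0 else INF, 0 if s == 1 else INF]
        else:
            costs = [0, 0]
            for child in node.child_nodes():
                ci = inside[child]
                for s in (0, 1):
                    costs[s] += min(ci[0] + (s != 0), ci[1] + (s != 1))
            inside[node] = costs
    root = tree.seed_node
    min_cost = min(inside[root])
    outside: dict = {root: [0, 0]}
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            continue
        for child in node.child_nodes():
            oc = [0, 0]
            for s_child in (0, 1):
                best = INF
                for s_node in (0, 1):
                    other = outside[node][s_node]
                    for sib in node.child_nodes():
                        if sib is child:
                            continue
                        si = inside[sib]
                        other += min(si[0] + (s_node != 0), si[1] + (s_node != 1))
                    best = min(best, other + (s_node != s_child))
                oc[s_child] = best
            outside[child] = oc
    return min_cost, inside, outside


def map_losses_fitch(
    matrix: PresenceMatrix, tree: dendropy.Tree | str
) -> list[LossEvent]:
    """Minimal loss/gain events per gene on a fixed tree.

    Every branch that carries a change in at least one minimal
    reconstruction is reported; when their number exceeds the minimal event
    count, the placements are flagged ambiguous and cross-listed.
    """
    if isinstance(tree, str):
        tree = dendropy.Tree.get(data=tree, schema="newick")
    tips = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    missing = tips - set(matrix.taxa)
    if missing:
        raise ValueError(f"tree tips missing from matrix: {sorted(missing)}")

    events: list[LossEvent] = []
    for gene in matrix.genes:
        states = {t: int(matrix.presence.loc[t, gene]) for t in tips}
        if len(set(states.values())) == 1:
            continue
        min_cost, inside, outside = _sankoff(tree, states)
        branch_events: list[tuple[str, str]] = []
        for node in tree.preorder_node_iter():
            if node.parent_node is None:
                continue
            # cost with both branch endpoints pinned: parent-side outside +
            # sibling subtrees + branch change + child subtree
            parent = node.parent_node
            for s_par in (0, 1):
                for s_child in (0, 1):
                    if s_par == s_child:
                        continue
                    out_par = outside[parent][s_par]
                    ins_rest = 0
                    for sib in parent.child_nodes():
                        if sib is node:
                            continue
                        si = inside[sib]
                        ins_rest += min(
                            si[0] + (s_par != 0), si[1] + (s_par != 1)
                        )
                    total = out_par + ins_rest + 1 + inside[node][s_child]
                    if total == min_cost:
                        direction = "loss" if (s_par, s_child) == (1, 0) else "gain"
                        branch_events.append((_node_label(node), direction))
                        break
        labels = [b for b, _ in branch_events]
        ambiguous = len(branch_events) > min_cost
        for branch, direction in branch_events:
            events.append(
                LossEvent(
                    gene,
                    branch,
                    direction,
                    ambiguous=ambiguous,
                    alternatives=[l for l in labels if l != branch] if ambiguous else [],
                )
            )
    return events


def min_event_count(matrix: PresenceMatrix, tree: dendropy.Tree | str, gene: str) -> int:
    """Minimal number of state changes for one gene on the tree."""
    if isinstance(tree, str):
        tree = dendropy.Tree.get(data=tree, schema="newick")
    tips = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    states = {t: int(matrix.presence.loc[t, gene]) for t in tips}
    if len(set(states.values())) == 1:
        return 0
    cost, _, _ = _sankoff(tree, states)
    return cost


# ---------------------------------------------------------------------------
# supermatrix


@dataclass
class Supermatrix:
    alignment: dict[str, str]  # taxon -> concatenated row
    partitions: dict[str, tuple[int, int]]  # gene -> (start, end) 1-based inclusive

    @property
    def width(self) -> int:
        return next(iter(self.alignment.values())).__len__() if self.alignment else 0

    def to_phylip(self) -> str:
        taxa = list(self.alignment)
        lines = [f" {len(taxa)} {self.width}"]
        for t in taxa:
            lines.append(f"{t}  {self.alignment[t]}")
        return "\n".join(lines) + "\n"

    def to_fasta(self) -> str:
        return "".join(f">{t}\n{s}\n" for t, s in self.alignment.items())

    def partition_file(self) -> str:
        return "".join(
            f"DNA, {gene} = {s}-{e}\n" for gene, (s, e) in self.partitions.items()
        )


def build_supermatrix(
    gene_alignments: dict[str, dict[str, str]],
    taxa: Optional[Sequence[str]] = None,
) -> Supermatrix:
    """Concatenate per-gene alignments over the taxa shared by all genes.

    Genes absent in any selected taxon are excluded (intersection rule).
    Raises when a gene's rows differ in length.
    """
    if taxa is None:
        taxa_set: Optional[set] = None
        for rows in gene_alignments.values():
            taxa_set = set(rows) if taxa_set is None else taxa_set
        taxa = sorted(taxa_set or [])
    taxa = list(taxa)
    kept = {}
    for gene, rows in sorted(gene_alignments.items()):
        if not all(t in rows for t in taxa):
            continue
        lengths = {len(rows[t]) for t in taxa}
        if len(lengths) != 1:
            raise ValueError(f"gene {gene}: aligned rows differ in length")
        kept[gene] = rows
    alignment = {t: "" for t in taxa}
    partitions: dict[str, tuple[int, int]] = {}
    pos = 1
    for gene, rows in kept.items():
        width = len(next(iter(rows.values())))
        for t in taxa:
            alignment[t] += rows[t]
        partitions[gene] = (pos, pos + width - 1)
        pos += width
    return Supermatrix(alignment, partitions)
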
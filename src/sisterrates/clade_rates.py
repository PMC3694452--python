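"""Sister-clade extraction and clade branch-length summaries.

For each comparison the pair's tips are pruned out of the genome tree with
path lengths preserved, the subtree is rooted on the outgroup, and each
clade's rate statistic is the sum of all edge lengths from the shared
ancestral node down to the clade's tips — the stem edge plus every internal
and terminal edge inside the clade.  Both clades have had the same time since
that shared node, so the difference of the two sums reflects a rate
difference.
"""

from __future__ import annotations

from dataclasses import dataclass

from .alignments import Alignment
from .pairs import ComparisonPair
from .trees import Tree, TreeError

__all__ = [
    "CladeRateSummary",
    "PairSubtree",
    "extract_pair_subtree",
    "clade_branch_sum",
    "gc_content",
    "summarize_pair",
    "sign_of",
]


def sign_of(diff: float) -> str:
    return "+" if diff > 0 else ("-" if diff < 0 else "0")


@dataclass(frozen=True)
class CladeRateSummary:
    """One table row: a pair x genome x rate-class statistic for both clades."""

    pair_id: int
    genome: str
    rate_class: str
    P: float
    NP: float

    @property
    def sign(self) -> str:
        return sign_of(self.P - self.NP)

    @property
    def difference(self) -> float:
        return self.P - self.NP


@dataclass
class PairSubtree:
    """An outgroup-rooted subtree for one comparison."""

    pair: ComparisonPair
    tree: Tree
    shared: object  # MRCA of parasite + nonparasite tips (dendropy node)
    clade_root: dict  # side ("P"/"NP") -> dendropy node


def _leafset(node) -> set[str]:
    return {lf.taxon.label for lf in node.leaf_iter()}


def extract_pair_subtree(tree: Tree, pair: ComparisonPair) -> PairSubtree:
    """Prune a genome tree down to one comparison and root it on the outgroup.

    Path lengths between retained tips are preserved exactly.  Raises
    :class:`TreeError` naming the intruding tips when the parasitic or
    non-parasitic set is not monophyletic in the supplied topology.
    """
    have = set(tree.tip_labels)
    missing = sorted(pair.all_tips - have)
    if missing:
        raise TreeError(f"pair {pair.pair_id}: tips not in tree: {missing}")

    sub = tree.clone()
    if pair.all_tips != have:
        sub.dtree.retain_taxa_with_labels(sorted(pair.all_tips))
        sub.dtree.purge_taxon_namespace()

    # root on the outgroup edge so both clades hang below their shared node
    out = Tree(sub.dtree, unit=tree.unit)
    og_node = out.mrca(sorted(pair.outgroup))
    if og_node.parent_node is not None:
        edge = og_node.edge
        half = (edge.length or 0.0) / 2.0
        out.dtree.reroot_at_edge(edge, length1=half, length2=half)
    out.dtree.purge_taxon_namespace()

    shared = out.mrca(sorted(pair.parasite | pair.nonparasite))
    roots = {}
    for side, tips in [("P", pair.parasite), ("NP", pair.nonparasite)]:
        node = out.mrca(sorted(tips))
        found = _leafset(node)
        intruders = sorted(found - tips)
        if intruders:
            raise TreeError(
                f"pair {pair.pair_id}: {side} clade not monophyletic; "
                f"intruding tips: {intruders}"
            )
        roots[side] = node
    return PairSubtree(pair=pair, tree=out, shared=shared, clade_root=roots)


def clade_branch_sum(sub: PairSubtree, side: str) -> float:
    """Total branch length of one clade measured from the shared node.

    Includes the stem edge(s) connecting the shared node to the clade root
    and every edge within the clade.  Raises on a missing edge length.
    """
    if side not in sub.clade_root:
        raise ValueError(f"side must be 'P' or 'NP', got {side!r}")
    root = sub.clade_root[side]
    total = 0.0

    def edge_len(node):
        if node.edge.length is None:
            raise TreeError(
                f"missing edge length above {getattr(node.taxon, 'label', 'internal node')}"
            )
        return node.edge.length

    # stem: walk from the clade root up to the shared node
    node = root
    while node is not sub.shared:
        if node.parent_node is None:
            raise TreeError("clade root is not a descendant of the shared node")
        total += edge_len(node)
        node = node.parent_node
    # everything inside the clade
    for nd in root.preorder_iter():
        if nd is root:
            continue
        total += edge_len(nd)
    return total


def gc_content(aln: Alignment, tips, per_tip_mean: bool = False) -> float:
    """G+C fraction over the listed tips' sequences, ignoring gaps and N.

    By default sites are pooled across tips (each counted base weighs
    equally); ``per_tip_mean`` averages per-tip fractions instead.
    """
    fractions = []
    gc_total = 0
    at_total = 0
    for label in tips:
        if label not in aln.records:
            raise ValueError(f"tip {label!r} not in alignment")
        seq = aln.records[label]
        gc = seq.count("G") + seq.count("C")
        at = seq.count("A") + seq.count("T")
        if gc + at:
            fractions.append(gc / (gc + at))
        gc_total += gc
        at_total += at
    if gc_total + at_total == 0:
        raise ValueError("no unambiguous bases in the listed tips")
    if per_tip_mean:
        return float(sum(fractions) / len(fractions))
    return gc_total / (gc_total + at_total)


def summarize_pair(
    pair_id: int, genome: str, values_by_class: dict[str, tuple[float, float]]
) -> list[CladeRateSummary]:
    """Build table rows from per-class (P, NP) clade statistics.

    ``values_by_class`` maps a rate class (``total``, ``dN``, ``dS``,
    ``omega``, ``GC``, or a gene name) to the parasitic and non-parasitic
    clade values.  Branch-sum classes carry clade sums; ``omega`` rows carry
    the per-clade fitted ratio, and ``GC`` rows must lie in [0, 1].
    """
    rows = []
    for rate_class, (p, np_) in values_by_class.items():
        if rate_class == "GC" and not (0 <= p <= 1 and 0 <= np_ <= 1):
            raise ValueError("GC content must lie in [0, 1]")
        if p < 0 or np_ < 0:
            raise ValueError(f"negative clade statistic for {rate_class!r}")
        rows.append(CladeRateSummary(pair_id, genome, rate_class, p, np_))
    return rows
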
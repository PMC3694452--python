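"""Phylogenetic tree container and newick I/O.

Trees are thin wrappers around :class:`dendropy.Tree` carrying a branch-length
unit tag (``"nucleotide-site"`` or ``"codon"``).  All branch lengths are
expected numbers of substitutions per site (or per codon for codon-model
fits).
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy

__all__ = ["Tree", "TreeError", "parse_newick", "write_newick"]

NUCLEOTIDE_SITE = "nucleotide-site"
CODON = "codon"


class TreeError(ValueError):
    """Raised for malformed newick or invalid tree operations."""


@dataclass
class Tree:
    """A rooted, labelled phylogenetic tree with edge lengths.

    Parameters
    ----------
    dtree:
        Backing dendropy tree.  Taxa must have unique labels.
    unit:
        Branch-length unit tag: ``"nucleotide-site"`` or ``"codon"``.
    """

    dtree: dendropy.Tree
    unit: str = NUCLEOTIDE_SITE

    # -- basic queries -------------------------------------------------
    @property
    def tip_labels(self) -> list[str]:
        return [lf.taxon.label for lf in self.dtree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return sum(1 for _ in self.dtree.leaf_node_iter())

    def total_length(self) -> float:
        """Sum of all edge lengths (missing lengths count as 0)."""
        return sum(
            e.length or 0.0
            for e in self.dtree.preorder_edge_iter()
            if e.head_node.parent_node is not None
        )

    def n_edges(self) -> int:
        return sum(
            1
            for e in self.dtree.preorder_edge_iter()
            if e.head_node.parent_node is not None
        )

    def clone(self) -> "Tree":
        # give the copy its own taxon namespace so pruning/rerooting the
        # clone can never corrupt the source tree
        nt = self.dtree.clone(depth=1)
        nt.migrate_taxon_namespace(dendropy.TaxonNamespace())
        return Tree(nt, unit=self.unit)

    # -- path metrics --------------------------------------------------
    def tip_distance_matrix(self) -> dict[tuple[str, str], float]:
        """Pairwise patristic distances between tips, keyed by sorted label pair."""
        pdm = self.dtree.phylogenetic_distance_matrix()
        out: dict[tuple[str, str], float] = {}
        taxa = list(self.dtree.taxon_namespace)
        for i, t1 in enumerate(taxa):
            for t2 in taxa[i + 1 :]:
                key = tuple(sorted((t1.label, t2.label)))
                out[key] = pdm.patristic_distance(t1, t2)
        return out

    def mrca(self, labels) -> dendropy.Node:
        labels = list(labels)
        if len(labels) == 1:
            node = self.dtree.find_node_with_taxon_label(labels[0])
            if node is None:
                raise TreeError(f"tip {labels[0]!r} not in tree")
            return node
        node = self.dtree.mrca(taxon_labels=labels)
        if node is None:
            raise TreeError(f"no MRCA found for {labels!r}")
        return node


def parse_newick(text: str, unit: str = NUCLEOTIDE_SITE) -> Tree:
    """Parse a newick string into a :class:`Tree`.

    Branch lengths are optional and default to ``None`` where omitted.
    Raises :class:`TreeError` naming the offending token for unbalanced
    parentheses or duplicate tip labels.
    """
    if text.count("(") != text.count(")"):
        raise TreeError(
            "unbalanced parentheses in newick: "
            f"{text.count('(')} '(' vs {text.count(')')} ')'"
        )
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises various error classes
        raise TreeError(f"newick parse error: {exc}") from exc
    labels = [lf.taxon.label for lf in dtree.leaf_node_iter()]
    seen: set[str] = set()
    for lab in labels:
        if lab in seen:
            raise TreeError(f"duplicate tip label: {lab!r}")
        seen.add(lab)
    return Tree(dtree, unit=unit)


def write_newick(tree: Tree, precision: int = 10) -> str:
    """Serialize a tree to a one-line newick string with branch lengths.

    Round-trips with :func:`parse_newick` up to numeric formatting
    (``precision`` significant digits).
    """
    s = tree.dtree.as_string(
        schema="newick",
        suppress_rooting=True,
        real_value_format_specifier=f".{precision}g",
        preserve_spaces=True,
        unquoted_underscores=True,
    )
    return s.strip()
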
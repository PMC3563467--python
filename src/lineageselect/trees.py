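"""Species trees with branch lengths, pruning, and foreground-branch marks.

The foreground branch is the single lineage tested for lineage-specific
selection under the branch-site models: either a terminal branch (an extant
lineage) or the branch subtending a named clade / MRCA of a taxon set (an
ancestral lineage).  Exactly one branch may carry the mark per fit.
"""

from __future__ import annotations

from pathlib import Path

import dendropy


class TreeError(ValueError):
    """Raised for malformed Newick input or invalid tree operations."""


class SpeciesTree:
    """A rooted phylogeny with optional internal-node labels and one
    optional foreground-branch mark.

    Thin wrapper around a :class:`dendropy.Tree`; node identity for the
    foreground mark is kept as a dendropy node reference.
    """

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        self.foreground_node: dendropy.Node | None = None
        for leaf in tree.leaf_node_iter():
            if leaf.taxon is None:
                raise TreeError("leaf without a taxon label")
        for edge in tree.preorder_edge_iter():
            if edge.length is not None and edge.length < 0:
                raise TreeError(f"negative branch length {edge.length}")

    # -- construction -------------------------------------------------

    @classmethod
    def from_newick(cls, text: str) -> "SpeciesTree":
        text = text.strip()
        if not text:
            raise TreeError("empty Newick input")
        try:
            tree = dendropy.Tree.get(
                data=text, schema="newick",
                suppress_internal_node_taxa=True,
                preserve_underscores=True,
            )
        except Exception as exc:
            raise TreeError(f"could not parse Newick: {exc}") from exc
        if tree.seed_node is None or not tree.leaf_nodes():
            raise TreeError("Newick input contains no leaves")
        tree.is_rooted = True
        return cls(tree)

    def clone(self) -> "SpeciesTree":
        out = SpeciesTree(self._tree.clone(depth=1))
        if self.foreground_node is not None:
            # re-locate the marked branch in the clone via its leaf set
            leaves = self.clade_leaves(self.foreground_node)
            out.foreground_node = out._node_for_leafset(leaves)
        return out

    # -- basic queries -------------------------------------------------

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree

    @property
    def leaf_names(self) -> list[str]:
        return [lf.taxon.label for lf in self._tree.leaf_node_iter()]

    def has_branch_lengths(self) -> bool:
        return all(
            nd.edge.length is not None
            for nd in self._tree.preorder_node_iter()
            if nd.parent_node is not None
        )

    @staticmethod
    def clade_leaves(node: dendropy.Node) -> frozenset[str]:
        return frozenset(lf.taxon.label for lf in node.leaf_iter())

    def _node_for_leafset(self, leaves: frozenset[str]) -> dendropy.Node:
        for nd in self._tree.preorder_node_iter():
            if nd.parent_node is None:
                continue
            if self.clade_leaves(nd) == leaves:
                return nd
        raise TreeError(f"no branch subtends exactly {sorted(leaves)}")

    def node_by_label(self, label: str) -> dendropy.Node:
        """Find a node by leaf taxon label or internal-node label."""
        for nd in self._tree.preorder_node_iter():
            if nd.taxon is not None and nd.taxon.label == label:
                return nd
            if nd.taxon is None and nd.label == label:
                return nd
        raise TreeError(f"no node labeled {label!r}")

    def mrca(self, taxa: list[str] | set[str]) -> dendropy.Node:
        taxa = sorted(taxa)
        present = set(self.leaf_names)
        missing = [t for t in taxa if t not in present]
        if missing:
            raise TreeError(f"taxa not in tree: {missing}")
        node = self._tree.mrca(taxon_labels=taxa)
        if node is None:
            raise TreeError(f"could not resolve MRCA of {taxa}")
        return node

    def depths(self) -> dict[str, float]:
        """Root-to-leaf path length for every leaf, including any stem edge
        retained on the root after pruning (missing lengths count 0)."""
        stem = self._tree.seed_node.edge.length or 0.0
        out: dict[str, float] = {}
        for lf in self._tree.leaf_node_iter():
            d, nd = stem, lf
            while nd.parent_node is not None:
                d += nd.edge.length or 0.0
                nd = nd.parent_node
            out[lf.taxon.label] = d
        return out


def read_species_tree(path: str | Path) -> SpeciesTree:
    """Read a Newick tree, preserving internal-node labels for branch selection."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    text = path.read_text()
    return SpeciesTree.from_newick(text)


def prune_tree(tree: SpeciesTree, keep: list[str] | set[str]) -> SpeciesTree:
    """Restrict the tree to ``keep``; degree-2 nodes are suppressed with their
    branch lengths summed, so root-to-leaf path lengths are preserved."""
    keep = list(keep)
    if len(keep) < 2:
        raise TreeError("must keep at least 2 taxa")
    present = set(tree.leaf_names)
    unknown = [t for t in keep if t not in present]
    if unknown:
        raise TreeError(f"unknown taxa in keep set: {unknown}")
    clone = tree.dendropy_tree.clone(depth=1)
    clone.retain_taxa_with_labels(keep)
    clone.suppress_unifurcations()
    # suppress_unifurcations can leave a degree-1 root; splice it away too
    seed = clone.seed_node
    while seed.num_child_nodes() == 1:
        child = seed.child_nodes()[0]
        child.edge.length = (child.edge.length or 0.0) + (seed.edge.length or 0.0)
        clone.seed_node = child
        child.parent_node = None
        seed = child
    return SpeciesTree(clone)


def mark_foreground(tree: SpeciesTree,
                    selector: str | list[str] | set[str]) -> SpeciesTree:
    """Return a copy with exactly one branch marked as foreground.

    ``selector`` is a leaf name, an internal-node label, or a collection of
    taxon names whose MRCA's subtending branch is marked.  Any prior mark is
    cleared first.
    """
    out = tree.clone()
    if isinstance(selector, str):
        node = out.node_by_label(selector)
    else:
        node = out.mrca(selector)
    if node.parent_node is None:
        raise TreeError(
            "selector resolves to the root, which has no subtending branch"
        )
    out.foreground_node = node
    return out
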
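"""Unrooted phylogenetic trees with branch lengths and Newick round-tripping.

Trees are stored rooted at an internal node; for an unrooted binary tree over
three or more taxa the storage root is a basal trifurcation.  The placement of
this virtual root is irrelevant for reversible-model likelihoods, which the
engine's tests exercise directly via :meth:`PhyloTree.reroot`.
"""

from __future__ import annotations

import io

import dendropy

__all__ = ["Node", "PhyloTree", "read_newick", "write_newick", "TreeError"]

DEFAULT_BRANCH_LENGTH = 0.1


class TreeError(ValueError):
    pass


class Node:
    __slots__ = ("label", "length", "children", "parent")

    def __init__(self, label=None, length=None):
        self.label = label
        self.length = length
        self.children: list[Node] = []
        self.parent: Node | None = None

    def add_child(self, node: "Node") -> "Node":
        node.parent = self
        self.children.append(node)
        return node

    def remove_child(self, node: "Node") -> None:
        self.children.remove(node)
        if node.parent is self:  # may already be re-linked (e.g. rerooting)
            node.parent = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self):  # pragma: no cover
        return f"Node({self.label!r}, n_children={len(self.children)})"


class PhyloTree:
    """Wrapper around a rooted node structure representing an unrooted tree."""

    def __init__(self, root: Node):
        self.root = root

    # -- construction -------------------------------------------------------

    @classmethod
    def from_newick(cls, text: str) -> "PhyloTree":
        return read_newick(text)

    def copy(self) -> "PhyloTree":
        def clone(n: Node) -> Node:
            c = Node(n.label, n.length)
            for ch in n.children:
                c.add_child(clone(ch))
            return c

        return PhyloTree(clone(self.root))

    # -- traversal ----------------------------------------------------------

    def postorder(self):
        out = []
        stack = [self.root]
        while stack:
            n = stack.pop()
            out.append(n)
            stack.extend(n.children)
        return reversed(out)

    def preorder(self):
        stack = [self.root]
        while stack:
            n = stack.pop()
            yield n
            stack.extend(reversed(n.children))

    def leaves(self) -> list[Node]:
        return [n for n in self.postorder() if n.is_leaf]

    def taxa(self) -> list[str]:
        return [n.label for n in self.leaves()]

    def internal_nodes(self) -> list[Node]:
        return [n for n in self.postorder() if not n.is_leaf]

    def edges(self) -> list[Node]:
        """Edges identified by their child endpoint (all non-root nodes)."""
        return [n for n in self.postorder() if n.parent is not None]

    def n_taxa(self) -> int:
        return len(self.leaves())

    # -- manipulation -------------------------------------------------------

    def set_default_branch_lengths(self, length: float = DEFAULT_BRANCH_LENGTH):
        for n in self.postorder():
            if n.parent is not None and n.length is None:
                n.length = length
        return self

    def reroot(self, node: Node) -> "PhyloTree":
        """Re-hang the tree at ``node`` (must be internal), in place.

        Preserves the unrooted topology and branch lengths; the old root is
        suppressed if left with degree two.
        """
        if node.is_leaf:
            raise TreeError("cannot root at a leaf")
        if node is self.root:
            return self
        # reverse the parent chain; edge lengths stay with their edges
        path = []
        n = node
        while n is not None:
            path.append(n)
            n = n.parent
        orig_length = {id(n): n.length for n in path}
        for child, parent in zip(path, path[1:]):
            parent.remove_child(child)
            child.add_child(parent)
            parent.length = orig_length[id(child)]
        old_root = path[-1]
        if len(old_root.children) == 1:
            # suppress degree-2 node: splice its single child into its parent
            child = old_root.children[0]
            parent = old_root.parent
            child.length = (child.length or 0.0) + (old_root.length or 0.0)
            parent.remove_child(old_root)
            old_root.remove_child(child)
            parent.add_child(child)
        self.root = node
        node.length = None
        return self

    def unroot(self) -> "PhyloTree":
        """Collapse a bifurcating storage root into a basal trifurcation."""
        while len(self.root.children) == 2 and self.n_taxa() > 2:
            a, b = self.root.children
            target = a if not a.is_leaf else b
            if target.is_leaf:
                break
            other = b if target is a else a
            self.root.remove_child(target)
            self.root.remove_child(other)
            other.length = (other.length or 0.0) + (target.length or 0.0)
            target.add_child(other)
            target.parent = None
            target.length = None
            self.root = target
        return self

    # -- serialization ------------------------------------------------------

    def to_newick(self, precision: int = 10) -> str:
        return write_newick(self, precision=precision)

    def __str__(self):  # pragma: no cover
        return self.to_newick()


def read_newick(text: str) -> PhyloTree:
    """Parse a Newick string into an unrooted :class:`PhyloTree`."""
    try:
        dt = dendropy.Tree.get(
            file=io.StringIO(text),
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises assorted error types
        raise TreeError(f"could not parse Newick: {exc}") from exc

    def convert(dnode) -> Node:
        n = Node(
            label=dnode.taxon.label if dnode.taxon is not None else None,
            length=dnode.edge.length,
        )
        for ch in dnode.child_nodes():
            n.add_child(convert(ch))
        return n

    root = convert(dt.seed_node)
    root.length = None
    tree = PhyloTree(root).unroot()
    labels = tree.taxa()
    if len(labels) != len(set(labels)):
        raise TreeError("duplicate taxon labels in tree")
    return tree


def write_newick(tree: PhyloTree, precision: int = 10) -> str:
    def fmt(n: Node) -> str:
        if n.is_leaf:
            body = n.label or ""
        else:
            body = "(" + ",".join(fmt(c) for c in n.children) + ")"
        if n.parent is not None and n.length is not None:
            body += f":{n.length:.{precision}g}"
        return body

    return fmt(tree.root) + ";"
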
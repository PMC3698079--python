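"""Phylogenetic tree container.

A deliberately small rooted-node structure (NJ trees are represented with
a trifurcating root) carrying branch lengths in expected substitutions
per codon site, optional clade labels on internal nodes, and per-branch
foreground flags for branch-site selection models.  Newick parsing goes
through dendropy; writing is direct.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy

from .errors import InputError, LookupError_


@dataclass
class Node:
    name: str | None = None
    length: float = 0.0  # length of the edge to the parent; 0.0 at the root
    children: list["Node"] = field(default_factory=list)
    label: str | None = None  # clade label (e.g. "AL7") or bootstrap support
    foreground: bool = False

    @property
    def is_leaf(self) -> bool:
        return not self.children


class PhyloTree:
    """Rooted tree with named leaves, branch lengths and clade labels."""

    def __init__(self, root: Node):
        self.root = root
        names = self.leaf_names
        if len(set(names)) != len(names):
            raise InputError("duplicate leaf names in tree")
        for node in self.postorder():
            if node is not self.root and not (node.length >= 0.0):
                raise InputError(f"negative or undefined branch length at {node.name or node.label}")

    # ---- traversal -------------------------------------------------

    def postorder(self):
        def walk(node):
            for c in node.children:
                yield from walk(c)
            yield node
        yield from walk(self.root)

    def preorder(self):
        def walk(node):
            yield node
            for c in node.children:
                yield from walk(c)
        yield from walk(self.root)

    @property
    def leaves(self) -> list[Node]:
        return [n for n in self.postorder() if n.is_leaf]

    @property
    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves]

    @property
    def n_branches(self) -> int:
        return sum(1 for n in self.postorder() if n is not self.root)

    def copy(self) -> "PhyloTree":
        def clone(node):
            return Node(
                name=node.name,
                length=node.length,
                children=[clone(c) for c in node.children],
                label=node.label,
                foreground=node.foreground,
            )
        return PhyloTree(clone(self.root))

    # ---- clades & foreground ---------------------------------------

    def find_clade(self, label: str) -> Node:
        for n in self.postorder():
            if n.label == label:
                return n
        raise LookupError_(f"no clade labeled {label!r}")

    @property
    def clade_labels(self) -> dict[str, list[str]]:
        """Map clade label -> leaf names under that node."""
        out = {}
        for n in self.postorder():
            if n.label is not None and not n.is_leaf:
                out[n.label] = [l.name for l in _leaves_under(n)]
        return out

    def mrca(self, names) -> Node:
        target = set(names)
        missing = target - set(self.leaf_names)
        if missing:
            raise LookupError_(f"leaves not in tree: {sorted(missing)}")
        best = None
        for n in self.postorder():
            under = {l.name for l in _leaves_under(n)}
            if target <= under and (best is None or len(under) < len(best[1])):
                best = (n, under)
        return best[0]

    def label_clade(self, names, label: str) -> Node:
        node = self.mrca(names)
        node.label = label
        return node

    def clear_foreground(self) -> None:
        for n in self.postorder():
            n.foreground = False

    def set_foreground_clade(self, label: str) -> None:
        """Mark a labeled clade's stem branch and all branches within it."""
        self.clear_foreground()
        node = self.find_clade(label)
        def mark(n):
            n.foreground = True
            for c in n.children:
                mark(c)
        mark(node)

    @property
    def foreground_branches(self) -> list[Node]:
        return [n for n in self.postorder() if n.foreground and n is not self.root]

    def prune_leaf(self, name: str) -> None:
        """Remove a leaf; its parent (if left unary) is collapsed into its child."""
        parent_of = {}
        for n in self.preorder():
            for c in n.children:
                parent_of[id(c)] = n
        leaf = next((l for l in self.leaves if l.name == name), None)
        if leaf is None:
            raise LookupError_(f"no leaf named {name!r}")
        parent = parent_of.get(id(leaf))
        if parent is None:
            raise InputError("cannot prune the only node of a tree")
        parent.children.remove(leaf)
        if len(parent.children) == 1 and parent is not self.root:
            child = parent.children[0]
            child.length += parent.length
            if child.label is None:  # keep e.g. a clade label on the merged edge
                child.label = parent.label
            child.foreground = child.foreground or parent.foreground
            grand = parent_of[id(parent)]
            grand.children[grand.children.index(parent)] = child
        elif len(parent.children) == 1 and parent is self.root:
            child = parent.children[0]
            child.length = 0.0
            self.root = child

    # ---- newick ----------------------------------------------------

    def to_newick(self, *, support_as_label: bool = True) -> str:
        def fmt(node):
            if node.is_leaf:
                return f"{node.name}:{node.length:.6g}"
            inner = ",".join(fmt(c) for c in node.children)
            lab = node.label if (node.label is not None and support_as_label) else ""
            if node is self.root:
                return f"({inner}){lab}"
            return f"({inner}){lab}:{node.length:.6g}"
        return fmt(self.root) + ";"

    @classmethod
    def from_newick(cls, newick: str) -> "PhyloTree":
        dt = dendropy.Tree.get(data=newick, schema="newick",
                               suppress_internal_node_taxa=True)

        def convert(dnode):
            node = Node(
                name=dnode.taxon.label.replace(" ", "_") if dnode.taxon else None,
                length=dnode.edge.length if dnode.edge.length is not None else 0.0,
                label=dnode.label,
            )
            node.children = [convert(c) for c in dnode.child_nodes()]
            return node

        return cls(convert(dt.seed_node))

    def __repr__(self):
        return f"PhyloTree({len(self.leaf_names)} leaves)"


def _leaves_under(node: Node) -> list[Node]:
    if node.is_leaf:
        return [node]
    out = []
    for c in node.children:
        out.extend(_leaves_under(c))
    return out
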
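"""Minimal rooted-tree structure for the fixed 5-taxon analyses.

The selection scan runs on one topology — dog outgroup, then human, then the
felid clade with cheetah sister to (cat, tiger).  Trees are parsed from / to
Newick through Bio.Phylo; internally a node is a plain dataclass so branch
attributes (length, omega) are easy to carry around.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from typing import Iterator

from Bio import Phylo

TAXA = ("cheetah", "cat", "tiger", "human", "dog")
DEFAULT_NEWICK = "(dog:1.0,(human:1.0,((cat:1.0,tiger:1.0)catstigers:1.0,cheetah:1.0)felids:1.0)boreo:1.0)root;"


@dataclass
class TreeNode:
    name: str
    length: float = 0.0
    omega: float | None = None
    children: list["TreeNode"] = field(default_factory=list)
    parent: "TreeNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def postorder(self) -> Iterator["TreeNode"]:
        for child in self.children:
            yield from child.postorder()
        yield self

    def preorder(self) -> Iterator["TreeNode"]:
        yield self
        for child in self.children:
            yield from child.preorder()

    def leaves(self) -> list["TreeNode"]:
        return [n for n in self.postorder() if n.is_leaf]

    def find(self, name: str) -> "TreeNode":
        for node in self.postorder():
            if node.name == name:
                return node
        raise KeyError(name)

    def branches(self) -> list["TreeNode"]:
        """All non-root nodes; each represents the branch above it."""
        return [n for n in self.postorder() if n.parent is not None]


def _convert(clade, parent: TreeNode | None, counter: list[int]) -> TreeNode:
    name = clade.name
    if not name:
        counter[0] += 1
        name = f"node{counter[0]}"
    node = TreeNode(name=name, length=float(clade.branch_length or 0.0),
                    parent=parent)
    for sub in clade.clades:
        node.children.append(_convert(sub, node, counter))
    return node


def from_newick(newick: str) -> TreeNode:
    tree = Phylo.read(_io.StringIO(newick), "newick")
    return _convert(tree.root, None, [0])


def to_newick(root: TreeNode) -> str:
    def fmt(node: TreeNode) -> str:
        if node.is_leaf:
            return f"{node.name}:{node.length:g}"
        inner = ",".join(fmt(c) for c in node.children)
        return f"({inner}){node.name}:{node.length:g}"

    inner = ",".join(fmt(c) for c in root.children)
    return f"({inner}){root.name};"


def five_taxon_tree(branch_length: float = 0.05,
                    omega: float | dict[str, float] = 0.2) -> TreeNode:
    """The fixed study tree with uniform branch lengths and per-branch omega.

    ``omega`` may be a scalar (applied to every branch) or a dict keyed by
    branch (child-node) name, e.g. ``{"cheetah": 2.0}`` with the rest at the
    scalar default 0.2.
    """
    root = from_newick(DEFAULT_NEWICK)
    for node in root.postorder():
        if node.parent is not None:
            node.length = branch_length
            if isinstance(omega, dict):
                node.omega = float(omega.get(node.name, 0.2))
            else:
                node.omega = float(omega)
    return root
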
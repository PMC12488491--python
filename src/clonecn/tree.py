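"""Rooted clone trees.

A tumour phylogeny is represented as a rooted tree whose root is the normal
diploid clone (ID ``"diploid"``) and whose single child is the most recent
common ancestor (MRCA) of all tumour cells.  Every other node is a tumour
clone, extant or extinct.  Edges point from parent to child and carry the
copy-number events that transform the parent profile into the child profile.
"""

from __future__ import annotations

import io as _io
from typing import Iterable

__all__ = ["CloneTree", "NORMAL_CLONE", "TreeError"]

#: reserved identifier of the normal diploid root clone
NORMAL_CLONE = "diploid"


class TreeError(ValueError):
    """Raised when an edge list does not describe a valid clone tree."""


class CloneTree:
    """A rooted clone phylogeny with a diploid root.

    Parameters
    ----------
    edges
        Ordered ``(parent, child)`` pairs.  Exactly one node must have no
        parent (the root), and the root must have exactly one child, the MRCA.
    root
        Identifier of the root clone.  Defaults to ``"diploid"``; if the edge
        list has a unique parentless node the argument is optional.
    """

    def __init__(self, edges: Iterable[tuple[str, str]], root: str | None = None):
        self._edges = [(str(p), str(c)) for p, c in edges]
        if not self._edges:
            raise TreeError("a clone tree needs at least one edge (root -> MRCA)")
        self._parent: dict[str, str] = {}
        self._children: dict[str, list[str]] = {}
        for p, c in self._edges:
            if c in self._parent:
                raise TreeError(f"clone {c!r} has more than one parent")
            if p == c:
                raise TreeError(f"self-loop on clone {p!r}")
            self._parent[c] = p
            self._children.setdefault(p, []).append(c)
            self._children.setdefault(c, [])
        roots = [n for n in self._children if n not in self._parent]
        if len(roots) != 1:
            raise TreeError(f"expected exactly one root, found {sorted(roots)}")
        self._root = roots[0]
        if root is not None and root != self._root:
            raise TreeError(f"declared root {root!r} but edge list roots at {self._root!r}")
        if len(self._children[self._root]) != 1:
            raise TreeError(
                "the diploid root must have exactly one child (the MRCA); "
                f"found {self._children[self._root]}"
            )
        # preorder traversal doubles as a cycle check
        order: list[str] = []
        stack = [self._root]
        while stack:
            node = stack.pop()
            order.append(node)
            stack.extend(reversed(self._children[node]))
        if len(order) != len(self._children):
            raise TreeError("edge list contains a cycle or disconnected component")
        self._preorder = order

    # -- basic accessors ---------------------------------------------------
    @property
    def root(self) -> str:
        return self._root

    @property
    def mrca(self) -> str:
        """The single child of the diploid root."""
        return self._children[self._root][0]

    @property
    def edges(self) -> list[tuple[str, str]]:
        return list(self._edges)

    @property
    def nodes(self) -> list[str]:
        """All clones in preorder (root first)."""
        return list(self._preorder)

    @property
    def tumour_clones(self) -> list[str]:
        """All clones except the normal root, in preorder."""
        return [n for n in self._preorder if n != self._root]

    def parent(self, node: str) -> str | None:
        if node == self._root:
            return None
        try:
            return self._parent[node]
        except KeyError:
            raise KeyError(f"unknown clone {node!r}") from None

    def children(self, node: str) -> list[str]:
        return list(self._children[node])

    def descendants(self, node: str) -> list[str]:
        """Strict descendants of ``node`` in preorder."""
        out: list[str] = []
        stack = list(self._children[node])
        while stack:
            n = stack.pop()
            out.append(n)
            stack.extend(self._children[n])
        return out

    def ancestors(self, node: str) -> list[str]:
        """Ancestors from parent up to the root."""
        out = []
        p = self.parent(node)
        while p is not None:
            out.append(p)
            p = self.parent(p)
        return out

    def path_from_root(self, node: str) -> list[str]:
        return list(reversed(self.ancestors(node))) + [node]

    def __contains__(self, node: str) -> bool:
        return node in self._children

    def __len__(self) -> int:
        return len(self._children)

    def __eq__(self, other) -> bool:
        return isinstance(other, CloneTree) and sorted(self._edges) == sorted(other._edges)

    def __repr__(self) -> str:
        return f"CloneTree(n_clones={len(self) - 1}, root={self._root!r})"

    # -- construction helpers ---------------------------------------------
    @classmethod
    def from_newick(cls, newick: str, root: str | None = None) -> "CloneTree":
        """Build a tree from a Newick string with named internal nodes."""
        from Bio import Phylo

        phylo = Phylo.read(_io.StringIO(newick), "newick")
        edges: list[tuple[str, str]] = []

        def walk(clade):
            for child in clade.clades:
                if clade.name is None or child.name is None:
                    raise TreeError("Newick clone trees require every node to be named")
                edges.append((clade.name, child.name))
                walk(child)

        walk(phylo.root)
        return cls(edges, root=root)

    def to_newick(self) -> str:
        def render(node: str) -> str:
            kids = self._children[node]
            if not kids:
                return node
            return "(" + ",".join(render(k) for k in kids) + ")" + node

        return render(self._root) + ";"
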
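"""Rooted phylogenetic trees with named internal nodes.

Newick parsing is delegated to :mod:`dendropy`; the in-memory structure is a
minimal rooted tree tuned for the event-mapping operations (preorder walks,
MRCA queries, leaf sets).  Unlabeled internal nodes are auto-named ``N1``,
``N2``, ... in preorder so that reports are reproducible.
"""

from __future__ import annotations

from typing import Iterator, Sequence

import dendropy


class TreeError(ValueError):
    """Raised for malformed or inconsistent trees."""


class Node:
    __slots__ = ("name", "parent", "children")

    def __init__(self, name: str | None = None, parent: "Node | None" = None) -> None:
        self.name = name
        self.parent = parent
        self.children: list[Node] = []

    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover
        return f"Node({self.name!r})"


class PhyloTree:
    """A rooted tree whose every node carries a unique label."""

    def __init__(self, root: Node) -> None:
        self.root = root
        self._autoname()
        self._index: dict[str, Node] = {}
        for node in self.preorder():
            if node.name in self._index:
                raise TreeError(f"duplicate node label {node.name!r}")
            self._index[node.name] = node
        self.tips: list[str] = [n.name for n in self.preorder() if n.is_leaf()]

    # -- construction -----------------------------------------------------
    @classmethod
    def from_newick(cls, text: str) -> "PhyloTree":
        try:
            dtree = dendropy.Tree.get(
                data=text,
                schema="newick",
                suppress_internal_node_taxa=True,
            )
        except Exception as exc:
            raise TreeError(f"newick parse error: {exc}") from None

        def convert(dnode: dendropy.Node, parent: Node | None) -> Node:
            label = None
            if dnode.taxon is not None and dnode.taxon.label:
                label = str(dnode.taxon.label)
            elif dnode.label:
                label = str(dnode.label)
            node = Node(label, parent)
            for child in dnode.child_nodes():
                node.children.append(convert(child, node))
            return node

        root = convert(dtree.seed_node, None)
        if root.is_leaf():
            raise TreeError("tree has no internal structure")
        return cls(root)

    def _autoname(self) -> None:
        used = {n.name for n in self.preorder() if n.name}
        counter = 1
        for node in self.preorder():
            if node.is_leaf():
                if not node.name:
                    raise TreeError("unlabeled tip")
            elif not node.name:
                while f"N{counter}" in used:
                    counter += 1
                node.name = f"N{counter}"
                used.add(node.name)
                counter += 1

    # -- traversal --------------------------------------------------------
    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator[Node]:
        out: list[Node] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        yield from reversed(out)

    # -- queries ----------------------------------------------------------
    def __contains__(self, name: str) -> bool:
        return name in self._index

    def node(self, name: str) -> Node:
        try:
            return self._index[name]
        except KeyError:
            raise TreeError(f"unknown node {name!r}") from None

    def is_tip(self, name: str) -> bool:
        return self.node(name).is_leaf()

    def parent(self, name: str) -> str | None:
        p = self.node(name).parent
        return p.name if p is not None else None

    def children(self, name: str) -> list[str]:
        return [c.name for c in self.node(name).children]

    def path_from_root(self, name: str) -> list[str]:
        """Node labels from the root down to (and including) *name*."""
        path: list[str] = []
        node: Node | None = self.node(name)
        while node is not None:
            path.append(node.name)  # type: ignore[arg-type]
            node = node.parent
        return path[::-1]

    def leaves_under(self, name: str) -> list[str]:
        node = self.node(name)
        if node.is_leaf():
            return [node.name]  # type: ignore[list-item]
        out: list[str] = []
        stack = [node]
        while stack:
            n = stack.pop()
            if n.is_leaf():
                out.append(n.name)  # type: ignore[arg-type]
            else:
                stack.extend(reversed(n.children))
        return out

    def mrca(self, names: Sequence[str]) -> str:
        if not names:
            raise TreeError("mrca of empty set")
        paths = [self.path_from_root(n) for n in names]
        shortest = min(len(p) for p in paths)
        anc = self.root.name
        for depth in range(shortest):
            level = {p[depth] for p in paths}
            if len(level) == 1:
                anc = level.pop()
            else:
                break
        return anc  # type: ignore[return-value]

    def is_strict_ancestor(self, ancestor: str, descendant: str) -> bool:
        if ancestor == descendant:
            return False
        return ancestor in self.path_from_root(descendant)[:-1]

    def branches(self) -> list[tuple[str, str]]:
        """(parent, child) label pairs in preorder; the root has no branch."""
        return [
            (n.parent.name, n.name)  # type: ignore[misc]
            for n in self.preorder()
            if n.parent is not None
        ]

    # -- output -----------------------------------------------------------
    def to_newick(self) -> str:
        def render(node: Node) -> str:
            if node.is_leaf():
                return str(node.name)
            inner = ",".join(render(c) for c in node.children)
            return f"({inner}){node.name}"

        return render(self.root) + ";"

    def __repr__(self) -> str:  # pragma: no cover
        return f"PhyloTree({len(self.tips)} tips, root={self.root.name!r})"
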
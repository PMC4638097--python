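"""Minimal phylogenetic tree container: nodes, Newick output, bipartitions, rooting.

Trees built by the distance methods in :mod:`clonetrace.phylo` are stored as
plain node hierarchies.  An "unrooted" tree is represented with an arbitrary
(typically trifurcating) root; all topology comparisons go through leaf
bipartitions, which are invariant to that choice.
"""

from __future__ import annotations

from typing import Iterator, Optional


class Node:
    """One tree node; ``length`` and ``support`` describe the edge above it."""

    __slots__ = ("name", "length", "support", "children")

    def __init__(
        self,
        name: Optional[str] = None,
        length: float = 0.0,
        children: Optional[list["Node"]] = None,
        support: Optional[float] = None,
    ):
        self.name = name
        self.length = float(length)
        self.support = support
        self.children = children if children is not None else []

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def walk(self) -> Iterator["Node"]:
        """Pre-order traversal."""
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.walk() if n.is_leaf]

    def find_leaf(self, name: str) -> Optional["Node"]:
        for n in self.walk():
            if n.is_leaf and n.name == name:
                return n
        return None

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"<Node {self.name or '*'} len={self.length:.3g} n_child={len(self.children)}>"

    # -- serialisation -------------------------------------------------

    def newick(self, include_support: bool = True, support_digits: int = 0) -> str:
        """Newick string, branch lengths always written, supports as internal labels."""
        return _newick(self, include_support, support_digits, top=True) + ";"


def _newick(node: Node, include_support: bool, digits: int, top: bool = False) -> str:
    if node.is_leaf:
        body = node.name or ""
    else:
        inner = ",".join(_newick(c, include_support, digits) for c in node.children)
        label = ""
        if include_support and node.support is not None:
            label = f"{node.support:.{digits}f}" if digits else f"{round(node.support):d}"
        body = f"({inner}){label}"
    if top:
        return body
    return f"{body}:{node.length:.10g}"


def bipartitions(root: Node) -> dict[frozenset, Node]:
    """Non-trivial leaf bipartitions of the (possibly unrooted) tree.

    Each internal edge is keyed by the canonical side of its split: the side
    not containing the lexicographically smallest leaf.  Maps to the child
    node below the edge (the node whose ``support`` slot annotates it).
    """
    all_leaves = frozenset(root.leaf_names())
    anchor = min(all_leaves)
    out: dict[frozenset, Node] = {}

    def below(node: Node) -> frozenset:
        if node.is_leaf:
            return frozenset([node.name])
        leaves = frozenset().union(*(below(c) for c in node.children))
        if node is not root:
            side = all_leaves - leaves if anchor in leaves else leaves
            if 1 < len(side) < len(all_leaves) - 1:
                # root edges of a bifurcating root map to one split; keep first
                out.setdefault(side, node)
        return leaves

    below(root)
    return out


def clade_leafsets(root: Node) -> dict[Node, frozenset]:
    """Map every node of a rooted tree to the set of leaf names below it."""
    out: dict[Node, frozenset] = {}

    def rec(node: Node) -> frozenset:
        s = frozenset([node.name]) if node.is_leaf else frozenset().union(
            *(rec(c) for c in node.children)
        )
        out[node] = s
        return s

    rec(root)
    return out


def _adjacency(root: Node):
    """Edge list view of the tree: node -> [(neighbour, length, support)]."""
    adj: dict[int, list] = {}
    nodes: dict[int, Node] = {}

    def add(a: Node, b: Node, length: float, support):
        adj.setdefault(id(a), []).append((b, length, support))
        adj.setdefault(id(b), []).append((a, length, support))
        nodes[id(a)] = a
        nodes[id(b)] = b

    def rec(node: Node):
        for c in node.children:
            add(node, c, c.length, c.support)
            rec(c)

    rec(node=root)
    nodes.setdefault(id(root), root)
    adj.setdefault(id(root), [])
    return adj, nodes


def root_on_leaf_edge(root: Node, leaf_name: str, fraction: float = 0.5) -> Node:
    """Re-root the tree on the edge leading to ``leaf_name`` (outgroup rooting).

    The new root splits that terminal edge, ``fraction`` of its length on the
    outgroup side.  Edge lengths and supports elsewhere are preserved (supports
    annotate bipartitions, which rooting does not change).
    """
    leaf = root.find_leaf(leaf_name)
    if leaf is None:
        raise ValueError(f"no leaf named {leaf_name!r} to root on")
    if len(root.children) == 2 and any(
        c.is_leaf and c.name == leaf_name for c in root.children
    ):
        return copy_tree(root)  # already rooted on this edge: idempotent
    adj, _ = _adjacency(root)

    def hang(node: Node, parent: Node, length: float, support) -> Node:
        new = Node(node.name, length, support=support)
        for nb, ln, sup in adj[id(node)]:
            if nb is not parent:
                new.children.append(hang(nb, node, ln, sup))
        return new

    (neigh, total_len, support) = adj[id(leaf)][0]
    new_root = Node(None)
    out = Node(leaf_name, total_len * fraction)
    ingroup = hang(neigh, leaf, total_len * (1.0 - fraction), support)
    new_root.children = [out, ingroup]
    # degree-2 nodes can appear where the old root had only two neighbours left
    _suppress_unifurcations(new_root)
    return new_root


def copy_tree(root: Node) -> Node:
    new = Node(root.name, root.length, support=root.support)
    new.children = [copy_tree(c) for c in root.children]
    return new


def _suppress_unifurcations(root: Node) -> None:
    changed = True
    while changed:
        changed = False
        for node in list(root.walk()):
            i = 0
            while i < len(node.children):
                c = node.children[i]
                if not c.is_leaf and len(c.children) == 1:
                    gc = c.children[0]
                    gc.length += c.length
                    if gc.support is None:
                        gc.support = c.support
                    node.children[i] = gc
                    changed = True
                else:
                    i += 1
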
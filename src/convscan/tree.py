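"""Rooted phylogenetic trees with stable branch identifiers.

Trees are stored as a light node structure so that downstream code (scenario
construction, per-column tree pruning, the pruning likelihood) can traverse
and rebuild them cheaply.  Newick text is parsed and validated through
dendropy; the parsed tree is converted into :class:`Tree` with deterministic
node ids: tips and labelled internal nodes keep their labels, unlabelled
internal nodes are named ``n<postorder index>`` (0-based, counting all nodes
in postorder).  The id of a node doubles as the id of the branch above it.
"""

from __future__ import annotations

import io as _io
from typing import Callable, Iterable, Iterator, Sequence

import dendropy
import numpy as np

__all__ = [
    "TreeError",
    "Node",
    "Tree",
    "parse_newick",
    "write_newick",
    "prune_to_tips",
    "random_bifurcating_tree",
    "balanced_tree",
]


class TreeError(ValueError):
    """Raised for malformed Newick input or invalid tree operations."""


class Node:
    __slots__ = ("id", "label", "length", "parent", "children", "generated_id")

    def __init__(self, label=None, length=None):
        self.id: str | None = None
        self.label: str | None = label
        self.length: float | None = length
        self.parent: "Node" | None = None
        self.children: list["Node"] = []
        # True when the id was synthesised (so Newick output omits it)
        self.generated_id: bool = False

    @property
    def is_tip(self) -> bool:
        return not self.children

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"<Node {self.id!r} len={self.length}>"


class Tree:
    """A rooted tree; ``nodes`` maps id -> Node, in postorder insertion order."""

    def __init__(self, root: Node):
        self.root = root
        self._assign_ids()

    # -- construction ---------------------------------------------------
    def _assign_ids(self) -> None:
        nodes: dict[str, Node] = {}
        for idx, node in enumerate(self._postorder_nodes(self.root)):
            if node.is_tip:
                if not node.label:
                    raise TreeError("tip with empty label")
                node.id = node.label
            elif node.label:
                node.id = node.label
            else:
                node.id = f"n{idx}"
                node.generated_id = True
            if node.id in nodes:
                raise TreeError(f"duplicate node id {node.id!r}")
            nodes[node.id] = node
        self.nodes = nodes

    @staticmethod
    def _postorder_nodes(root: Node) -> Iterator[Node]:
        stack: list[tuple[Node, bool]] = [(root, False)]
        while stack:
            node, done = stack.pop()
            if done:
                yield node
            else:
                stack.append((node, True))
                for child in reversed(node.children):
                    stack.append((child, False))

    # -- traversal ------------------------------------------------------
    def postorder(self) -> Iterator[Node]:
        return self._postorder_nodes(self.root)

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def tips(self) -> list[Node]:
        return [n for n in self.postorder() if n.is_tip]

    def tip_labels(self) -> list[str]:
        return [n.label for n in self.tips()]

    @property
    def n_tips(self) -> int:
        return sum(1 for _ in self.tips())

    def __getitem__(self, node_id: str) -> Node:
        return self.nodes[node_id]

    def __contains__(self, node_id: str) -> bool:
        return node_id in self.nodes

    def total_branch_length(self) -> float:
        return sum(n.length or 0.0 for n in self.postorder() if n.parent is not None)

    def height(self) -> float:
        """Maximum root-to-tip path length."""
        depth = {id(self.root): 0.0}
        best = 0.0
        for node in self.preorder():
            if node.parent is not None:
                depth[id(node)] = depth[id(node.parent)] + (node.length or 0.0)
                if node.is_tip:
                    best = max(best, depth[id(node)])
        return best

    def copy(self) -> "Tree":
        def clone(node: Node) -> Node:
            new = Node(node.label, node.length)
            for child in node.children:
                new.add_child(clone(child))
            return new

        return Tree(clone(self.root))

    def newick(self) -> str:
        return write_newick(self)

    def __repr__(self):  # pragma: no cover
        return f"<Tree {self.n_tips} tips>"


# ---------------------------------------------------------------------------
# Newick I/O


def _convert_dendropy(dnode, default_length: float) -> Node:
    label = None
    if dnode.taxon is not None:
        label = dnode.taxon.label
    elif dnode.label:
        label = dnode.label
    length = dnode.edge.length
    node = Node(label=label, length=length)
    for child in dnode.child_nodes():
        node.add_child(_convert_dendropy(child, default_length))
    return node


def parse_newick(text: str, default_length: float = 1.0) -> Tree:
    """Parse a single rooted Newick statement into a :class:`Tree`.

    Missing branch lengths on non-root edges default to ``default_length``;
    the root edge length is dropped.  Negative branch lengths and duplicate
    tip labels are rejected.
    """
    text = text.strip()
    if not text.endswith(";"):
        raise TreeError("Newick statement must end with ';'")
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise TreeError(f"Newick parse error: {exc}") from exc

    root = _convert_dendropy(dtree.seed_node, default_length)
    root.length = None
    # fill defaults / validate lengths
    labels_seen: set[str] = set()

    def visit(node: Node) -> None:
        if node.parent is not None:
            if node.length is None:
                node.length = default_length
            if node.length < 0:
                name = node.label or "(internal)"
                raise TreeError(
                    f"negative branch length {node.length} on edge above {name}"
                )
        if node.is_tip:
            if not node.label:
                raise TreeError("tip with empty label")
            if node.label in labels_seen:
                raise TreeError(f"duplicate tip label {node.label!r}")
            labels_seen.add(node.label)
        for child in node.children:
            visit(child)

    visit(root)
    if len(labels_seen) < 2:
        raise TreeError("tree must have at least 2 tips")
    return Tree(root)


def _fmt_length(x: float) -> str:
    return format(x, ".12g")


def write_newick(tree: Tree) -> str:
    """Serialise a tree back to Newick; generated internal ids are omitted."""

    def render(node: Node) -> str:
        if node.is_tip:
            body = node.label
        else:
            inner = ",".join(render(c) for c in node.children)
            label = "" if node.generated_id or node.label is None else node.label
            body = f"({inner}){label}"
        if node.parent is not None and node.length is not None:
            return f"{body}:{_fmt_length(node.length)}"
        return body

    return render(tree.root) + ";"


# ---------------------------------------------------------------------------
# Pruning


def prune_to_tips(tree: Tree, keep: Iterable[str]) -> Tree:
    """Restrict the tree to the tips in ``keep``.

    Unary internal nodes are suppressed with branch lengths summed, so path
    lengths between retained tips are preserved.  The new root is the MRCA of
    the retained tips.  Retained nodes keep their original ids.
    """
    keep = set(keep)
    missing = keep - set(tree.tip_labels())
    if missing:
        raise TreeError(f"tips not in tree: {sorted(missing)}")
    if len(keep) < 1:
        raise TreeError("no tips to keep")

    def build(node: Node) -> Node | None:
        if node.is_tip:
            if node.label in keep:
                new = Node(node.label, node.length)
                new.id = node.id
                return new
            return None
        kept = [c for c in (build(ch) for ch in node.children) if c is not None]
        if not kept:
            return None
        if len(kept) == 1:
            # suppress this node: fold its branch into the surviving child
            child = kept[0]
            if node.parent is not None:
                child.length = (child.length or 0.0) + (node.length or 0.0)
            return child
        new = Node(node.label, node.length)
        new.id = node.id
        new.generated_id = node.generated_id
        for c in kept:
            new.add_child(c)
        return new

    new_root = build(tree.root)
    if new_root is None:
        raise TreeError("pruning removed all tips")
    new_root.length = None
    new_root.parent = None
    pruned = Tree.__new__(Tree)
    pruned.root = new_root
    # keep original ids (already set on retained nodes)
    nodes: dict[str, Node] = {}
    for node in Tree._postorder_nodes(new_root):
        nodes[node.id] = node
    pruned.nodes = nodes
    return pruned


# ---------------------------------------------------------------------------
# Synthetic topologies (used by the simulator, tests and benchmarks)


def random_bifurcating_tree(
    n_tips: int,
    rng: np.random.Generator,
    length_sampler: Callable[[np.random.Generator], float] | None = None,
    prefix: str = "t",
) -> Tree:
    """Random rooted bifurcating topology via random sequential joins.

    Branch lengths are drawn i.i.d. from ``length_sampler`` (default
    Uniform(0.05, 1.0)).
    """
    if n_tips < 2:
        raise TreeError("need at least 2 tips")
    if length_sampler is None:
        length_sampler = lambda g: float(g.uniform(0.05, 1.0))
    lineages = [Node(f"{prefix}{i}") for i in range(n_tips)]
    for node in lineages:
        node.length = length_sampler(rng)
    while len(lineages) > 1:
        i, j = sorted(rng.choice(len(lineages), size=2, replace=False))
        a = lineages.pop(j)
        b = lineages.pop(i)
        parent = Node(length=length_sampler(rng))
        parent.add_child(b)
        parent.add_child(a)
        lineages.append(parent)
    root = lineages[0]
    root.length = None
    return Tree(root)


def balanced_tree(depth: int, branch_length: float = 0.3, prefix: str = "t") -> Tree:
    """Fully balanced bifurcating tree with 2**depth tips, equal branch lengths."""
    counter = [0]

    def build(d: int) -> Node:
        if d == 0:
            node = Node(f"{prefix}{counter[0]}", branch_length)
            counter[0] += 1
            return node
        node = Node(length=branch_length)
        node.add_child(build(d - 1))
        node.add_child(build(d - 1))
        return node

    root = build(depth)
    root.length = None
    return Tree(root)
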
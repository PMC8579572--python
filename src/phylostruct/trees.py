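"""Rooted phylogenies with deme labels and explicit migration nodes.

A tree from a structured host population carries, on every node, the label of
the sub-population (deme) the lineage belonged to at that point.  A migration
event is rendered as a *unifurcating* node: a node with exactly one child whose
deme differs from its own.  Trees from a non-structured population are plain
binary birth-death trees with a constant deme label.

All traversals are iterative so that deeply ladderised trees (depth close to
the tip count) never hit the interpreter recursion limit.
"""

from __future__ import annotations

from typing import Iterator, Optional


class Node:
    """A node of a rooted phylogeny.

    Attributes
    ----------
    parent : Node or None
    children : list of Node (0 for tips, 1 for migration nodes, 2 otherwise)
    edge_length : float
        Length of the edge above this node, in model time units (>= 0).
    deme : int
        Sub-population label (1-based; constant over non-structured trees).
    is_migration : bool
        True for the unifurcating colour-change node created by a migration
        event; its single child carries a different deme label.
    label : str or None
        Tip name or internal-node name.
    alive : bool
        Simulator bookkeeping: False marks a lineage terminated by a death
        event, removed by :func:`phylostruct.simulate.prune_extinct_lineages`.
    """

    __slots__ = ("parent", "children", "edge_length", "deme", "is_migration",
                 "label", "alive", "t0")

    def __init__(self, deme: int = 1, edge_length: float = 0.0,
                 label: Optional[str] = None, is_migration: bool = False):
        self.parent: Optional[Node] = None
        self.children: list[Node] = []
        self.edge_length = float(edge_length)
        self.deme = deme
        self.is_migration = is_migration
        self.label = label
        self.alive = True
        self.t0 = 0.0  # birth time of the edge above (simulator use only)

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        kind = "tip" if self.is_leaf else ("migration" if self.is_migration
                                           else "internal")
        return f"<Node {self.label or ''} {kind} deme={self.deme}>"


class Phylogeny:
    """A rooted tree plus free-form metadata (label, seed, termination rule)."""

    def __init__(self, root: Node, metadata: Optional[dict] = None):
        self.root = root
        self.metadata: dict = dict(metadata or {})

    # -- traversals ---------------------------------------------------------

    def iter_preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            # reversed keeps left-to-right order for callers that care
            stack.extend(reversed(node.children))

    def iter_postorder(self) -> Iterator[Node]:
        stack: list[tuple[Node, bool]] = [(self.root, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded:
                yield node
            else:
                stack.append((node, True))
                stack.extend((c, False) for c in reversed(node.children))

    def leaves(self) -> list[Node]:
        return [n for n in self.iter_preorder() if n.is_leaf]

    @property
    def n_tips(self) -> int:
        return sum(1 for n in self.iter_preorder() if n.is_leaf)

    def internal_nodes(self) -> list[Node]:
        return [n for n in self.iter_preorder() if not n.is_leaf]

    @property
    def n_migration_nodes(self) -> int:
        return sum(1 for n in self.iter_preorder() if n.is_migration)

    def depths(self) -> dict[Node, int]:
        """Edge-count depth of every node (root = 0); migration edges count."""
        out: dict[Node, int] = {self.root: 0}
        for node in self.iter_preorder():
            if node is not self.root:
                out[node] = out[node.parent] + 1
        return out

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        """Check structural invariants; raise ``ValueError`` on violation."""
        n_tips = 0
        n_internal = 0
        has_migration = False
        for node in self.iter_preorder():
            if node.edge_length < 0:
                raise ValueError("negative branch length")
            k = len(node.children)
            if k > 2:
                raise ValueError("node with more than two children")
            if node.is_migration:
                has_migration = True
                if k != 1:
                    raise ValueError("migration node without exactly one child")
                if node.children[0].deme == node.deme:
                    raise ValueError("migration node child in the same deme")
            if k == 0:
                n_tips += 1
            else:
                n_internal += 1
            for child in node.children:
                if child.parent is not node:
                    raise ValueError("broken parent link")
        if n_tips >= 2:
            if has_migration:
                if n_internal < n_tips - 1:
                    raise ValueError("structured tree with too few internal nodes")
            elif n_internal != n_tips - 1:
                raise ValueError(
                    f"binary tree with {n_tips} tips must have {n_tips - 1} "
                    f"internal nodes, found {n_internal}")


# ---------------------------------------------------------------------------
# Small constructors used in documentation, examples and tests
# ---------------------------------------------------------------------------

def worked_example_tree() -> Phylogeny:
    """The five-tip structured tree used as the worked example.

    Newick ``(((1,2)E)B,(3,(4,5)D)C)A;`` where ``B`` is a migration node:
    lineage B switches deme, so its single child E (and the cherry 1,2 below
    it) carries the other colour.  Branch lengths are arbitrary (statistics
    are purely topological).
    """
    a = Node(deme=1, label="A")
    b = a.add_child(Node(deme=1, label="B", is_migration=True, edge_length=1.0))
    c = a.add_child(Node(deme=1, label="C", edge_length=1.0))
    e = b.add_child(Node(deme=2, label="E", edge_length=1.0))
    e.add_child(Node(deme=2, label="1", edge_length=1.0))
    e.add_child(Node(deme=2, label="2", edge_length=1.0))
    c.add_child(Node(deme=1, label="3", edge_length=1.0))
    d = c.add_child(Node(deme=1, label="D", edge_length=1.0))
    d.add_child(Node(deme=1, label="4", edge_length=1.0))
    d.add_child(Node(deme=1, label="5", edge_length=1.0))
    tree = Phylogeny(a, metadata={"label": "structured", "source": "worked-example"})
    tree.validate()
    return tree


def caterpillar_tree(n_tips: int) -> Phylogeny:
    """Fully imbalanced (ladder) binary tree with ``n_tips`` tips."""
    if n_tips < 2:
        raise ValueError("need at least two tips")
    root = Node(label="i1")
    node = root
    for i in range(n_tips - 2):
        node.add_child(Node(label=str(n_tips - i), edge_length=1.0))
        node = node.add_child(Node(label=f"i{i + 2}", edge_length=1.0))
    node.add_child(Node(label="2", edge_length=1.0))
    node.add_child(Node(label="1", edge_length=1.0))
    return Phylogeny(root)


def balanced_tree(depth: int) -> Phylogeny:
    """Fully balanced binary tree with ``2**depth`` tips."""
    root = Node()
    frontier = [root]
    for _ in range(depth):
        nxt = []
        for node in frontier:
            nxt.append(node.add_child(Node(edge_length=1.0)))
            nxt.append(node.add_child(Node(edge_length=1.0)))
        frontier = nxt
    for i, leaf in enumerate(frontier, start=1):
        leaf.label = str(i)
    return Phylogeny(root)
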
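"""Tree-shape statistics for structured and non-structured phylogenies.

Eight topological statistics are computed per tree: number of cherries,
Sackin index, Colless index, total cophenetic index, ladder length, maximum
depth, maximum width and the width-to-depth ratio, plus normalised versions
of the first three.  All are invariant to branch lengths and child order.

Migration nodes (unifurcating colour-change nodes of structured trees)
follow fixed conventions:

* depth-type statistics (Sackin, maximum depth, maximum width, cophenetic
  LCA depth) count migration nodes and their edges;
* balance-type statistics (cherries, Colless) treat migration nodes as
  transparent pass-throughs: they contribute nothing and simply forward the
  subtended leaf count;
* the ladder counts nodes having exactly one *leaf* child, so a migration
  node whose single child is internal never extends a ladder.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import pandas as pd

from .trees import Node, Phylogeny

__all__ = [
    "TreeShapeStatistics", "count_cherries", "sackin_index", "colless_index",
    "total_cophenetic_index", "ladder_length", "max_depth", "max_width",
    "width_depth_ratio", "normalise_statistics", "compute_statistics_record",
    "statistics_table", "STATISTIC_COLUMNS", "FEATURE_COLUMNS",
]

#: column order of the per-tree statistics table
STATISTIC_COLUMNS = [
    "n_cherries", "sackin", "colless", "total_cophenetic", "ladder_length",
    "max_depth", "max_width", "width_depth_ratio",
    "cherries_norm", "sackin_norm", "colless_norm",
]

#: the eight-statistic feature vector used for classification
FEATURE_COLUMNS = [
    "cherries_norm", "sackin_norm", "colless_norm", "total_cophenetic",
    "ladder_length", "max_width", "max_depth", "width_depth_ratio",
]


@dataclass(frozen=True)
class TreeShapeStatistics:
    n_tips: int
    n_cherries: int
    sackin: int
    colless: int
    total_cophenetic: int
    ladder_length: float
    max_depth: int
    max_width: int
    width_depth_ratio: float
    cherries_norm: float
    sackin_norm: float
    colless_norm: float

    def as_dict(self) -> dict:
        return asdict(self)


def _leaf_counts(tree: Phylogeny) -> dict[Node, int]:
    counts: dict[Node, int] = {}
    for node in tree.iter_postorder():
        counts[node] = 1 if node.is_leaf else sum(counts[c] for c in node.children)
    return counts


def _resolve(node: Node) -> Node:
    """Skip transparent migration unifurcations below ``node``."""
    while node.is_migration and len(node.children) == 1:
        node = node.children[0]
    return node


def count_cherries(tree: Phylogeny) -> int:
    """Internal nodes whose two children (migration nodes skipped) are leaves."""
    if tree.n_tips < 2:
        raise ValueError("cherries undefined for fewer than two tips")
    count = 0
    for node in tree.iter_preorder():
        if len(node.children) == 2:
            if all(_resolve(c).is_leaf for c in node.children):
                count += 1
    return count


def sackin_index(tree: Phylogeny) -> int:
    """Sum over leaves of the edge count from leaf to root (migration edges
    included)."""
    depths = tree.depths()
    return sum(d for node, d in depths.items() if node.is_leaf)


def colless_index(tree: Phylogeny) -> int:
    """Sum over bifurcations of |leaves(left) - leaves(right)|.

    Migration nodes are transparent (contribute 0, pass the leaf count
    through); a node with more than two children is rejected.
    """
    counts = _leaf_counts(tree)
    total = 0
    for node in tree.iter_preorder():
        k = len(node.children)
        if k > 2:
            raise ValueError("non-binary tree")
        if k == 2:
            left, right = node.children
            total += abs(counts[left] - counts[right])
    return total


def total_cophenetic_index(tree: Phylogeny) -> int:
    """Sum over unordered tip pairs of the edge-depth of their LCA.

    Computed via the identity sum_pairs depth(LCA) = sum over non-root nodes
    v of C(k_v, 2) where k_v is the number of leaves below v: each non-root
    node on the root-to-LCA path contributes one unit of depth for every
    tip pair whose LCA lies at or below it.  Migration nodes count like any
    other node, deepening the LCA of the pairs beneath them.
    """
    counts = _leaf_counts(tree)
    return sum(k * (k - 1) // 2
               for node, k in counts.items() if node is not tree.root)


def ladder_length(tree: Phylogeny) -> float:
    """Longest chain of connected internal nodes each having exactly one leaf
    child, divided by the number of tips."""
    n = tree.n_tips
    if n < 1:
        raise ValueError("empty tree")
    qualifies = {node: sum(c.is_leaf for c in node.children) == 1
                 for node in tree.iter_preorder() if not node.is_leaf}
    chain: dict[Node, int] = {}
    best = 0
    for node in tree.iter_postorder():
        if node.is_leaf or not qualifies[node]:
            continue
        below = max((chain[c] for c in node.children
                     if not c.is_leaf and qualifies.get(c)), default=0)
        chain[node] = 1 + below
        best = max(best, chain[node])
    return best / n


def max_depth(tree: Phylogeny) -> int:
    """Largest root-to-leaf edge count (migration edges included)."""
    depths = tree.depths()
    return max(d for node, d in depths.items() if node.is_leaf)


def max_width(tree: Phylogeny) -> int:
    """Largest number of nodes (tips, bifurcations and migration nodes alike)
    found at any single edge-depth."""
    per_depth: dict[int, int] = {}
    for d in tree.depths().values():
        per_depth[d] = per_depth.get(d, 0) + 1
    return max(per_depth.values())


def width_depth_ratio(tree: Phylogeny) -> float:
    depth = max_depth(tree)
    if depth == 0:
        raise ValueError("single-tip tree has zero depth")
    return max_width(tree) / depth


def normalise_statistics(n_cherries: int, sackin: int, colless: int,
                         n_tips: int) -> tuple[float, float, float]:
    """Normalised cherries, Sackin and Colless.

    cherries / (n/2); Sackin / (0.5 n (n+1) - 1) [caterpillar maximum];
    Colless / ((n-1)(n-2)/2) [caterpillar maximum, needs n >= 3].
    """
    if n_tips < 3:
        raise ValueError("Colless normalisation needs at least three tips")
    return (n_cherries / (n_tips / 2),
            sackin / (0.5 * n_tips * (n_tips + 1) - 1),
            colless / ((n_tips - 1) * (n_tips - 2) / 2))


def compute_statistics_record(tree: Phylogeny) -> TreeShapeStatistics:
    """All eleven statistics of one tree, mutually consistent."""
    n = tree.n_tips
    cherries = count_cherries(tree)
    sackin = sackin_index(tree)
    colless = colless_index(tree)
    depth = max_depth(tree)
    width = max_width(tree)
    ch_n, sa_n, co_n = normalise_statistics(cherries, sackin, colless, n)
    return TreeShapeStatistics(
        n_tips=n, n_cherries=cherries, sackin=sackin, colless=colless,
        total_cophenetic=total_cophenetic_index(tree),
        ladder_length=ladder_length(tree),
        max_depth=depth, max_width=width, width_depth_ratio=width / depth,
        cherries_norm=ch_n, sackin_norm=sa_n, colless_norm=co_n)


def statistics_table(trees, labels=None, tree_ids=None) -> pd.DataFrame:
    """Per-tree statistics table: tree_id, label, n_tips + 11 statistics."""
    trees = list(trees)
    if labels is None:
        labels = [t.metadata.get("label", "") for t in trees]
    if tree_ids is None:
        tree_ids = [t.metadata.get("replicate_id", str(i))
                    for i, t in enumerate(trees)]
    rows = []
    for tid, label, tree in zip(tree_ids, labels, trees):
        rec = compute_statistics_record(tree).as_dict()
        rec["tree_id"] = tid
        rec["label"] = label
        rows.append(rec)
    df = pd.DataFrame(rows)
    return df[["tree_id", "label", "n_tips"] + STATISTIC_COLUMNS]
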
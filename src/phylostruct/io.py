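"""Newick and table input/output.

Trees are serialised one per line in strict Newick with deme labels (and the
migration flag) carried as bracketed node comments, e.g.::

    ((1[&deme=2]:0.1,2[&deme=2]:0.2)E[&deme=2]:0.3)B[&deme=1,migration]:0.4;

Unifurcations (migration nodes) are written explicitly as single-child
clauses and preserved on reading.  Parsing is delegated to DendroPy; node
comments, when present, are interpreted to restore deme labels and migration
flags (a unifurcation with a deme-changing child is recognised as a migration
node even without the flag).
"""

from __future__ import annotations

import json
import re
from pathlib import Path

import dendropy
import pandas as pd

from .trees import Node, Phylogeny

__all__ = [
    "newick_string", "parse_newick", "read_newick", "write_newick",
    "write_statistics_table", "read_statistics_table", "write_dataset",
]

_DEME_RE = re.compile(r"deme=(\d+)")


def newick_string(tree: Phylogeny, comments: bool = True,
                  precision: int = 6) -> str:
    """Serialise one tree to a Newick string (iterative, deep-tree safe)."""
    parts: list[str] = []
    # explicit stack machine: (node, child_index)
    stack: list[tuple[Node, int]] = [(tree.root, 0)]
    while stack:
        node, i = stack.pop()
        if node.children and i == 0:
            parts.append("(")
        if i < len(node.children):
            if i > 0:
                parts.append(",")
            stack.append((node, i + 1))
            stack.append((node.children[i], 0))
            continue
        if node.children:
            parts.append(")")
        if node.label:
            parts.append(node.label)
        if comments:
            tags = [f"deme={node.deme}"]
            if node.is_migration:
                tags.append("migration")
            parts.append("[&" + ",".join(tags) + "]")
        parts.append(f":{node.edge_length:.{precision}g}")
    # the root's edge length is its stem; drop the trailing branch if zero
    return "".join(parts) + ";"


def _convert_dendropy(dnode: dendropy.Node) -> Node:
    root = _node_from_dendropy(dnode)
    stack = [(dnode, root)]
    while stack:
        dn, node = stack.pop()
        for dchild in dn.child_nodes():
            child = node.add_child(_node_from_dendropy(dchild))
            stack.append((dchild, child))
    return root


def _node_from_dendropy(dn: dendropy.Node) -> Node:
    label = None
    if dn.taxon is not None and dn.taxon.label:
        label = dn.taxon.label
    elif dn.label:
        label = dn.label
    node = Node(label=label,
                edge_length=dn.edge.length if dn.edge.length else 0.0)
    comment = ",".join(c or "" for c in (dn.comments or []))
    m = _DEME_RE.search(comment)
    if m:
        node.deme = int(m.group(1))
    if "migration" in comment:
        node.is_migration = True
    return node


def _finalise(tree: Phylogeny) -> Phylogeny:
    # recognise unflagged migration nodes by the colour change below them
    for node in tree.iter_preorder():
        if len(node.children) == 1 and node.children[0].deme != node.deme:
            node.is_migration = True
    return tree


def parse_newick(text: str) -> list[Phylogeny]:
    """Parse one or more Newick trees from a string."""
    try:
        tlist = dendropy.TreeList.get(
            data=text, schema="newick", suppress_internal_node_taxa=True,
            preserve_underscores=True, extract_comment_metadata=False)
    except Exception as err:
        raise ValueError(f"malformed Newick: {err}") from err
    return [_finalise(Phylogeny(_convert_dendropy(t.seed_node)))
            for t in tlist]


def read_newick(path) -> list[Phylogeny]:
    """Read a Newick file (one or more trees) into rooted phylogenies."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    trees = parse_newick(path.read_text())
    for i, tree in enumerate(trees):
        tree.metadata.setdefault("source", str(path))
        tree.metadata.setdefault("replicate_id", f"{path.stem}_{i}")
    return trees


def write_newick(trees, path, comments: bool = True) -> None:
    """Write trees one per line."""
    path = Path(path)
    with path.open("w") as fh:
        for tree in trees:
            fh.write(newick_string(tree, comments=comments) + "\n")


def write_statistics_table(table: pd.DataFrame, path) -> None:
    """Write the per-tree statistics table as UTF-8 CSV with full precision."""
    if table.empty:
        raise ValueError("refusing to write an empty statistics table")
    table.to_csv(path, index=False)


def read_statistics_table(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_dataset(dataset, outdir, stem: str = "trees") -> dict:
    """Write a simulated dataset: Newick file + manifest CSV.

    Returns the mapping of artefact names to paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    newick_path = outdir / f"{stem}.nwk"
    manifest_path = outdir / f"{stem}_manifest.csv"
    write_newick(dataset.trees, newick_path)
    manifest = dataset.manifest.copy()
    manifest["newick_path"] = str(newick_path)
    manifest["n_tips"] = [t.n_tips for t in dataset.trees]
    manifest.to_csv(manifest_path, index=False)
    return {"newick": str(newick_path), "manifest": str(manifest_path)}


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
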
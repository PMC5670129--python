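"""Class taxonomy trees and lineage labels.

A hierarchy is a rooted tree whose leaves are terminal classes (e.g. bacterial
species, cancer subtypes) and whose internal nodes are higher taxa (genus,
family, ..., or cancer type).  Samples carry *lineage labels*: the ordered list
of taxon names from the top level down to their terminal class, serialized as
semicolon-delimited strings (``"Gram-negative;Gammaproteobacteria;...;E. coli"``).

Node identity is the full path from the root, so identical display names under
different parents are distinct nodes (species epithets repeat across genera).
The root is the empty path ``()`` at level 0; a node's level equals the length
of its path.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

NodeId = tuple[str, ...]

ROOT: NodeId = ()


def parse_lineage(s: str | Sequence[str]) -> tuple[str, ...]:
    """Parse a lineage into a tuple of taxon names.

    Accepts a semicolon-delimited string or any sequence of names.  Components
    are stripped of surrounding whitespace; empty components are an error.
    """
    if isinstance(s, str):
        parts = [p.strip() for p in s.split(";")]
    else:
        parts = [str(p).strip() for p in s]
    if not parts or any(p == "" for p in parts):
        raise ValueError(f"lineage has empty component(s): {s!r}")
    return tuple(parts)


def format_lineage(lineage: Sequence[str]) -> str:
    return ";".join(lineage)


@dataclass
class HierarchyTree:
    """Rooted labeled tree of classes.

    Attributes
    ----------
    children : mapping node-id -> ordered list of child node-ids
        Children are stored in first-seen order of the input lineages.
    depth : int
        Maximum leaf level.
    """

    children: dict[NodeId, list[NodeId]] = field(default_factory=dict)

    # -- structure queries ---------------------------------------------------

    @property
    def nodes(self) -> list[NodeId]:
        out = [ROOT]
        stack = list(reversed(self.children.get(ROOT, [])))
        while stack:
            n = stack.pop()
            out.append(n)
            stack.extend(reversed(self.children.get(n, [])))
        return out

    @property
    def leaves(self) -> list[NodeId]:
        return [n for n in self.nodes if not self.children.get(n)]

    @property
    def internal_nodes(self) -> list[NodeId]:
        return [n for n in self.nodes if self.children.get(n)]

    @property
    def depth(self) -> int:
        return max((len(n) for n in self.leaves), default=0)

    def __contains__(self, node: NodeId) -> bool:
        return node == ROOT or node in self._node_set()

    def _node_set(self) -> set[NodeId]:
        return set(self.nodes)

    @staticmethod
    def parent(node: NodeId) -> NodeId:
        if node == ROOT:
            raise ValueError("root has no parent")
        return node[:-1]

    @staticmethod
    def level(node: NodeId) -> int:
        return len(node)

    def is_leaf(self, node: NodeId) -> bool:
        return not self.children.get(node)

    # -- serialization -------------------------------------------------------

    def to_lineages(self) -> list[str]:
        return [format_lineage(leaf) for leaf in self.leaves]

    def to_json(self) -> str:
        def rec(node: NodeId):
            return {
                "name": node[-1] if node else "root",
                "children": [rec(c) for c in self.children.get(node, [])],
            }

        return json.dumps(rec(ROOT), indent=1)

    def to_parent_child_tsv(self) -> str:
        lines = ["#parent\tchild"]
        for n in self.nodes:
            if n == ROOT:
                continue
            lines.append(f"{format_lineage(n[:-1]) or 'root'}\t{n[-1]}")
        return "\n".join(lines) + "\n"


def build_tree(
    labels: Iterable[str | Sequence[str]], ragged: bool = False
) -> HierarchyTree:
    """Build the minimal tree containing every lineage as a root-to-leaf path.

    Parameters
    ----------
    labels : iterable of lineage strings or name sequences
    ragged : bool
        If False (default), all lineages must share the same depth.

    Children are stored in first-seen order.
    """
    lineages = [parse_lineage(s) for s in labels]
    if not lineages:
        raise ValueError("at least one lineage label is required")
    depths = {len(lin) for lin in lineages}
    if not ragged and len(depths) > 1:
        raise ValueError(
            f"lineages have unequal depths {sorted(depths)}; "
            "pass ragged=True to allow this"
        )
    tree = HierarchyTree(children={ROOT: []})
    for lin in lineages:
        for i in range(len(lin)):
            parent, child = lin[:i], lin[: i + 1]
            sibs = tree.children.setdefault(parent, [])
            if child not in sibs:
                sibs.append(child)
            tree.children.setdefault(child, [])
    # drop empty child lists for leaves to keep is_leaf cheap and repr clean
    tree.children = {k: v for k, v in tree.children.items() if v or k == ROOT}
    return tree


def stratify_at_node(
    tree: HierarchyTree,
    node: NodeId,
    lineages: Sequence[Sequence[str]],
) -> dict[NodeId, np.ndarray]:
    """Group sample indices by the immediate child of ``node`` they fall under.

    Samples whose lineage does not pass through ``node`` are excluded; the
    returned groups partition the samples under the node.
    """
    kids = tree.children.get(node)
    if not kids:
        raise ValueError(f"node {node!r} has no children to stratify")
    lvl = len(node)
    groups: dict[NodeId, list[int]] = {}
    for i, lin in enumerate(lineages):
        lin = tuple(lin)
        if len(lin) <= lvl or lin[:lvl] != node:
            continue
        child = lin[: lvl + 1]
        if child not in tree.children and child not in set(kids):
            continue
        groups.setdefault(child, []).append(i)
    return {c: np.asarray(ix, dtype=int) for c, ix in groups.items()}


def highest_prediction_level(tree: HierarchyTree, leaf: NodeId) -> NodeId:
    """Deepest ancestor of ``leaf`` that remains identifiable without it.

    Removing a terminal class from the database prunes every ancestor it was
    the sole descendant of.  The deepest surviving ancestor — equivalently the
    deepest proper ancestor with at least two children — is the highest level
    at which samples of the held-out class can still be routed correctly.
    A species sharing its genus with others is predictable to genus level; a
    species that is the only member of its genus only to family level (or
    higher, if the family too is a singleton).
    """
    if not tree.is_leaf(leaf):
        raise ValueError(f"{leaf!r} is not a leaf")
    for k in range(len(leaf) - 1, -1, -1):
        anc = leaf[:k]
        if len(tree.children.get(anc, [])) >= 2:
            return anc
    raise ValueError(
        f"no ancestor of {leaf!r} has another descendant; nothing is predictable"
    )


def prune_leaf(tree: HierarchyTree, leaf: NodeId) -> HierarchyTree:
    """Return a new tree with ``leaf`` removed and childless ancestors pruned."""
    if not tree.is_leaf(leaf):
        raise ValueError(f"{leaf!r} is not a leaf")
    remaining = [lin for lin in tree.leaves if lin != leaf]
    if not remaining:
        raise ValueError("removing the leaf empties the tree")
    return build_tree(remaining, ragged=True)


def read_label_file(path) -> dict[str, tuple[str, ...]]:
    """Read a two-column TSV ``sample_id<TAB>lineage`` (``#`` comments ignored)."""
    out: dict[str, tuple[str, ...]] = {}
    with open(path, encoding="utf-8") as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{ln}: expected 2 tab-separated columns")
            out[parts[0].strip()] = parse_lineage(parts[1])
    return out


def write_label_file(path, labels: Mapping[str, Sequence[str]]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("#sample_id\tlineage\n")
        for sid, lin in labels.items():
            fh.write(f"{sid}\t{format_lineage(tuple(lin))}\n")
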
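"""The trained hierarchical classifier: one NodeModel per internal node.

Training stratifies the samples at each parent node by immediate child and fits
the method named in the method map (see :mod:`hierclass.selection`).  Nodes
with a single down-stream child are fitted with the single-offspring rule,
discriminating that child against the offspring of the nearest ancestor's other
branches.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import hierarchy as hi
from . import node_model as nm
from .hierarchy import ROOT, HierarchyTree, NodeId


@dataclass
class HCModel:
    """Trained tree of per-node classifiers."""

    tree: HierarchyTree
    method_map: dict  # node-id -> {"method": tag, "inner_accuracy": {...}}
    node_models: dict  # node-id -> NodeModel
    n_features: int
    feature_names: list | None = None
    config: dict = field(default_factory=dict)
    seed: int | None = None

    # -- serialization --------------------------------------------------------

    def to_json(self) -> str:
        return json.dumps(
            {
                "lineages": self.tree.to_lineages(),
                "method_map": {
                    ";".join(k): {
                        "method": v["method"],
                        "inner_accuracy": v.get("inner_accuracy", {}),
                        **({"pls_k": v["pls_k"]} if "pls_k" in v else {}),
                    }
                    for k, v in self.method_map.items()
                },
                "node_models": [m.to_dict() for m in self.node_models.values()],
                "n_features": self.n_features,
                "feature_names": self.feature_names,
                "config": self.config,
                "seed": self.seed,
            }
        )

    @classmethod
    def from_json(cls, s: str) -> "HCModel":
        d = json.loads(s)
        tree = hi.build_tree(d["lineages"], ragged=True)
        models = {}
        for md in d["node_models"]:
            m = nm.NodeModel.from_dict(md)
            models[m.node] = m
        mmap = {
            tuple(k.split(";")) if k else ROOT: v for k, v in d["method_map"].items()
        }
        return cls(
            tree=tree,
            method_map=mmap,
            node_models=models,
            n_features=d["n_features"],
            feature_names=d.get("feature_names"),
            config=d.get("config", {}),
            seed=d.get("seed"),
        )

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(self.to_json())

    @classmethod
    def load(cls, path) -> "HCModel":
        with open(path, encoding="utf-8") as fh:
            return cls.from_json(fh.read())


def related_lower_nodes(tree: HierarchyTree, node: NodeId) -> list[NodeId]:
    """Offspring of the nearest ancestor's other branches, for the
    single-offspring rule.

    Walks up from ``node`` to the first ancestor with another child; returns
    the children of those sibling branches (the siblings themselves when they
    are leaves).
    """
    cur = node
    while cur != ROOT:
        parent = cur[:-1]
        sibs = [s for s in tree.children.get(parent, []) if s != cur]
        if sibs:
            related: list[NodeId] = []
            for s in sibs:
                kids = tree.children.get(s, [])
                related.extend(kids if kids else [s])
            return related
        cur = parent
    return []


def _indices_under(node: NodeId, lineages: Sequence[tuple]) -> np.ndarray:
    lvl = len(node)
    return np.asarray(
        [i for i, lin in enumerate(lineages) if tuple(lin)[:lvl] == node], dtype=int
    )


def fit_node_from_tree(
    tree: HierarchyTree,
    node: NodeId,
    X: np.ndarray,
    lineages: Sequence[tuple],
    method: str,
    pls_components: int | None = None,
) -> nm.NodeModel | None:
    """Fit one node's classifier from the stratified data, applying the
    single-offspring rule when only one child carries samples."""
    groups = hi.stratify_at_node(tree, node, lineages)
    if not groups:
        return None
    if len(groups) >= 2:
        idx = np.concatenate([groups[c] for c in tree.children[node] if c in groups])
        labels = []
        for c in tree.children[node]:
            labels.extend([c] * len(groups.get(c, [])))
        model = nm.fit_node(
            X[idx], labels, method, node=node, pls_components=pls_components
        )
        # emission order follows the tree's child order, not name order
        order = [c for c in tree.children[node] if c in groups]
        model = _reorder_children(model, order)
        return model
    (child, child_idx), = groups.items()
    related = related_lower_nodes(tree, node)
    X_related = {}
    for rc in related:
        ridx = _indices_under(rc, lineages)
        if len(ridx):
            X_related[rc] = X[ridx]
    return nm.fit_single_offspring(
        X[child_idx], child, X_related, method, node=node,
        pls_components=pls_components,
    )


def _reorder_children(model: nm.NodeModel, order: list) -> nm.NodeModel:
    if model.classes == order:
        return model
    perm = [model.classes.index(c) for c in order]
    model.classes = order
    model.children = list(order)
    if len(order) > 2:
        model.coefs = model.coefs[perm]
        model.intercepts = model.intercepts[perm]
    elif perm == [1, 0]:  # binary symmetric model: flip the positive class
        model.coefs = -model.coefs
        model.intercepts = -model.intercepts
    return model


def train_hcmodel(
    tree: HierarchyTree,
    X: np.ndarray,
    lineages: Sequence[tuple],
    method_map: dict,
    feature_names: list | None = None,
    config: dict | None = None,
    seed: int | None = None,
    default_method: str = "PLS",
) -> HCModel:
    """Train NodeModels for every internal node reachable with training data."""
    X = np.asarray(X, dtype=float)
    lineages = [tuple(lin) for lin in lineages]
    models: dict[NodeId, nm.NodeModel] = {}
    for node in tree.internal_nodes:
        if not len(_indices_under(node, lineages)):
            continue
        entry = method_map.get(node, {})
        method = entry.get("method", default_method)
        m = fit_node_from_tree(
            tree, node, X, lineages, method, pls_components=entry.get("pls_k")
        )
        if m is not None:
            models[node] = m
    return HCModel(
        tree=tree,
        method_map=method_map,
        node_models=models,
        n_features=X.shape[1],
        feature_names=feature_names,
        config=config or {},
        seed=seed,
    )
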
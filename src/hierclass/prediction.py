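"""Top-down probabilistic prediction and leave-one-class-out evaluation.

A sample descends the trained hierarchy from the root: at each node the
NodeModel emits a probability distribution over the children, the sample is
assigned to the most probable child, and descent continues.  When the gap
between the two highest child probabilities falls below a threshold ``delta``
the sample is left *non-classified* at that level — the class-prediction
analogue of "unable to call below this rank".  Single-offspring nodes apply
their own rule: the sample must beat the related outside classes or it stops.

Leave-one-class-out removes a terminal class entirely, retrains (method map
included) on the remaining data, and measures how reliably the held-out
samples are routed through the correct ancestor taxa — the clinical use case
of assigning an unknown species to its genus or family.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import hierarchy as hi
from . import node_model as nm
from . import selection as sel
from .hcmodel import HCModel, train_hcmodel
from .hierarchy import ROOT, HierarchyTree, NodeId


@dataclass
class PredictionConfig:
    """Probability-difference threshold and depth limit for top-down descent."""

    delta: float = 0.05
    max_depth: int | None = None

    def __post_init__(self):
        if not 0.0 <= self.delta <= 1.0:
            raise ValueError("delta must lie in [0, 1]")


@dataclass
class PredictionStep:
    node: NodeId
    classes: list
    probabilities: np.ndarray
    assigned: NodeId | None


@dataclass
class PredictionPath:
    """Per-sample trajectory through the tree."""

    steps: list[PredictionStep] = field(default_factory=list)
    status: str = "reached-leaf"  # or "non-classified"
    stop_level: int = 0

    @property
    def deepest(self) -> NodeId:
        for st in reversed(self.steps):
            if st.assigned is not None:
                return st.assigned
        return ROOT

    def assignment_at(self, level: int) -> NodeId | None:
        """Node assigned at ``level`` (1-based), or None if descent stopped above."""
        for st in self.steps:
            if st.assigned is not None and len(st.assigned) == level:
                return st.assigned
        return None

    def passes_through(self, node: NodeId) -> bool:
        return node == ROOT or self.assignment_at(len(node)) == node


def predict_topdown(
    model: HCModel, x: np.ndarray, cfg: PredictionConfig | None = None
) -> PredictionPath:
    """Descend from the root, assigning the sample at each node.

    With ``delta = 0`` every sample reaches a leaf unless a single-offspring
    node rejects it.
    """
    cfg = cfg or PredictionConfig()
    x = np.asarray(x, dtype=float).ravel()
    path = PredictionPath()
    node: NodeId = ROOT
    while not model.tree.is_leaf(node):
        if cfg.max_depth is not None and len(node) >= cfg.max_depth:
            break
        node_model = model.node_models.get(node)
        if node_model is None:
            raise ValueError(f"untrained node encountered: {node!r}")
        probs = nm.predict_node_proba(node_model, x[None, :])[0]
        j = int(np.argmax(probs))  # ties -> first, i.e. tree child order
        winner = node_model.classes[j]
        if node_model.single_offspring:
            if winner != node_model.children[0]:
                path.steps.append(
                    PredictionStep(node, node_model.classes, probs, None)
                )
                path.status = "non-classified"
                path.stop_level = len(node)
                return path
            assigned = node_model.children[0]
        else:
            top2 = np.sort(probs)[::-1][:2]
            if top2[0] - top2[1] < cfg.delta:
                path.steps.append(
                    PredictionStep(node, node_model.classes, probs, None)
                )
                path.status = "non-classified"
                path.stop_level = len(node)
                return path
            assigned = winner
        path.steps.append(PredictionStep(node, node_model.classes, probs, assigned))
        node = assigned
    path.status = "reached-leaf" if model.tree.is_leaf(node) else "max-depth"
    path.stop_level = len(node)
    return path


def predict_many(
    model: HCModel, X: np.ndarray, cfg: PredictionConfig | None = None
) -> list[PredictionPath]:
    X = np.asarray(X, dtype=float)
    return [predict_topdown(model, X[i], cfg) for i in range(X.shape[0])]


def leave_one_class_out(
    tree: HierarchyTree,
    X: np.ndarray,
    lineages: Sequence[tuple],
    target_leaf: NodeId,
    cv_cfg: "sel.CVConfig | None" = None,
    pred_cfg: PredictionConfig | None = None,
) -> dict:
    """Hold out one terminal class, retrain, and score ancestor-level routing.

    Returns a record with the evaluation level (the deepest ancestor still
    identifiable without the class), per-level accuracies for each repetition,
    and the mean/sd accuracy at the evaluation level.
    """
    cv_cfg = cv_cfg or sel.CVConfig()
    pred_cfg = pred_cfg or PredictionConfig()
    X = np.asarray(X, dtype=float)
    lineages = [tuple(lin) for lin in lineages]
    target_leaf = tuple(target_leaf)
    if target_leaf not in set(tree.leaves):
        raise ValueError(f"{target_leaf!r} is not a leaf of the tree")

    held = np.asarray([lin == target_leaf for lin in lineages])
    if held.sum() == 0:
        raise ValueError("no samples carry the target class")
    rest = ~held
    lin_rest = [lin for lin, keep in zip(lineages, rest) if keep]
    if not lin_rest:
        raise ValueError("removing the leaf empties the root")
    subtree = hi.build_tree(lin_rest, ragged=True)
    eval_node = hi.highest_prediction_level(tree, target_leaf)

    X_rest, X_held = X[rest], X[held]
    per_level: dict[int, list[float]] = {
        lvl: [] for lvl in range(1, len(target_leaf))
    }
    for rep in range(cv_cfg.repetitions):
        seed = sel.derive_seed(cv_cfg.seed, rep, 7919)
        mmap = sel.derive_method_map(subtree, X_rest, lin_rest, cv_cfg, seed=seed)
        model = train_hcmodel(
            subtree, X_rest, lin_rest, mmap, config=vars(cv_cfg).copy(), seed=seed
        )
        paths = predict_many(model, X_held, pred_cfg)
        for lvl in per_level:
            anc = target_leaf[:lvl]
            hits = sum(p.passes_through(anc) for p in paths)
            per_level[lvl].append(100.0 * hits / len(paths))

    eval_level = len(eval_node)
    eval_accs = per_level.get(eval_level, [100.0] * cv_cfg.repetitions)
    return {
        "target": hi.format_lineage(target_leaf),
        "evaluation_level": eval_level,
        "evaluation_node": hi.format_lineage(eval_node) if eval_node else "root",
        "per_level_accuracy": {str(k): v for k, v in per_level.items()},
        "accuracy_at_evaluation_level": float(np.mean(eval_accs)),
        "accuracy_sd": float(np.std(eval_accs)),
        "n_held_out": int(held.sum()),
        "repetitions": cv_cfg.repetitions,
    }
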
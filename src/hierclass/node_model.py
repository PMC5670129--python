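"""Per-node probabilistic classifiers.

Each internal node of the hierarchy carries a ``NodeModel``: a fitted linear
reducer (see :mod:`hierclass.reducers`) plus a one-vs-all logistic layer over
the reducer scores.  The logistic probabilities are normalized to a
distribution over the node's children; a sample descends to the child with the
highest probability.

Where a parent has exactly one child, classifying into it would be vacuous.
The *single-offspring rule* instead discriminates the single child against the
offspring of the parent's sibling nodes; a sample whose most probable class is
not the single child is flagged non-classified at that node.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import reducers
from .reducers import ReducedModel


def _fit_logistic(
    scores: np.ndarray,
    target: np.ndarray,
    max_iter: int = 150,
    tol: float = 1e-8,
) -> tuple[np.ndarray, float]:
    """Firth bias-reduced logistic regression (Jeffreys-prior penalty).

    Nodes that separate cleanly are the norm here, and the plain MLE then
    diverges with the decision boundary left wherever the optimizer stopped.
    The Jeffreys penalty keeps the optimum finite and well-centered while the
    fitted probabilities stay sharp — the standard remedy for separation
    (Firth 1993; Heinze & Schemper 2002).  Deterministic Newton iteration.
    """
    y = np.asarray(target, dtype=float)
    X = np.column_stack([np.ones(len(y)), np.asarray(scores, dtype=float)])
    beta = np.zeros(X.shape[1])
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -30.0, 30.0)
        p = 1.0 / (1.0 + np.exp(-eta))
        w = p * (1.0 - p)
        info = X.T @ (X * w[:, None])
        try:
            info_inv = np.linalg.inv(info)
        except np.linalg.LinAlgError:
            info_inv = np.linalg.pinv(info)
        hat = np.einsum("ij,jk,ik->i", X, info_inv, X) * w
        score_vec = X.T @ (y - p + hat * (0.5 - p))
        step = info_inv @ score_vec
        norm = np.abs(step).max()
        if norm > 5.0:  # damp early oversized Newton steps
            step *= 5.0 / norm
        beta = beta + step
        if norm < tol:
            break
    return beta[1:], float(beta[0])


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


@dataclass
class NodeModel:
    """Reducer + one-vs-all logistic layer for one internal node."""

    node: tuple
    method: str
    reducer: ReducedModel
    classes: list  # logistic classes, in emission (column) order
    coefs: np.ndarray  # (n_classes or 1, k) logistic weights over scores
    intercepts: np.ndarray
    children: list = field(default_factory=list)  # tree children (== classes
    # except at single-offspring nodes, where classes ⊃ children)
    single_offspring: bool = False

    def to_dict(self) -> dict:
        return {
            "node": list(self.node),
            "method": self.method,
            "reducer": self.reducer.to_dict(),
            "classes": [list(c) if isinstance(c, tuple) else c for c in self.classes],
            "coefs": self.coefs.tolist(),
            "intercepts": self.intercepts.tolist(),
            "children": [list(c) for c in self.children],
            "single_offspring": self.single_offspring,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NodeModel":
        return cls(
            node=tuple(d["node"]),
            method=d["method"],
            reducer=ReducedModel.from_dict(d["reducer"]),
            classes=[tuple(c) if isinstance(c, list) else c for c in d["classes"]],
            coefs=np.asarray(d["coefs"], dtype=float),
            intercepts=np.asarray(d["intercepts"], dtype=float),
            children=[tuple(c) for c in d["children"]],
            single_offspring=bool(d["single_offspring"]),
        )


def fit_logistic_layer(
    scores: np.ndarray, labels: list, classes: list
) -> tuple[np.ndarray, np.ndarray]:
    """One-vs-all logistic layer on reducer scores.

    Two classes get a single symmetric model (positive class = ``classes[1]``);
    more get one binary model per class.
    """
    codes, enc_classes = reducers.encode_labels(labels)
    lut = {c: j for j, c in enumerate(classes)}
    codes = np.asarray([lut[enc_classes[c]] for c in codes])
    if len(classes) == 2:
        coef, b = _fit_logistic(scores, (codes == 1).astype(int))
        return coef[None, :], np.array([b])
    coefs, bs = [], []
    for j in range(len(classes)):
        coef, b = _fit_logistic(scores, (codes == j).astype(int))
        coefs.append(coef)
        bs.append(b)
    return np.vstack(coefs), np.asarray(bs)


def _fit_layers(
    X: np.ndarray, labels: list, classes: list, method: str,
    pls_components: int | None = None,
) -> tuple[ReducedModel, np.ndarray, np.ndarray]:
    reducer = reducers.fit_reducer(method, X, labels, pls_components=pls_components)
    scores = reducers.score(reducer, X)
    coefs, bs = fit_logistic_layer(scores, labels, classes)
    return reducer, coefs, bs


def fit_node(
    X: np.ndarray,
    child_labels,
    method: str,
    node: tuple = (),
    pls_components: int | None = None,
) -> NodeModel:
    """Fit the classifier discriminating a node's children.

    ``child_labels`` assigns each row of ``X`` to one immediate child; every
    child needs at least 2 samples.  ``pls_components`` pins the SIMPLS
    component count (normally the value chosen by the inner CV).
    """
    labels = list(child_labels)
    codes, classes = reducers.encode_labels(labels)
    if len(classes) < 2:
        raise ValueError(
            "fit_node needs >= 2 distinct children; use fit_single_offspring"
        )
    for j, c in enumerate(classes):
        if int(np.sum(codes == j)) < 2:
            raise ValueError(f"child {c!r} has fewer than 2 samples")
    reducer, coefs, bs = _fit_layers(
        np.asarray(X, float), labels, classes, method, pls_components=pls_components
    )
    return NodeModel(
        node=node,
        method=method,
        reducer=reducer,
        classes=classes,
        coefs=coefs,
        intercepts=bs,
        children=list(classes),
    )


def fit_single_offspring(
    X_child: np.ndarray,
    child: tuple,
    X_related: dict,
    method: str,
    node: tuple = (),
    pls_components: int | None = None,
) -> NodeModel:
    """Single-offspring rule: discriminate the only child against related classes.

    ``X_related`` maps each related lower-order node (offspring of the parent's
    siblings) to its sample matrix.  At prediction time a sample whose argmax
    class is not ``child`` is non-classified at this node.
    """
    if not X_related:
        raise ValueError("cannot calibrate single-offspring node: no related classes")
    Xs = [np.asarray(X_child, float)]
    labs: list = [child] * len(X_child)
    for rc in sorted(X_related, key=str):
        Xr = np.asarray(X_related[rc], float)
        Xs.append(Xr)
        labs.extend([rc] * len(Xr))
    X = np.vstack(Xs)
    classes = sorted(set(labs), key=str)
    reducer, coefs, bs = _fit_layers(
        X, labs, classes, method, pls_components=pls_components
    )
    return NodeModel(
        node=node,
        method=method,
        reducer=reducer,
        classes=classes,
        coefs=coefs,
        intercepts=bs,
        children=[child],
        single_offspring=True,
    )


def predict_node_proba(model: NodeModel, X_new: np.ndarray) -> np.ndarray:
    """Probability distribution over the node's logistic classes.

    Rows sum to 1; for a binary node the two columns are exact complements.
    """
    s = reducers.score(model.reducer, X_new)
    if len(model.classes) == 2:
        p1 = _sigmoid(s @ model.coefs[0] + model.intercepts[0])
        return np.column_stack([1.0 - p1, p1])
    raw = _sigmoid(s @ model.coefs.T + model.intercepts)
    tot = raw.sum(axis=1, keepdims=True)
    tot[tot == 0] = 1.0
    return raw / tot
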
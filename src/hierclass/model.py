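"""Model/Results surface for hierarchical classification.

:class:`HierarchicalClassifier` is built from a feature matrix and lineage
labels (statsmodels-style); :meth:`~HierarchicalClassifier.fit` derives the
per-node method map by nested cross-validation and trains one discriminant
model per internal node, returning an :class:`HCResults` that carries the
trained tree, the method map, prediction methods, cross-validation and
leave-one-class-out evaluation, and a ``summary()`` table.

Example
-------
>>> from hierclass import TreeSpec, gen_hierarchical_gaussians
>>> from hierclass.model import HierarchicalClassifier
>>> X, lineages, tree = gen_hierarchical_gaussians(TreeSpec(seed=1))
>>> res = HierarchicalClassifier(X, lineages).fit()
>>> paths = res.predict(X[:3])
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from . import hierarchy as hi
from . import prediction as pr
from . import selection as sel
from .hcmodel import HCModel, train_hcmodel
from .hierarchy import HierarchyTree


class HierarchicalClassifier:
    """Top-down hierarchical classifier over a samples x features matrix.

    Parameters
    ----------
    X : (n, d) array
        Feature matrix, samples in rows.
    lineages : sequence of lineage tuples/strings
        One full root-to-leaf class path per sample.
    tree : HierarchyTree, optional
        The class taxonomy; built from the lineages when omitted.
    config : CVConfig, optional
        Folds, repetitions, and seed for all cross-validation.
    """

    def __init__(
        self,
        X: np.ndarray,
        lineages: Sequence,
        tree: HierarchyTree | None = None,
        config: sel.CVConfig | None = None,
        feature_names: list | None = None,
    ):
        self.X = np.asarray(X, dtype=float)
        self.lineages = [hi.parse_lineage(l) if isinstance(l, str) else tuple(l)
                         for l in lineages]
        if len(self.lineages) != self.X.shape[0]:
            raise ValueError("one lineage per sample required")
        self.tree = tree or hi.build_tree(self.lineages, ragged=True)
        self.config = config or sel.CVConfig()
        self.feature_names = feature_names

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        labels: "pd.Series | dict | Sequence",
        config: sel.CVConfig | None = None,
    ) -> "HierarchicalClassifier":
        """Build from a samples x features DataFrame and per-sample lineages.

        ``labels`` may be a dict / Series keyed by the DataFrame index or a
        positional sequence of lineage strings.
        """
        if isinstance(labels, dict):
            labels = pd.Series(labels)
        if isinstance(labels, pd.Series):
            labels = labels.loc[df.index]
        return cls(
            df.values,
            list(labels),
            config=config,
            feature_names=list(df.columns),
        )

    def fit(self) -> "HCResults":
        """Derive the method map (nested CV) and train all node models."""
        mmap = sel.derive_method_map(self.tree, self.X, self.lineages, self.config)
        model = train_hcmodel(
            self.tree,
            self.X,
            self.lineages,
            mmap,
            feature_names=self.feature_names,
            config=vars(self.config).copy(),
            seed=self.config.seed,
        )
        return HCResults(self, model)

    def cross_validate(self, delta: float = 0.0) -> sel.ConfusionReport:
        """Repeated outer CV with per-fold method-map re-derivation."""
        return sel.cross_validate(self.tree, self.X, self.lineages,
                                  self.config, delta=delta)

    def leave_one_class_out(
        self, target_leaf, pred_cfg: pr.PredictionConfig | None = None
    ) -> dict:
        target = (hi.parse_lineage(target_leaf)
                  if isinstance(target_leaf, str) else tuple(target_leaf))
        return pr.leave_one_class_out(
            self.tree, self.X, self.lineages, target, self.config, pred_cfg
        )


class HCResults:
    """Trained hierarchical classifier plus its provenance."""

    def __init__(self, model_spec: HierarchicalClassifier, hcmodel: HCModel):
        self.model_spec = model_spec
        self.hcmodel = hcmodel

    @property
    def method_map(self) -> dict:
        return self.hcmodel.method_map

    @property
    def tree(self) -> HierarchyTree:
        return self.hcmodel.tree

    def predict(
        self, X_new: np.ndarray, pred_cfg: pr.PredictionConfig | None = None
    ) -> list[pr.PredictionPath]:
        return pr.predict_many(self.hcmodel, X_new, pred_cfg)

    def predict_classes(
        self, X_new: np.ndarray, pred_cfg: pr.PredictionConfig | None = None
    ) -> list[str]:
        """Deepest confident class per sample, as lineage strings."""
        return [hi.format_lineage(p.deepest) or "non_classified"
                for p in self.predict(X_new, pred_cfg)]

    def summary(self) -> str:
        """Human-readable account of the trained tree and method map."""
        lines = [
            "Hierarchical classifier",
            "=" * 55,
            f"samples: {self.model_spec.X.shape[0]}   "
            f"features: {self.model_spec.X.shape[1]}",
            f"tree depth: {self.tree.depth}   leaves: {len(self.tree.leaves)}   "
            f"internal nodes: {len(self.tree.internal_nodes)}",
            f"seed: {self.hcmodel.seed}",
            "-" * 55,
            f"{'node':<32}{'method':<9}{'inner acc %':>12}",
        ]
        for node, entry in self.hcmodel.method_map.items():
            accs = entry.get("inner_accuracy", {}).get(entry["method"], [])
            acc = f"{np.nanmean(accs):.1f}" if len(accs) else "-"
            name = hi.format_lineage(node) or "(root)"
            flag = ("*" if self.hcmodel.node_models.get(node) is not None
                    and self.hcmodel.node_models[node].single_offspring else "")
            lines.append(f"{name[:31]:<32}{entry['method'] + flag:<9}{acc:>12}")
        lines.append("-" * 55)
        lines.append("* single-offspring node (child vs related classes)")
        return "\n".join(lines)

    def save(self, path) -> None:
        self.hcmodel.save(path)
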
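"""Nested cross-validated method selection and repeated CV evaluation.

At every internal node the four discriminant methods are trained and scored on
identical stratified inner folds; the method with the highest mean inner
accuracy wins (ties break by the fixed efficiency order PLS > MMC-LDA >
PCA-LDA > SVM).  The per-node winners form the *method map*.  Evaluation runs
repeated stratified outer CV: the method map is re-derived on each outer
training portion only (no leakage into the outer test set), the full tree of
node models is trained, and the outer test samples are classified top-down.
Per-level confusion matrices and accuracies (mean +/- sd over repetitions) are
collected in a :class:`ConfusionReport`.

Fold counts adapt to the smallest class: ``effective_folds = min(K, smallest
class size)``, with a logged warning when reduced.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from . import hierarchy as hi
from . import node_model as nm
from .hcmodel import HCModel, related_lower_nodes, train_hcmodel, _indices_under
from .hierarchy import HierarchyTree, NodeId
from .reducers import METHOD_PRIORITY

logger = logging.getLogger("hierclass")

NON_CLASSIFIED = "non_classified"


@dataclass
class CVConfig:
    """Fold counts, repetitions, and the master seed for all CV randomness."""

    outer_folds: int = 5
    inner_folds: int = 5
    repetitions: int = 5
    seed: int = 0
    stratified: bool = True

    def __post_init__(self):
        if self.outer_folds < 2 or self.inner_folds < 2:
            raise ValueError("fold counts must be >= 2")
        if self.repetitions < 1:
            raise ValueError("repetitions must be >= 1")


def derive_seed(seed: int, *parts: int) -> int:
    """Deterministic child seed below 2**31 from a master seed and indices."""
    h = (int(seed) + 1) % 2147483647
    for p in parts:
        h = (h * 1000003 + int(p) + 12345) % 2147483647
    return h


def _effective_folds(k: int, labels: np.ndarray, what: str) -> int:
    counts = pd.Series(labels).value_counts()
    eff = int(min(k, counts.min()))
    if eff < k:
        logger.warning(
            "%s folds reduced from %d to %d (smallest class has %d samples)",
            what, k, eff, counts.min(),
        )
    if eff < 2:
        raise ValueError(f"smallest class has {counts.min()} sample(s); need >= 2")
    return eff


#: SIMPLS component-count grid searched by the inner CV (capped by data rank)
PLS_K_GRID = (1, 2, 3, 5, 10, 15)


def _accuracy(model: nm.NodeModel, X_te: np.ndarray, truth: list) -> float:
    probs = nm.predict_node_proba(model, X_te)
    pred = [model.classes[j] for j in np.argmax(probs, axis=1)]
    return 100.0 * float(np.mean([p == t for p, t in zip(pred, truth)]))


def _pls_fold_accuracies(
    X_tr: np.ndarray, y_tr: list, X_te: np.ndarray, y_te: list, ks: Sequence[int]
) -> dict[int, float]:
    """Inner-fold accuracy of SIMPLS + logistic for each component count.

    SIMPLS components are nested (the first k columns of a larger fit are the
    k-component fit), so one reducer fit at max(ks) serves every k.
    """
    from .reducers import ReducedModel, fit_reducer, score

    classes = sorted(set(y_tr), key=str)
    # c classes in general position need c-1 discriminant dimensions: never
    # search below that (a 1-D projection of 3+ classes is brittle)
    floor = len(classes) - 1
    ks = sorted({max(k, floor) for k in ks})
    full = fit_reducer("PLS", X_tr, y_tr, pls_components=max(ks))
    out: dict[int, float] = {}
    for k in ks:
        kk = min(k, full.k)
        sliced = ReducedModel(
            method="PLS", W=full.W[:, :kk], center=full.center, k=kk, classes=classes
        )
        coefs, bs = nm.fit_logistic_layer(
            score(sliced, X_tr), y_tr, classes
        )
        model = nm.NodeModel(
            node=(), method="PLS", reducer=sliced, classes=classes,
            coefs=coefs, intercepts=bs, children=list(classes),
        )
        out[k] = _accuracy(model, X_te, y_te)
        if kk < k:
            break  # grid exhausted the data rank
    return out


def select_method(
    X: np.ndarray,
    labels: Sequence,
    cfg: CVConfig | None = None,
    seed: int | None = None,
) -> tuple[str, dict, dict]:
    """Pick the best of the four methods by stratified inner CV.

    All methods see identical folds.  PLS is additionally tuned over the
    component grid ``PLS_K_GRID`` (ties -> fewest components); its table entry
    reports the chosen count's fold accuracies.  Returns
    ``(winner, table, details)`` where ``details`` carries ``pls_k``.  A method
    that cannot be fitted on some fold (e.g. Fisherfaces with too few samples)
    is scored NaN there and judged on its remaining folds.
    """
    cfg = cfg or CVConfig()
    X = np.asarray(X, dtype=float)
    labels = list(labels)
    key = np.asarray([str(l) for l in labels])
    eff = _effective_folds(cfg.inner_folds, key, "inner")
    rs = derive_seed(cfg.seed, 1) if seed is None else seed
    skf = StratifiedKFold(n_splits=eff, shuffle=True, random_state=rs)
    table: dict[str, list[float]] = {m: [] for m in METHOD_PRIORITY}
    pls_folds: list[dict[int, float]] = []
    for tr, te in skf.split(X, key):
        y_tr = [labels[i] for i in tr]
        y_te = [labels[i] for i in te]
        for method in METHOD_PRIORITY:
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    if method == "PLS":
                        pls_folds.append(
                            _pls_fold_accuracies(X[tr], y_tr, X[te], y_te, PLS_K_GRID)
                        )
                        continue
                    model = nm.fit_node(X[tr], y_tr, method)
                acc = _accuracy(model, X[te], y_te)
            except (ValueError, np.linalg.LinAlgError):
                acc = np.nan
            table[method].append(float(acc))
    # choose the PLS component count: highest mean accuracy, ties -> fewest
    ks = [k for k in PLS_K_GRID if all(k in f for f in pls_folds)] or [
        min(min(f) for f in pls_folds)
    ]
    k_means = {k: float(np.mean([f[k] for f in pls_folds])) for k in ks}
    pls_k = min(k_means, key=lambda k: (-k_means[k], k))
    table["PLS"] = [f.get(pls_k, min(f.values())) for f in pls_folds]

    means = {
        m: (np.nanmean(v) if v and not np.all(np.isnan(v)) else -np.inf)
        for m, v in table.items()
    }
    winner = METHOD_PRIORITY[0]
    for m in METHOD_PRIORITY:
        if means[m] > means[winner]:
            winner = m
    return winner, table, {"pls_k": pls_k}


def derive_method_map(
    tree: HierarchyTree,
    X: np.ndarray,
    lineages: Sequence[tuple],
    cfg: CVConfig | None = None,
    seed: int | None = None,
) -> dict[NodeId, dict]:
    """Run method selection at every internal node of the tree.

    Single-offspring nodes are selected on their child-vs-related-classes
    data so every trained node has a map entry.
    """
    cfg = cfg or CVConfig()
    X = np.asarray(X, dtype=float)
    lineages = [tuple(lin) for lin in lineages]
    base = derive_seed(cfg.seed, 2) if seed is None else seed
    mmap: dict[NodeId, dict] = {}
    for i, node in enumerate(tree.internal_nodes):
        groups = hi.stratify_at_node(tree, node, lineages)
        if not groups:
            continue
        if len(groups) >= 2:
            idx = np.concatenate(list(groups.values()))
            labels = []
            for child, ix in groups.items():
                labels.extend([child] * len(ix))
            Xn, yn = X[idx], labels
        else:
            (child, cidx), = groups.items()
            Xs, labels = [X[cidx]], [child] * len(cidx)
            for rc in related_lower_nodes(tree, node):
                ridx = _indices_under(rc, lineages)
                if len(ridx):
                    Xs.append(X[ridx])
                    labels.extend([rc] * len(ridx))
            if len(set(labels)) < 2:
                mmap[node] = {"method": METHOD_PRIORITY[0], "inner_accuracy": {}}
                continue
            Xn, yn = np.vstack(Xs), labels
        try:
            method, table, details = select_method(Xn, yn, cfg, seed=derive_seed(base, i))
        except ValueError:
            method, table, details = METHOD_PRIORITY[0], {}, {}
        mmap[node] = {"method": method, "inner_accuracy": table, **details}
        logger.info("node %s -> %s", hi.format_lineage(node) or "root", method)
    return mmap


# --------------------------------------------------------------------------
# repeated outer CV and confusion reporting


class ConfusionReport:
    """Per-level confusion matrices and accuracies over repeated outer CV.

    ``matrices[level]`` is the mean confusion matrix over repetitions: rows are
    true classes at that level, columns are predicted classes plus a
    ``non_classified`` column; each row sums to the class's test-sample count.
    Accuracies are reported both counting non-classified samples as errors and
    excluding them from the denominator.
    """

    def __init__(self, levels: list[int]):
        self.levels = levels
        self.rep_matrices: dict[int, list[pd.DataFrame]] = {l: [] for l in levels}
        self.accuracies: dict[int, list[float]] = {l: [] for l in levels}
        self.accuracies_excl_nc: dict[int, list[float]] = {l: [] for l in levels}
        self.method_maps: list[dict] = []

    def add_repetition(self, matrices: dict[int, pd.DataFrame]) -> None:
        for lvl, M in matrices.items():
            self.rep_matrices[lvl].append(M)
            correct = float(np.trace(M.loc[:, M.index].values))
            total = float(M.values.sum())
            nc = float(M[NON_CLASSIFIED].sum())
            self.accuracies[lvl].append(100.0 * correct / total)
            self.accuracies_excl_nc[lvl].append(
                100.0 * correct / (total - nc) if total > nc else np.nan
            )

    @property
    def matrices(self) -> dict[int, pd.DataFrame]:
        return {
            lvl: sum(ms) / len(ms) for lvl, ms in self.rep_matrices.items() if ms
        }

    def summary(self) -> pd.DataFrame:
        rows = []
        for lvl in self.levels:
            a = np.asarray(self.accuracies[lvl])
            e = np.asarray(self.accuracies_excl_nc[lvl])
            rows.append(
                {
                    "level": lvl,
                    "mean_accuracy_pct": a.mean(),
                    "sd_accuracy_pct": a.std(),
                    "mean_accuracy_excl_nonclassified_pct": np.nanmean(e),
                    "repetitions": len(a),
                }
            )
        return pd.DataFrame(rows).set_index("level")

    def to_files(self, outdir) -> None:
        import json
        import pathlib

        outdir = pathlib.Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for lvl, M in self.matrices.items():
            M.to_csv(outdir / f"confusion_level{lvl}.csv")
        summ = {
            str(lvl): {
                "mean": float(np.mean(self.accuracies[lvl])),
                "sd": float(np.std(self.accuracies[lvl])),
            }
            for lvl in self.levels
        }
        (outdir / "accuracy_summary.json").write_text(json.dumps(summ, indent=1))


def _level_classes(tree: HierarchyTree, level: int) -> list[str]:
    return [hi.format_lineage(n) for n in tree.nodes if len(n) == level]


def cross_validate(
    tree: HierarchyTree,
    X: np.ndarray,
    lineages: Sequence[tuple],
    cfg: CVConfig | None = None,
    delta: float = 0.0,
) -> ConfusionReport:
    """Repeated stratified outer CV of the full hierarchical classifier.

    Within each outer fold the method map is derived by nested inner CV on the
    training portion alone, the tree of node models is trained on it, and the
    test portion is classified top-down (``delta = 0``: every sample descends
    to a leaf unless a single-offspring node stops it).
    """
    from . import prediction as pr  # local import; prediction imports this module

    cfg = cfg or CVConfig()
    X = np.asarray(X, dtype=float)
    lineages = [tuple(lin) for lin in lineages]
    depth = tree.depth
    levels = list(range(1, depth + 1))
    leaf_key = np.asarray([hi.format_lineage(lin) for lin in lineages])
    eff_out = _effective_folds(cfg.outer_folds, leaf_key, "outer")
    report = ConfusionReport(levels)
    pred_cfg = pr.PredictionConfig(delta=delta)

    for rep in range(cfg.repetitions):
        rep_seed = derive_seed(cfg.seed, rep)
        skf = StratifiedKFold(n_splits=eff_out, shuffle=True, random_state=rep_seed)
        mats = {
            lvl: pd.DataFrame(
                0.0,
                index=_level_classes(tree, lvl),
                columns=_level_classes(tree, lvl) + [NON_CLASSIFIED],
            )
            for lvl in levels
        }
        for fold, (tr, te) in enumerate(skf.split(X, leaf_key)):
            lin_tr = [lineages[i] for i in tr]
            fold_seed = derive_seed(rep_seed, fold)
            mmap = derive_method_map(tree, X[tr], lin_tr, cfg, seed=fold_seed)
            model = train_hcmodel(tree, X[tr], lin_tr, mmap, seed=fold_seed)
            report.method_maps.append(mmap)
            for i in te:
                path = pr.predict_topdown(model, X[i], pred_cfg)
                for lvl in levels:
                    true = hi.format_lineage(lineages[i][:lvl])
                    got = path.assignment_at(lvl)
                    col = NON_CLASSIFIED if got is None else hi.format_lineage(got)
                    mats[lvl].loc[true, col] += 1.0
        report.add_repetition(mats)
        logger.info(
            "repetition %d/%d: %s", rep + 1, cfg.repetitions,
            {lvl: round(report.accuracies[lvl][-1], 1) for lvl in levels},
        )
    return report
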
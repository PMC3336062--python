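"""Hierarchical Models Fusion (HMF).

Validated binary PLS-DA models are chained into an ordered decision tree.
Each node contributes one score axis — the projection of every sample onto
the node's first latent-variable weight vector, after applying the node's
own variable subset and training scaler — so all classes can be visualized
in the joint (Xscore, Yscore, Zscore, ...) space, and new samples are
classified by descending the tree: the sign of the node's coded prediction
routes the sample to a terminal class set or to the next node.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .plsda import PLSDAClassifier, pls_fit

__all__ = [
    "HMFNode",
    "HMFModel",
    "HMFScores",
    "PermutationResult",
    "build_hmf",
    "hmf_scores",
    "hmf_predict",
    "routing_accuracy",
    "permutation_test_hmf",
]

log = logging.getLogger("hmfuse")

_AXIS_NAMES = ["Xscore", "Yscore", "Zscore"]
_ORTHOGONALITY_LIMIT = 0.3


def _axis_name(step: int) -> str:
    return _AXIS_NAMES[step - 1] if step <= len(_AXIS_NAMES) else f"score{step}"


@dataclass
class HMFNode:
    """One binary PLS-DA model inside the hierarchy.

    ``columns`` are indices into the full fused matrix every sample is
    represented in; the classifier was fitted on exactly those columns (its
    internal subset is None).  ``descend_side`` names which side ('A' or
    'B') continues to the next node; the other side is terminal.
    """

    classifier: PLSDAClassifier
    semantics: str
    step: int
    columns: np.ndarray
    variable_names: list | None = None
    descend_side: str = "B"

    def __post_init__(self):
        self.columns = np.asarray(self.columns, dtype=int)
        if self.descend_side not in ("A", "B"):
            raise ValueError("descend_side must be 'A' or 'B'")

    def score(self, X: np.ndarray) -> np.ndarray:
        """First-LV score: scaled node variables times the LV-1 weights."""
        Xs = self.classifier.model.x_scaler.transform(
            np.asarray(X, dtype=float)[:, self.columns]
        )
        return Xs @ self.classifier.model.W[:, 0]

    def coded_prediction(self, X: np.ndarray) -> np.ndarray:
        return self.classifier.decision_function(
            np.asarray(X, dtype=float)[:, self.columns]
        )


@dataclass
class HMFModel:
    """Ordered nodes plus the map from decision paths to class labels."""

    nodes: list
    classes: list
    path_map: dict  # path key "step<i>:<side>" -> list of class labels

    def all_columns(self) -> np.ndarray:
        return np.unique(np.concatenate([n.columns for n in self.nodes]))

    def path_keys(self) -> list:
        keys = []
        for node in self.nodes:
            term = "A" if node.descend_side == "B" else "B"
            keys.append(f"step{node.step}:{term}")
        last = self.nodes[-1]
        keys.append(f"step{last.step}:{last.descend_side}")
        return keys

    def to_json(self, path) -> None:
        tree = {
            "classes": list(self.classes),
            "path_map": {k: list(v) for k, v in self.path_map.items()},
            "nodes": [
                {
                    "step": n.step,
                    "semantics": n.semantics,
                    "class_a": n.classifier.class_a,
                    "class_b": n.classifier.class_b,
                    "descend_side": n.descend_side,
                    "columns": [int(j) for j in n.columns],
                    "variable_names": n.variable_names,
                    "n_components": n.classifier.n_components,
                    "test_accuracy": n.classifier.test_accuracy_,
                    "scaler_mean": n.classifier.model.x_scaler.mean_.tolist(),
                    "scaler_sd": n.classifier.model.x_scaler.sd_.tolist(),
                    "weights_lv1": n.classifier.model.W[:, 0].tolist(),
                    "coefficients": n.classifier.model.B[:, 0].tolist(),
                }
                for n in self.nodes
            ],
        }
        with open(path, "w") as fh:
            json.dump(tree, fh, indent=1)


@dataclass
class HMFScores:
    """Stacked per-node scores with the pairwise-correlation report."""

    frame: pd.DataFrame  # sample rows; one column per axis (+ group if known)
    scores: np.ndarray
    correlations: pd.DataFrame
    warnings: list  # (axis_i, axis_j, r) with |r| above the limit


class UnvalidatedNodeError(RuntimeError):
    """A node classifier lacks a recorded test validation."""


def build_hmf(
    nodes: list,
    classes: list,
    path_map: dict,
    allow_unvalidated: bool = False,
) -> HMFModel:
    """Assemble and check the hierarchy.

    Steps must be consecutive from 1; every class must sit on exactly one
    decision path; every node must carry a recorded test-set validation
    unless ``allow_unvalidated`` is set.
    """
    nodes = sorted(nodes, key=lambda n: n.step)
    steps = [n.step for n in nodes]
    if len(set(steps)) != len(steps):
        raise ValueError(f"duplicate step indices: {steps}")
    if steps != list(range(1, len(nodes) + 1)):
        raise ValueError(f"step indices must be consecutive from 1, got {steps}")
    for n in nodes:
        if n.classifier.test_accuracy_ is None and not allow_unvalidated:
            raise UnvalidatedNodeError(
                f"node step {n.step} ({n.semantics}) has no test validation"
            )
    model = HMFModel(nodes=nodes, classes=list(classes), path_map=dict(path_map))
    valid_keys = set(model.path_keys())
    for key in model.path_map:
        if key not in valid_keys:
            raise ValueError(f"path key {key!r} does not exist in this hierarchy")
    seen: dict = {}
    for key, cls_list in model.path_map.items():
        for c in cls_list:
            if c in seen:
                raise ValueError(f"class {c!r} on two paths: {seen[c]} and {key}")
            seen[c] = key
    missing = [c for c in classes if c not in seen]
    if missing:
        raise ValueError(f"classes on no decision path: {missing}")
    return model


def hmf_scores(model: HMFModel, X, sample_groups=None, sample_ids=None) -> HMFScores:
    """Project every sample through every node's scaler and LV-1 weights."""
    X = np.asarray(X, dtype=float)
    cols = {}
    for node in model.nodes:
        if X.shape[1] <= int(node.columns.max()):
            raise ValueError(
                f"step {node.step} needs column {int(node.columns.max())}, "
                f"matrix has {X.shape[1]}"
            )
        cols[_axis_name(node.step)] = node.score(X)
    scores = np.column_stack(list(cols.values()))
    if not np.all(np.isfinite(scores)):
        raise ValueError("non-finite score produced")
    frame = pd.DataFrame(cols, index=sample_ids)
    if sample_groups is not None:
        frame.insert(0, "group", np.asarray(sample_groups))
    names = list(cols.keys())
    corr = pd.DataFrame(np.corrcoef(scores, rowvar=False), index=names, columns=names)
    warns = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            r = float(corr.iloc[i, j])
            if abs(r) > _ORTHOGONALITY_LIMIT:
                warns.append((names[i], names[j], r))
                log.warning(
                    "score axes %s and %s are not orthogonal (r=%.3f)",
                    names[i], names[j], r,
                )
    return HMFScores(frame=frame, scores=scores, correlations=corr, warnings=warns)


def hmf_predict(model: HMFModel, X):
    """Descend the tree; ties (coded y exactly 0) go to the class-B side.

    Returns (labels, paths, scores): per sample the terminal label (classes
    of the terminal path, joined with '|' when the path holds several), the
    path key, and the per-step score matrix.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    n = X.shape[0]
    paths = np.empty(n, dtype=object)
    labels = np.empty(n, dtype=object)
    scores = np.column_stack([node.score(X) for node in model.nodes])
    active = np.arange(n)
    for k, node in enumerate(model.nodes):
        if active.size == 0:
            break
        coded = node.coded_prediction(X[active])
        side_b = coded >= 0.0
        sides = np.where(side_b, "B", "A")
        last = k == len(model.nodes) - 1
        stay = np.zeros(active.size, dtype=bool)
        for s in ("A", "B"):
            m = sides == s
            if s == node.descend_side and not last:
                stay |= m
                continue
            key = f"step{node.step}:{s}"
            cls = model.path_map.get(key, [])
            lab = "|".join(cls) if cls else key
            for idx in active[m]:
                paths[idx] = key
                labels[idx] = lab
        active = active[stay]
    return labels, paths, scores


def routing_accuracy(model: HMFModel, X, true_labels):
    """Fraction of samples whose terminal path contains their true class."""
    true_labels = np.asarray(true_labels)
    labels, paths, _ = hmf_predict(model, X)
    ok = np.array(
        [
            t in model.path_map.get(p, [])
            for t, p in zip(true_labels, paths)
        ]
    )
    return float(ok.mean()), ok


@dataclass
class PermutationResult:
    p_value: float
    observed: float
    null: np.ndarray
    n_perm: int
    statistic: str


def _hmf_statistic(model, X, rows, labels, statistic):
    acc, ok = routing_accuracy(model, X[rows], labels[rows])
    if statistic == "overall":
        return acc
    per = []
    for c in np.unique(labels[rows]):
        m = labels[rows] == c
        per.append(float(ok[m].mean()))
    return float(np.mean(per))


def _refit_nodes(model: HMFModel, X, labels, train_rows):
    """Refit each node on its fixed columns for a new label vector."""
    from .plsda import fit_binary_plsda

    new_nodes = []
    for node in model.nodes:
        ga, gb = node.classifier.class_a, node.classifier.class_b
        rows = train_rows[np.isin(labels[train_rows], [ga, gb])]
        clf = fit_binary_plsda(
            X[rows][:, node.columns],
            labels[rows],
            class_a=ga,
            class_b=gb,
            n_components=node.classifier.n_components,
        )
        clf.test_accuracy_ = 0.0  # marker only; permutation models are throwaway
        new_nodes.append(
            HMFNode(
                classifier=clf,
                semantics=node.semantics,
                step=node.step,
                columns=node.columns,
                variable_names=node.variable_names,
                descend_side=node.descend_side,
            )
        )
    return HMFModel(nodes=new_nodes, classes=model.classes, path_map=model.path_map)


def permutation_test_hmf(
    model: HMFModel,
    X,
    labels,
    train_rows,
    test_rows,
    n_perm: int = 999,
    seed: int = 0,
    statistic: str = "overall",
) -> PermutationResult:
    """Label-permutation null for the HMF classification statistic.

    Class labels are permuted within the training set and within the test
    set separately: permuting across the fixed train/test boundary would
    change the class composition of each set and break the exchangeability
    of the observed statistic with the null draws.  The node classifiers
    are refitted on their FIXED variable subsets (selection is not rerun;
    documented choice), and the statistic is recomputed on the test rows.
    p = (1 + #{null >= observed}) / (1 + n_perm); ties between null and
    observed values are broken by a seeded infinitesimal jitter so the
    p-value is exactly uniform under the null.
    """
    if statistic not in ("overall", "mean_per_class"):
        raise ValueError("statistic must be 'overall' or 'mean_per_class'")
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    train_rows = np.asarray(train_rows, dtype=int)
    test_rows = np.asarray(test_rows, dtype=int)
    rng = np.random.default_rng(seed)
    observed = _hmf_statistic(model, X, test_rows, labels, statistic)
    null = np.empty(n_perm)
    for b in range(n_perm):
        perm = labels.copy()
        perm[train_rows] = labels[train_rows][rng.permutation(train_rows.size)]
        perm[test_rows] = labels[test_rows][rng.permutation(test_rows.size)]
        pm = _refit_nodes(model, X, perm, train_rows)
        null[b] = _hmf_statistic(pm, X, test_rows, perm, statistic)
    jitter = rng.uniform(0.0, 1e-9, size=n_perm + 1)
    obs_j = observed + jitter[0]
    null_j = null + jitter[1:]
    p = (1.0 + float(np.sum(null_j >= obs_j))) / (1.0 + n_perm)
    return PermutationResult(
        p_value=p, observed=observed, null=null, n_perm=n_perm, statistic=statistic
    )
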
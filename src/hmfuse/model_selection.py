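"""Duplex train/test splitting, classification metrics and orchestration."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import autoscale_fit_tolerant

__all__ = [
    "SplitPlan",
    "ClassificationReport",
    "duplex_split",
    "correct_classification",
    "expected_random_accuracy",
    "run_experiment",
]

log = logging.getLogger("hmfuse")


@dataclass
class SplitPlan:
    """Disjoint train/test indices with a per-class breakdown."""

    train_indices: np.ndarray
    test_indices: np.ndarray
    test_fraction: float
    per_class: dict = field(default_factory=dict)  # label -> (train idx, test idx)

    def __post_init__(self):
        tr = set(self.train_indices.tolist())
        te = set(self.test_indices.tolist())
        if tr & te:
            raise ValueError("train and test sets overlap")

    def to_dict(self) -> dict:
        return {
            "train": [int(i) for i in self.train_indices],
            "test": [int(i) for i in self.test_indices],
            "test_fraction": self.test_fraction,
        }


@dataclass
class ClassificationReport:
    """Overall and per-class percent correct plus a confusion table."""

    overall_pct: float
    per_class_pct: dict
    confusion: pd.DataFrame  # rows = true, columns = predicted
    n: int

    def to_dict(self) -> dict:
        return {
            "overall_pct": self.overall_pct,
            "per_class_pct": self.per_class_pct,
            "confusion": self.confusion.to_dict(),
            "n": self.n,
        }


def _duplex_one_class(D: np.ndarray, n_test: int) -> tuple[list, list]:
    """Duplex on one class given its pairwise distance matrix.

    Alternately assigns the two mutually farthest remaining points, first
    pair to TRAINING, until the test set holds n_test points; leftovers go
    to training.  Within a round, the point farther from the pair's partner
    (lower index on ties) comes first — the order inside a pair does not
    affect membership.
    """
    m = D.shape[0]
    remaining = list(range(m))
    train: list = []
    test: list = []
    to_train = True
    while remaining:
        target = train if to_train else test
        if not to_train and len(test) >= n_test:
            train.extend(remaining)
            break
        if len(remaining) == 1:
            target.append(remaining.pop())
            to_train = not to_train
            continue
        sub = D[np.ix_(remaining, remaining)]
        flat = int(np.argmax(sub))
        a, b = divmod(flat, len(remaining))
        i, j = remaining[a], remaining[b]
        if i > j:
            i, j = j, i
        target.extend([i, j])
        remaining.remove(i)
        remaining.remove(j)
        to_train = not to_train
    if len(test) > n_test:  # the last pair may overshoot by one
        train.append(test.pop())
    return train, test


def duplex_split(X, labels, test_fraction: float) -> SplitPlan:
    """Deterministic per-class Duplex split on autoscaled data.

    Per class, the quota of test samples is round(fraction * n) with
    round-half-up (minimum 1 when the fraction is positive); pairs of
    mutually farthest samples are assigned alternately to training first,
    then test.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    if not 0.0 <= test_fraction < 1.0:
        raise ValueError("test_fraction must be in [0, 1)")
    if X.shape[0] != labels.size:
        raise ValueError("X and labels disagree on the sample count")
    Xs, _ = autoscale_fit_tolerant(X)
    train_all: list = []
    test_all: list = []
    per_class: dict = {}
    for cls in pd.unique(labels):
        idx = np.flatnonzero(labels == cls)
        if idx.size < 4:
            raise ValueError(f"class {cls!r} has fewer than 4 samples")
        if test_fraction == 0.0:
            n_test = 0
        else:
            n_test = max(1, int(np.floor(test_fraction * idx.size + 0.5)))
        diff = Xs[idx][:, None, :] - Xs[idx][None, :, :]
        D = np.sqrt((diff**2).sum(axis=2))
        tr, te = _duplex_one_class(D, n_test)
        tr_idx = idx[np.array(tr, dtype=int)] if tr else np.empty(0, dtype=int)
        te_idx = idx[np.array(te, dtype=int)] if te else np.empty(0, dtype=int)
        per_class[cls] = (np.sort(tr_idx), np.sort(te_idx))
        train_all.extend(tr_idx.tolist())
        test_all.extend(te_idx.tolist())
    return SplitPlan(
        train_indices=np.sort(np.array(train_all, dtype=int)),
        test_indices=np.sort(np.array(test_all, dtype=int)),
        test_fraction=float(test_fraction),
        per_class=per_class,
    )


def correct_classification(pred, true, classes=None) -> ClassificationReport:
    """Percent correct overall and per class, plus the confusion table."""
    pred = np.asarray(pred)
    true = np.asarray(true)
    if pred.size != true.size:
        raise ValueError("pred and true lengths differ")
    if pred.size == 0:
        raise ValueError("empty prediction vector")
    if classes is None:
        classes = sorted(set(true.tolist()) | set(pred.tolist()))
    conf = pd.DataFrame(0, index=classes, columns=classes, dtype=int)
    for t, p in zip(true, pred):
        conf.loc[t, p] += 1
    per_class = {}
    for c in classes:
        nc = int((true == c).sum())
        if nc:
            per_class[c] = 100.0 * float(((true == c) & (pred == true)).sum()) / nc
    overall = 100.0 * float((pred == true).sum()) / true.size
    return ClassificationReport(
        overall_pct=overall, per_class_pct=per_class, confusion=conf, n=int(true.size)
    )


def expected_random_accuracy(n_classes: int) -> float:
    """Expected percent correct of a uniform random classifier."""
    if n_classes < 1:
        raise ValueError("need at least one class")
    return 100.0 / n_classes


# ----------------------------------------------------------------------
def run_experiment(
    seed: int = 7,
    outdir=None,
    n_per_group: int = 14,
    test_fraction: float = 0.25,
    n_perm: int = 0,
    config=None,
    svm_c: float = 1.0,
):
    """End-to-end pipeline on the default synthetic study.

    simulate -> preprocess both blocks -> one Duplex split on the fused bin
    matrix -> per-block SVM-RFE selection per contrast -> mid-level fusion
    with re-selection -> binary PLS-DA node models -> HMF build/validate ->
    optional permutation test.  Returns a results dict; when ``outdir`` is
    given, artifacts are written there as CSV/JSON.
    """
    from . import fusion as fus
    from . import hmf as hmfmod
    from .feature_selection import loocv_select
    from .plsda import fit_binary_plsda, fit_pls2da
    from .preprocess import preprocess_block
    from .synthetic import default_config, simulate_study

    stage = "simulate"
    try:
        cfg = config if config is not None else default_config(seed=seed,
                                                               n_per_group=n_per_group)
        block_a, block_b, truth = simulate_study(cfg)

        stage = "preprocess"
        bins_a = preprocess_block(block_a)
        bins_b = preprocess_block(block_b)
        log.info("bins: %s=%d, %s=%d", block_a.block_id, bins_a.values.shape[1],
                 block_b.block_id, bins_b.values.shape[1])

        stage = "split"
        groups = bins_a.metadata["group"].to_numpy()
        fused_raw = np.hstack([bins_a.values.to_numpy(), bins_b.values.to_numpy()])
        split = duplex_split(fused_raw, groups, test_fraction)
        tr, te = split.train_indices, split.test_indices

        stage = "select+fuse+fit"
        contrasts = [("C10", "P10"), ("P10", "N10"), ("N10", "N14")]
        nodes = []
        results_models = {}
        for step, (ga, gb) in enumerate(contrasts, start=1):
            pair_tr = tr[np.isin(groups[tr], [ga, gb])]
            pair_te = te[np.isin(groups[te], [ga, gb])]
            y = np.where(groups == gb, 1.0, -1.0)
            sel = {}
            block_acc = {}
            for tab in (bins_a, bins_b):
                M = tab.values.to_numpy()
                Ms, _ = autoscale_fit_tolerant(M[pair_tr])
                s = loocv_select(
                    Ms, y[pair_tr], C=svm_c, seed=seed + step,
                    variable_names=tab.labels,
                )
                sel[tab.block_id] = s
                bclf = fit_binary_plsda(
                    M[pair_tr][:, s.selected], groups[pair_tr],
                    class_a=ga, class_b=gb,
                )
                block_acc[tab.block_id] = bclf.validate(
                    M[pair_te][:, s.selected], groups[pair_te]
                )
            fused, fused_sel = fus.fuse_and_select(
                bins_a, sel[bins_a.block_id], bins_b, sel[bins_b.block_id],
                groups, (ga, gb), train_rows=pair_tr, C=svm_c, seed=seed + 10 + step,
            )
            node_cols = fused.column_indices[fused_sel.selected]
            node_names = [fused.variable_names[j] for j in fused_sel.selected]
            clf = fit_binary_plsda(
                fused_raw[pair_tr][:, node_cols],
                groups[pair_tr],
                class_a=ga,
                class_b=gb,
                variable_names=node_names,
            )
            acc = clf.validate(fused_raw[pair_te][:, node_cols], groups[pair_te])
            clf_1lv = fit_binary_plsda(
                fused_raw[pair_tr][:, node_cols], groups[pair_tr],
                class_a=ga, class_b=gb, n_components=1,
            )
            acc_1lv = clf_1lv.validate(fused_raw[pair_te][:, node_cols],
                                       groups[pair_te])
            results_models[f"{ga}_vs_{gb}"] = {
                "n_selected": int(fused_sel.selected.size),
                "n_components": clf.n_components,
                "test_accuracy": acc,
                "test_accuracy_1lv": acc_1lv,
                "single_block_test_accuracy": block_acc,
            }
            nodes.append(
                hmfmod.HMFNode(
                    classifier=clf,
                    semantics=f"{ga} vs {gb}",
                    step=step,
                    columns=node_cols,
                    variable_names=node_names,
                )
            )

        stage = "hmf"
        path_map = {
            "step1:A": ["C10", "C14", "P14"],
            "step2:A": ["P10"],
            "step3:A": ["N10"],
            "step3:B": ["N14"],
        }
        model = hmfmod.build_hmf(nodes, classes=list(cfg.groups), path_map=path_map)
        scores = hmfmod.hmf_scores(
            model, fused_raw, sample_groups=groups,
            sample_ids=list(bins_a.metadata.index),
        )
        routing_acc, routed_ok = hmfmod.routing_accuracy(
            model, fused_raw[te], groups[te]
        )

        stage = "pls2da"
        pls2 = fit_pls2da(fused_raw[tr][:, model.all_columns()], groups[tr],
                          max_components=6)
        pls2_acc = float(np.mean(
            pls2.predict(fused_raw[te][:, model.all_columns()]) == groups[te]))

        perm = None
        if n_perm:
            stage = "permutation"
            perm = hmfmod.permutation_test_hmf(
                model, fused_raw, groups, tr, te, n_perm=n_perm, seed=seed
            )

        out = {
            "seed": seed,
            "n_bins": {bins_a.block_id: bins_a.values.shape[1],
                       bins_b.block_id: bins_b.values.shape[1]},
            "split": split.to_dict(),
            "models": results_models,
            "hmf_routing_accuracy": routing_acc,
            "score_correlations": scores.correlations.to_dict(),
            "score_warnings": scores.warnings,
            "pls2da_test_accuracy": pls2_acc,
            "permutation": None if perm is None else {
                "p_value": perm.p_value, "observed": perm.observed,
                "n_perm": perm.n_perm,
            },
        }
        if outdir is not None:
            stage = "write"
            outdir = Path(outdir)
            outdir.mkdir(parents=True, exist_ok=True)
            bins_a.write(outdir / "bins_blockA.csv", outdir / "bins_blockA.json")
            bins_b.write(outdir / "bins_blockB.csv", outdir / "bins_blockB.json")
            truth.to_json(outdir / "ground_truth.json")
            scores.frame.to_csv(outdir / "hmf_scores.csv")
            model.to_json(outdir / "hmf_model.json")
            with open(outdir / "results.json", "w") as fh:
                json.dump(out, fh, indent=1, default=str)
        # attach the per-sample score frame after the JSON dump (not serializable)
        out["scores"] = scores.frame
        return out
    except Exception as exc:
        raise RuntimeError(f"experiment failed at stage '{stage}': {exc}") from exc
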
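import json

import numpy as np
import pytest

from hmfuse.hmf import (
    HMFNode,
    UnvalidatedNodeError,
    build_hmf,
    hmf_predict,
    hmf_scores,
    permutation_test_hmf,
    routing_accuracy,
)
from hmfuse.plsda import fit_binary_plsda


def _three_class_data(seed=0, n_per=8, sep=4.0):
    """Classes c1 < c2 < c3 along feature 0; features 1-3 are noise."""
    rng = np.random.default_rng(seed)
    labels = np.repeat(np.array(["c1", "c2", "c3"], dtype=object), n_per)
    X = rng.normal(0, 0.3, size=(3 * n_per, 4))
    X[:, 0] += np.repeat([0.0, sep, 2 * sep], n_per)
    train = np.concatenate([np.arange(i * n_per, i * n_per + n_per - 2) for i in range(3)])
    test = np.setdiff1d(np.arange(3 * n_per), train)
    return X, labels, train, test


def _node(X, labels, train, test, cols, a, b, step, validate=True):
    rows = train[np.isin(labels[train], [a, b])]
    clf = fit_binary_plsda(X[np.ix_(rows, cols)], labels[rows], class_a=a, class_b=b)
    if validate:
        vrows = test[np.isin(labels[test], [a, b])]
        clf.validate(X[np.ix_(vrows, cols)], labels[vrows])
    return HMFNode(
        classifier=clf, semantics=f"{a} vs {b}", step=step, columns=np.array(cols)
    )


def _two_node_model(seed=0):
    X, labels, train, test = _three_class_data(seed=seed)
    n1 = _node(X, labels, train, test, [0, 1], "c1", "c2", step=1)
    n2 = _node(X, labels, train, test, [0, 2], "c2", "c3", step=2)
    path_map = {"step1:A": ["c1"], "step2:A": ["c2"], "step2:B": ["c3"]}
    model = build_hmf([n1, n2], ["c1", "c2", "c3"], path_map)
    return model, X, labels, train, test


# ---------------------------------------------------------------- construction
def test_build_hmf_rejects_bad_hierarchies():
    X, labels, train, test = _three_class_data()
    n1 = _node(X, labels, train, test, [0], "c1", "c2", step=1)
    n2 = _node(X, labels, train, test, [0], "c2", "c3", step=2)
    ok_map = {"step1:A": ["c1"], "step2:A": ["c2"], "step2:B": ["c3"]}
    classes = ["c1", "c2", "c3"]

    dup = _node(X, labels, train, test, [0], "c2", "c3", step=1)
    with pytest.raises(ValueError, match="duplicate"):
        build_hmf([n1, dup], classes, ok_map)
    n3 = _node(X, labels, train, test, [0], "c2", "c3", step=3)
    with pytest.raises(ValueError, match="consecutive"):
        build_hmf([n1, n3], classes, ok_map)
    with pytest.raises(ValueError, match="path key"):
        build_hmf([n1, n2], classes, {**ok_map, "step9:A": ["c1"]})
    with pytest.raises(ValueError, match="two paths"):
        build_hmf([n1, n2], classes, {"step1:A": ["c1"], "step2:A": ["c1"], "step2:B": ["c3"]})
    with pytest.raises(ValueError, match="no decision path"):
        build_hmf([n1, n2], classes, {"step1:A": ["c1"], "step2:B": ["c3"]})


def test_unvalidated_node_rejected_unless_allowed():
    X, labels, train, test = _three_class_data()
    n1 = _node(X, labels, train, test, [0], "c1", "c2", step=1, validate=False)
    with pytest.raises(UnvalidatedNodeError):
        build_hmf([n1], ["c1", "c2"], {"step1:A": ["c1"], "step1:B": ["c2"]})
    model = build_hmf(
        [n1], ["c1", "c2"], {"step1:A": ["c1"], "step1:B": ["c2"]},
        allow_unvalidated=True,
    )
    assert model.path_keys() == ["step1:A", "step1:B"]


# ---------------------------------------------------------------- scores
def test_single_node_scores_match_node_score_and_training_lv1():
    X, labels, train, test = _three_class_data(seed=1)
    node = _node(X, labels, train, test, [0, 1], "c1", "c2", step=1)
    model = build_hmf([node], ["c1", "c2"], {"step1:A": ["c1"], "step1:B": ["c2"]})
    sc = hmf_scores(model, X, sample_groups=labels)
    assert np.allclose(sc.scores[:, 0], node.score(X))
    assert list(sc.frame.columns) == ["group", "Xscore"]
    # on the training samples the node score is the model's first LV score
    rows = train[np.isin(labels[train], ["c1", "c2"])]
    T = node.classifier.model.transform(X[np.ix_(rows, [0, 1])])
    assert np.max(np.abs(node.score(X[rows]) - T[:, 0])) < 1e-10


def test_node_scores_are_independent_of_other_nodes():
    model, X, labels, train, test = _two_node_model(seed=2)
    sc_full = hmf_scores(model, X)
    single = build_hmf(
        [model.nodes[0]], ["c1", "c2"], {"step1:A": ["c1"], "step1:B": ["c2"]}
    )
    sc_one = hmf_scores(single, X)
    assert np.array_equal(sc_full.scores[:, 0], sc_one.scores[:, 0])


def test_orthogonality_warning_above_limit():
    X, labels, train, test = _three_class_data(seed=3)
    # both nodes read the same dominating feature -> strongly correlated axes
    n1 = _node(X, labels, train, test, [0], "c1", "c2", step=1)
    n2 = _node(X, labels, train, test, [0], "c2", "c3", step=2)
    model = build_hmf(
        [n1, n2], ["c1", "c2", "c3"],
        {"step1:A": ["c1"], "step2:A": ["c2"], "step2:B": ["c3"]},
    )
    sc = hmf_scores(model, X)
    assert sc.warnings, "expected an orthogonality warning"
    axis_i, axis_j, r = sc.warnings[0]
    assert (axis_i, axis_j) == ("Xscore", "Yscore")
    assert abs(r) > 0.3
    assert abs(sc.correlations.loc[axis_i, axis_j] - r) < 1e-12


# ---------------------------------------------------------------- prediction
def test_hmf_predict_routes_all_classes():
    model, X, labels, train, test = _two_node_model(seed=4)
    pred, paths, scores = hmf_predict(model, X[test])
    assert np.all(pred == labels[test])
    acc, ok = routing_accuracy(model, X[test], labels[test])
    assert acc == 1.0 and ok.all()
    assert scores.shape == (test.size, 2)
    # paths follow the map
    assert set(paths) <= {"step1:A", "step2:A", "step2:B"}


def test_hmf_predict_tie_goes_to_b_side():
    # symmetric one-variable problem: the training mean is exactly 0, so a
    # sample at 0 has coded prediction exactly 0 and must route to side B
    X = np.array([[-1.0], [-1.0], [1.0], [1.0]])
    labels = np.array(["a", "a", "b", "b"], dtype=object)
    clf = fit_binary_plsda(X, labels, class_a="a", class_b="b")
    clf.validate(X, labels)
    node = HMFNode(classifier=clf, semantics="a vs b", step=1, columns=np.array([0]))
    model = build_hmf([node], ["a", "b"], {"step1:A": ["a"], "step1:B": ["b"]})
    assert float(node.coded_prediction(np.array([[0.0]]))[0]) == 0.0
    pred, paths, _ = hmf_predict(model, np.array([[0.0]]))
    assert pred[0] == "b" and paths[0] == "step1:B"


def test_hmf_json_export(tmp_path):
    model, X, labels, train, test = _two_node_model(seed=5)
    path = tmp_path / "hmf.json"
    model.to_json(path)
    tree = json.loads(path.read_text())
    assert tree["classes"] == ["c1", "c2", "c3"]
    assert len(tree["nodes"]) == 2
    n0 = tree["nodes"][0]
    assert n0["step"] == 1 and n0["class_a"] == "c1"
    assert len(n0["weights_lv1"]) == len(n0["columns"])


# ---------------------------------------------------------------- permutation
def test_permutation_min_p_on_separable_data():
    model, X, labels, train, test = _two_node_model(seed=6)
    res = permutation_test_hmf(
        model, X, labels, train, test, n_perm=99, seed=0
    )
    assert res.observed == 1.0
    assert res.p_value == pytest.approx(1.0 / 100.0)
    assert res.null.shape == (99,)
    assert res.null.max() < 1.0


def test_permutation_determinism_and_validation():
    model, X, labels, train, test = _two_node_model(seed=7)
    r1 = permutation_test_hmf(model, X, labels, train, test, n_perm=99, seed=3)
    r2 = permutation_test_hmf(model, X, labels, train, test, n_perm=99, seed=3)
    assert r1.p_value == r2.p_value
    assert np.array_equal(r1.null, r2.null)
    with pytest.raises(ValueError, match="n_perm"):
        permutation_test_hmf(model, X, labels, train, test, n_perm=50)
    with pytest.raises(ValueError, match="statistic"):
        permutation_test_hmf(model, X, labels, train, test, n_perm=99, statistic="zzz")


def test_hmf_scores_column_bound_check():
    model, X, labels, train, test = _two_node_model(seed=8)
    with pytest.raises(ValueError, match="column"):
        hmf_scores(model, X[:, :1])
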
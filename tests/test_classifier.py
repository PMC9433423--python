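"""Bagged decision trees with surrogate splits, CV reports, importances."""
import numpy as np
import pandas as pd
import pytest

from noxpipe import classify, trees


def _toy_table(n_infants=30, informative=True, seed=0, extra_noise=0):
    """Paired-event table: one informative feature plus noise features."""
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_infants):
        pma = rng.uniform(28, 40) * 7
        for label, shift in (("noxious", 1.5), ("nonnoxious", 0.0)):
            row = {"infant_id": f"i{i:03d}", "label": label, "pma": pma,
                   "signal": rng.standard_normal()
                   + (shift if informative else 0.0)}
            for k in range(extra_noise):
                row[f"noise{k}"] = rng.standard_normal()
            rows.append(row)
    return pd.DataFrame(rows)


def test_training_separates_perfect_feature():
    table = _toy_table(20, seed=1)
    table["signal"] = np.where(table["label"] == "noxious", 5.0, -5.0)
    X = table[["signal", "pma"]].to_numpy(float)
    model = trees.train_bagged_trees(X, table["label"], ["signal", "pma"],
                                     n_trees=25, seed=0)
    labels, frac = trees.predict(model, X)
    assert np.all(labels == table["label"].to_numpy())
    assert set(frac) <= {0.0, 1.0}  # unanimous trees on separable data


def test_shuffled_labels_give_chance_accuracy():
    rng = np.random.default_rng(2)
    table = _toy_table(40, informative=True, seed=2, extra_noise=2)
    table["label"] = rng.permutation(table["label"].to_numpy())
    rep = classify.loo_by_infant_cv(
        table, feature_names=["signal", "noise0", "noise1", "pma"],
        n_trees=60, seed=0)
    assert 0.30 < rep.accuracy < 0.70  # wide binomial band around 0.5


def test_surrogate_split_routes_correlated_feature():
    """Rows missing the primary separator are routed by a correlated
    surrogate and reproduce (almost all of) the complete-data
    predictions.

    For bivariate-normal features with correlation r the best surrogate
    can agree with the primary sign rule on at most
    1 - arccos(r)/pi of rows (~0.899 at r = 0.95); the routed
    predictions must reach that ceiling up to sampling error.
    """
    rng = np.random.default_rng(3)
    n = 400
    r = 0.95
    x1 = rng.standard_normal(n)
    x2 = r * x1 + np.sqrt(1 - r ** 2) * rng.standard_normal(n)
    y = np.where(x1 > 0, "noxious", "nonnoxious")
    X = np.column_stack([x1, x2])
    model = trees.train_bagged_trees(X, y, ["x1", "x2"], n_trees=40, seed=0)
    complete, _ = trees.predict(model, X)
    X_missing = X.copy()
    X_missing[:, 0] = np.nan
    routed, _ = trees.predict(model, X_missing)
    ceiling = 1 - np.arccos(r) / np.pi           # ~0.899
    se = np.sqrt(ceiling * (1 - ceiling) / n)    # ~0.015
    assert np.mean(routed == complete) >= ceiling - 2 * se


def test_predict_handles_mostly_missing_row():
    table = _toy_table(15, seed=4)
    feats = ["signal", "pma"]
    model = trees.train_bagged_trees(table[feats].to_numpy(float),
                                     table["label"], feats, n_trees=15, seed=0)
    row = np.array([[np.nan, 30 * 7.0]])
    labels, frac = trees.predict(model, row)
    assert labels[0] in ("noxious", "nonnoxious")
    assert 0.0 <= frac[0] <= 1.0


def test_two_tree_votes_hand_traced():
    # separable 1-D data: every tree learns the same single split, so the
    # ensemble vote can be traced by hand through the node records
    X = np.array([[0.0], [1.0], [2.0], [10.0], [11.0], [12.0]])
    y = np.array(["nonnoxious"] * 3 + ["noxious"] * 3)
    model = trees.train_bagged_trees(X, y, ["x"], n_trees=2, min_leaf=1,
                                     seed=5)
    for t in range(2):
        tr = model.trees[t].tree_
        assert tr.node_count == 3
        assert 2.0 < tr.threshold[0] < 10.0
    labels, frac = trees.predict(model, np.array([[1.5], [11.5]]))
    assert list(labels) == ["nonnoxious", "noxious"]
    np.testing.assert_array_equal(frac, [0.0, 1.0])


def test_training_input_validation():
    X = np.zeros((4, 2))
    with pytest.raises(ValueError):
        trees.train_bagged_trees(X, ["noxious"] * 4, n_trees=2)
    Xn = np.random.default_rng(0).standard_normal((10, 2))
    Xn[:, 1] = np.nan
    with pytest.warns(UserWarning, match="entirely missing"):
        model = trees.train_bagged_trees(
            Xn, ["noxious"] * 5 + ["nonnoxious"] * 5, ["a", "b"],
            n_trees=5, seed=0)
    used = {model.trees[t].tree_.feature[0] for t in range(5)}
    assert 1 not in used  # the all-missing predictor is never split on


def test_training_determinism():
    table = _toy_table(20, seed=6, extra_noise=1)
    feats = ["signal", "noise0", "pma"]
    kw = dict(feature_names=feats, n_trees=30, seed=11)
    X = table[feats].to_numpy(float)
    m1 = trees.train_bagged_trees(X, table["label"], **kw)
    m2 = trees.train_bagged_trees(X, table["label"], **kw)
    p1, f1 = trees.predict(m1, X)
    p2, f2 = trees.predict(m2, X)
    np.testing.assert_array_equal(f1, f2)
    np.testing.assert_array_equal(m1.inbag_indices[0], m2.inbag_indices[0])


# ----------------------------------------------------------------- reports

def test_binomial_ci_reproduces_printed_intervals():
    lo, hi = classify.binomial_ci(74, 94)
    assert (round(lo, 2), round(hi, 2)) == (0.70, 0.87)
    lo, hi = classify.binomial_ci(124, 148)
    assert (round(lo, 2), round(hi, 2)) == (0.78, 0.90)
    lo, hi = classify.binomial_ci(50, 100)
    assert lo == pytest.approx(0.402, abs=5e-4)
    assert hi == pytest.approx(0.598, abs=5e-4)
    with pytest.raises(ValueError):
        classify.binomial_ci(1, 0)
    with pytest.raises(ValueError):
        classify.binomial_ci(5, 4)


def test_confusion_report_identity():
    rep = classify.report_from_confusion(13, 7, 47)
    assert rep.accuracy == pytest.approx(1 - (rep.fpr + rep.fnr) / 2)
    assert rep.accuracy == pytest.approx(74 / 94)
    assert rep.n_obs == 94


def test_subgroup_accuracy_conventions():
    pred = pd.DataFrame({
        "infant_id": [f"i{k}" for k in range(8)],
        "label": ["noxious"] * 8,
        "predicted": ["noxious"] * 6 + ["nonnoxious"] * 2,
        "pma": [29 * 7, 30 * 7, 31.0 * 7, 33 * 7, 35 * 7, 36 * 7,
                38 * 7, 39 * 7],
    })
    out = classify.subgroup_accuracy(pred)
    # infant at exactly 31.0 weeks belongs to [31, 34)
    assert out.loc[0, "n_obs"] == 2 and out.loc[1, "n_obs"] == 2
    # hand-tallied: errors are the two oldest infants
    np.testing.assert_allclose(out["accuracy"], [1.0, 1.0, 1.0, 0.0])
    assert not out.loc[0, "reliable"]  # fewer than 3 infants


def test_subgroup_uniform_accuracy_equals_overall():
    rng = np.random.default_rng(7)
    n = 400
    pred = pd.DataFrame({
        "infant_id": [f"i{k}" for k in range(n)],
        "label": ["noxious"] * n,
        "predicted": ["noxious"] * n,
        "pma": rng.uniform(28, 40, n) * 7,
    })
    out = classify.subgroup_accuracy(pred)
    np.testing.assert_allclose(out["accuracy"], 1.0)


# ------------------------------------------------------------- importances

def test_oob_importance_ranks_informative_feature():
    table = _toy_table(40, seed=8, extra_noise=3)
    feats = ["signal", "noise0", "noise1", "noise2", "pma"]
    model = trees.train_bagged_trees(table[feats].to_numpy(float),
                                     table["label"], feats, n_trees=80, seed=0)
    imp = classify.oob_importance(model, seed=0)
    assert max(imp, key=imp.get) == "signal"
    for k in ("noise0", "noise1", "noise2"):
        assert imp[k] < imp["signal"]


def test_oob_importance_pure_noise_near_zero():
    zs = []
    for seed in range(12):
        table = _toy_table(20, informative=False, seed=seed, extra_noise=1)
        feats = ["signal", "noise0", "pma"]
        model = trees.train_bagged_trees(table[feats].to_numpy(float),
                                         table["label"], feats,
                                         n_trees=40, seed=seed)
        imp = classify.oob_importance(model, seed=seed)
        zs.append(imp["noise0"])
    assert abs(np.mean(zs)) < 2.0 / np.sqrt(len(zs)) * 3


def test_heldout_importance_contracts():
    train = _toy_table(30, seed=9, extra_noise=1)
    test = _toy_table(16, seed=10, extra_noise=1)
    test["constant"] = 1.0
    train["constant"] = 1.0
    feats = ["signal", "noise0", "constant", "pma"]
    model = trees.train_bagged_trees(train[feats].to_numpy(float),
                                     train["label"], feats, n_trees=40, seed=0)
    with pytest.warns(UserWarning, match="zero importance"):
        imp = classify.heldout_permutation_importance(model, test, n_perm=5,
                                                      seed=0)
    assert imp["constant"] == 0.0  # permuting a constant changes nothing
    assert imp["signal"] > imp["noise0"]
    with pytest.raises(ValueError):
        classify.heldout_permutation_importance(model, test.iloc[:3])


def test_heldout_importance_single_perm_matches_direct_oracle():
    train = _toy_table(20, seed=11)
    test = _toy_table(10, seed=12)
    feats = ["signal", "pma"]
    model = trees.train_bagged_trees(train[feats].to_numpy(float),
                                     train["label"], feats, n_trees=10, seed=0)
    imp = classify.heldout_permutation_importance(model, test, n_perm=1,
                                                  seed=123)
    # direct recomputation with the same permutation stream
    rng = np.random.default_rng(123)
    X = test[feats].to_numpy(float)
    y = trees.encode_labels(test["label"].to_numpy())
    perm = rng.permutation(X.shape[0])
    drops = np.zeros((10, len(feats)))
    for t in range(10):
        base = np.mean(trees.predict_tree(model, t, X) == y)
        for j in range(len(feats)):
            Xp = X.copy()
            Xp[:, j] = Xp[perm, j]
            drops[t, j] = base - np.mean(trees.predict_tree(model, t, Xp) == y)
    expected = drops.mean(axis=0) / drops.std(axis=0, ddof=1)
    for j, name in enumerate(feats):
        assert imp[name] == pytest.approx(expected[j])


# ----------------------------------------------------------- feature table

def test_assemble_features_contracts(default_table):
    assert len(default_table) == 94
    assert list(default_table.columns[2:]) == classify.FEATURE_NAMES
    assert default_table["pma"].notna().all()
    assert set(default_table["label"]) == {"noxious", "nonnoxious"}
    # a row with one missing entry keeps its other 19 predictors
    incomplete = default_table[default_table[classify.FEATURE_NAMES]
                               .isna().sum(axis=1) == 1]
    if len(incomplete):
        assert (incomplete[classify.FEATURE_NAMES].notna()
                .sum(axis=1) == 19).all()


def test_assemble_features_rejects_duplicates():
    keys = pd.DataFrame({"infant_id": ["a", "a"], "label": ["noxious"] * 2})
    eeg = keys.assign(**{c: 0.0 for c in classify.FEATURE_NAMES[:15]})
    physio = keys.assign(heart_rate=0.0, ipsi_reflex=1.0, contra_reflex=1.0)
    behavior = keys.assign(brow_bulge=0.0)
    demo = pd.DataFrame({"infant_id": ["a"], "pma_days": [210.0]})
    with pytest.raises(ValueError, match="duplicate"):
        classify.assemble_features(eeg, physio, behavior, demo)


def test_assemble_features_drops_incomplete_infant():
    keys = pd.DataFrame({"infant_id": ["a", "a", "b"],
                         "label": ["noxious", "nonnoxious", "noxious"]})
    eeg = keys.assign(**{c: 0.0 for c in classify.FEATURE_NAMES[:15]})
    physio = keys.assign(heart_rate=0.0, ipsi_reflex=1.0, contra_reflex=1.0)
    behavior = keys.assign(brow_bulge=0.0)
    demo = pd.DataFrame({"infant_id": ["a", "b"], "pma_days": [210.0, 220.0]})
    with pytest.warns(UserWarning, match="lacks one condition"):
        table = classify.assemble_features(eeg, physio, behavior, demo)
    assert set(table["infant_id"]) == {"a"}


def test_reduced_model_on_separable_heart_rate():
    table = _toy_table(12, seed=13)
    for name in classify.TOP_FEATURES:
        table[name] = 0.0
    table["heart_rate"] = np.where(table["label"] == "noxious", 20.0, 0.0)
    rep = classify.reduced_model(table, n_trees=20, seed=0)
    assert rep.accuracy == 1.0
    assert rep.fpr == 0.0 and rep.fnr == 0.0
    with pytest.raises(KeyError):
        classify.reduced_model(table.drop(columns=["template"]))
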
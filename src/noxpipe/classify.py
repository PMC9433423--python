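"""Discrimination analysis: feature table assembly, leave-one-infant-out
cross-validation, accuracy reporting with binomial confidence intervals,
age-subgroup accuracy, permutation feature importances, and the reduced
top-4 + PMA model.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .config import DAYS_PER_WEEK
from .trees import (NEGATIVE, POSITIVE, BaggedTreeModel, encode_labels,
                    predict, predict_tree, train_bagged_trees)

#: the 20 predictors, in canonical order
FEATURE_NAMES = [
    "template",
    "pc1_noxious", "pc2_noxious", "pc3_noxious",
    "pc1_nonnoxious", "pc2_nonnoxious", "pc3_nonnoxious",
    "pc1_all", "pc2_all", "pc3_all",
    "early_delta", "early_alpha", "late_delta", "late_alpha", "late_beta",
    "heart_rate", "ipsi_reflex", "contra_reflex", "brow_bulge", "pma",
]

TOP_FEATURES = ["heart_rate", "late_delta", "ipsi_reflex", "template"]
PMA_BIN_EDGES_WEEKS = (28.0, 31.0, 34.0, 37.0, 40.0)


@dataclass
class ClassificationReport:
    accuracy: float
    ci_lo: float
    ci_hi: float
    fpr: float
    fnr: float
    n_obs: int
    per_bin: pd.DataFrame | None = None
    predictions: pd.DataFrame | None = None
    importances: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        out = {"accuracy": self.accuracy, "ci_lo": self.ci_lo,
               "ci_hi": self.ci_hi, "fpr": self.fpr, "fnr": self.fnr,
               "n_obs": self.n_obs}
        if self.per_bin is not None:
            out["per_bin"] = self.per_bin.to_dict(orient="records")
        if self.importances:
            out["importances"] = {k: dict(v) for k, v in self.importances.items()}
        return out


def binomial_ci(successes: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Normal-approximation (Wald) binomial proportion confidence interval,
    clipped to [0, 1].  Reproduces the printed 95% intervals, e.g.
    74/94 -> (0.70, 0.87) and 124/148 -> (0.78, 0.90)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= successes <= n:
        raise ValueError("successes must be in [0, n]")
    p = successes / n
    z = norm.ppf(0.5 + level / 2.0)
    half = z * np.sqrt(p * (1.0 - p) / n)
    return max(0.0, p - half), min(1.0, p + half)


def report_from_confusion(fp: int, fn: int, n_per_class: int,
                          level: float = 0.95) -> ClassificationReport:
    """Accuracy/FPR/FNR report from confusion counts on balanced data.

    accuracy = 1 − (FP + FN) / n_obs, with n_obs = 2 · n_per_class; on
    balanced data this equals 1 − (FPR + FNR) / 2.
    """
    n_obs = 2 * n_per_class
    correct = n_obs - fp - fn
    lo, hi = binomial_ci(correct, n_obs, level)
    return ClassificationReport(accuracy=correct / n_obs, ci_lo=lo, ci_hi=hi,
                                fpr=fp / n_per_class, fnr=fn / n_per_class,
                                n_obs=n_obs)


def assemble_features(eeg_rows: pd.DataFrame, physio_rows: pd.DataFrame,
                      behavior_rows: pd.DataFrame,
                      demographics: pd.DataFrame) -> pd.DataFrame:
    """Join the per-event feature rows into the 20-predictor table.

    One row per stimulus event, two per infant, keyed by
    (infant_id, label); missing entries are explicit NaN.  Infants
    lacking either condition are excluded with a logged reason;
    duplicate keys are an error.
    """
    keys = ["infant_id", "label"]
    merged = eeg_rows.merge(physio_rows, on=keys, how="outer")
    merged = merged.merge(behavior_rows, on=keys, how="outer")
    merged = merged.merge(demographics[["infant_id", "pma_days"]],
                          on="infant_id", how="left")
    if merged.duplicated(subset=keys).any():
        raise ValueError("duplicate (infant_id, label) keys in feature rows")
    merged["pma"] = merged["pma_days"].astype(float)
    counts = merged.groupby("infant_id")["label"].nunique()
    incomplete = counts[counts < 2].index
    for iid in incomplete:
        warnings.warn(f"infant {iid} lacks one condition; excluded")
    merged = merged[~merged["infant_id"].isin(incomplete)].reset_index(drop=True)
    if merged["pma"].isna().any():
        raise ValueError("PMA may never be missing")
    return merged[keys + FEATURE_NAMES]


def _report_from_predictions(pred_df: pd.DataFrame) -> ClassificationReport:
    y = encode_labels(pred_df["label"].to_numpy())
    yhat = encode_labels(pred_df["predicted"].to_numpy())
    fp = int(np.sum((y == 0) & (yhat == 1)))
    fn = int(np.sum((y == 1) & (yhat == 0)))
    n_obs = len(pred_df)
    correct = n_obs - fp - fn
    lo, hi = binomial_ci(correct, n_obs)
    n_neg, n_pos = int(np.sum(y == 0)), int(np.sum(y == 1))
    return ClassificationReport(
        accuracy=correct / n_obs, ci_lo=lo, ci_hi=hi,
        fpr=fp / n_neg if n_neg else np.nan,
        fnr=fn / n_pos if n_pos else np.nan,
        n_obs=n_obs, predictions=pred_df)


def loo_by_infant_cv(table: pd.DataFrame, feature_names=None,
                     n_trees: int = 500, min_leaf: int = 3,
                     seed: int = 0) -> ClassificationReport:
    """Leave-one-infant-out cross-validation: both of an infant's events
    are held out together, the ensemble is retrained on the rest, and
    both held-out rows are predicted."""
    if feature_names is None:
        feature_names = FEATURE_NAMES
    infants = table["infant_id"].unique()
    if infants.size < 3:
        raise ValueError("need at least 3 infants for leave-one-infant-out CV")
    rows = []
    for k, iid in enumerate(infants):
        train = table[table["infant_id"] != iid]
        test = table[table["infant_id"] == iid]
        model = train_bagged_trees(
            train[feature_names].to_numpy(float), train["label"].to_numpy(),
            feature_names=feature_names, n_trees=n_trees, min_leaf=min_leaf,
            seed=seed + 1009 * k)
        labels, frac = predict(model, test[feature_names].to_numpy(float))
        for (_, row), lab, fr in zip(test.iterrows(), labels, frac):
            rows.append({"infant_id": iid, "label": row["label"],
                         "pma": row["pma"], "predicted": lab,
                         "vote_fraction": fr})
    pred_df = pd.DataFrame(rows)
    report = _report_from_predictions(pred_df)
    report.per_bin = subgroup_accuracy(pred_df)
    return report


def subgroup_accuracy(pred_df: pd.DataFrame,
                      bin_edges_weeks=PMA_BIN_EDGES_WEEKS,
                      min_infants: int = 3) -> pd.DataFrame:
    """Accuracy with binomial CI per half-open PMA bin (weeks).

    Bins holding fewer than ``min_infants`` infants are flagged
    unreliable rather than suppressed.
    """
    edges = np.asarray(bin_edges_weeks, dtype=float)
    pma_w = pred_df["pma"].to_numpy(float) / DAYS_PER_WEEK
    correct = (encode_labels(pred_df["label"].to_numpy())
               == encode_labels(pred_df["predicted"].to_numpy()))
    recs = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        sel = (pma_w >= lo) & (pma_w < hi)
        n = int(sel.sum())
        n_inf = pred_df.loc[sel, "infant_id"].nunique() if n else 0
        if n == 0:
            recs.append({"pma_lo": lo, "pma_hi": hi, "n_obs": 0,
                         "n_infants": 0, "accuracy": np.nan,
                         "ci_lo": np.nan, "ci_hi": np.nan, "reliable": False})
            continue
        k = int(correct[sel].sum())
        ci = binomial_ci(k, n)
        recs.append({"pma_lo": lo, "pma_hi": hi, "n_obs": n,
                     "n_infants": n_inf, "accuracy": k / n,
                     "ci_lo": ci[0], "ci_hi": ci[1],
                     "reliable": n_inf >= min_infants})
    return pd.DataFrame(recs)


def _accuracy(model: BaggedTreeModel, t: int, X, y) -> float:
    return float(np.mean(predict_tree(model, t, X) == y))


def oob_importance(model: BaggedTreeModel, seed: int = 0) -> dict[str, float]:
    """Standardized out-of-bag permutation importance.

    Per tree, the drop in out-of-bag accuracy when one feature's OOB
    values are permuted; the importance is the mean drop across trees
    divided by its standard deviation (sample SD).  Features with zero
    SD report 0.
    """
    rng = np.random.default_rng(seed)
    n_feat = len(model.feature_names)
    drops = np.zeros((model.n_trees, n_feat))
    for t in range(model.n_trees):
        oob = np.flatnonzero(model.oob_mask(t))
        if oob.size == 0:
            continue
        Xo, yo = model.X_train[oob], model.y_train[oob]
        base = _accuracy(model, t, Xo, yo)
        for j in range(n_feat):
            Xp = Xo.copy()
            Xp[:, j] = Xp[rng.permutation(oob.size), j]
            drops[t, j] = base - _accuracy(model, t, Xp, yo)
    return _standardize(drops, model.feature_names)


def heldout_permutation_importance(model: BaggedTreeModel,
                                   test_table: pd.DataFrame,
                                   n_perm: int = 50,
                                   seed: int = 0) -> dict[str, float]:
    """Held-out permutation importance: each feature permuted across the
    held-out rows ``n_perm`` times for each tree; mean accuracy loss per
    tree, then mean/SD standardization across trees."""
    if len(test_table) < 4:
        raise ValueError("need at least 4 held-out rows")
    rng = np.random.default_rng(seed)
    X = test_table[model.feature_names].to_numpy(float)
    y = encode_labels(test_table["label"].to_numpy())
    n_feat = len(model.feature_names)
    perms = [rng.permutation(X.shape[0]) for _ in range(n_perm)]
    drops = np.zeros((model.n_trees, n_feat))
    for t in range(model.n_trees):
        base = _accuracy(model, t, X, y)
        for j in range(n_feat):
            losses = np.empty(n_perm)
            for p, perm in enumerate(perms):
                Xp = X.copy()
                Xp[:, j] = Xp[perm, j]
                losses[p] = base - _accuracy(model, t, Xp, y)
            drops[t, j] = losses.mean()
    return _standardize(drops, model.feature_names)


def _standardize(drops: np.ndarray, names) -> dict[str, float]:
    mean = drops.mean(axis=0)
    sd = drops.std(axis=0, ddof=1)
    out = {}
    for j, name in enumerate(names):
        if sd[j] == 0:
            warnings.warn(f"zero importance spread for {name!r}; reported as 0")
            out[name] = 0.0
        else:
            out[name] = float(mean[j] / sd[j])
    return out


def reduced_model(table: pd.DataFrame, top_features=None,
                  always_include=("pma",), n_trees: int = 500,
                  min_leaf: int = 3, seed: int = 0) -> ClassificationReport:
    """Leave-one-infant-out report of the model restricted to the four
    most important features plus PMA."""
    if top_features is None:
        top_features = TOP_FEATURES
    feats = list(top_features) + [f for f in always_include
                                  if f not in top_features]
    missing = [f for f in feats if f not in table.columns]
    if missing:
        raise KeyError(f"features not in table: {missing}")
    return loo_by_infant_cv(table, feature_names=feats, n_trees=n_trees,
                            min_leaf=min_leaf, seed=seed)
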
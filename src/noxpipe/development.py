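"""Developmental trajectories and permutation-based inference.

Age-weighted feature trajectories over postmenstrual age (Gaussian
weights in 4-week sliding windows for means, lower weighted medians for
limb withdrawal, hard ±1.5-week windows for brow-bulge response
proportions), linear PMA-association models with permutation p-values
(Freedman–Lane residual permutation when covariates such as postnatal
age are adjusted for), paired sign-flip t-tests, Holm–Bonferroni
correction, and the z-scored trajectory matrix sorted by PMA slope.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .config import DAYS_PER_WEEK
from .eeg import gaussian_age_weight

#: features whose PMA association forms the Holm-corrected family
PMA_TEST_FAMILY = [
    "heart_rate", "pc1_noxious", "pc2_noxious", "pc3_noxious",
    "early_delta", "early_alpha", "late_delta", "late_alpha", "late_beta",
    "ipsi_reflex", "contra_reflex",
]


@dataclass
class RegressionResult:
    beta: float
    t_statistic: float
    p_perm: float
    n: int
    p_holm: float | None = None

    def to_dict(self) -> dict:
        return {"beta": self.beta, "t": self.t_statistic,
                "p_perm": self.p_perm, "p_holm": self.p_holm, "n": self.n}


@dataclass
class TrajectoryCurve:
    central_pma_weeks: np.ndarray
    values: np.ndarray
    statistic_kind: str  # weighted_mean | weighted_median | proportion
    window_weeks: float
    n_effective: np.ndarray


def weighted_median(values, weights) -> float:
    """Deterministic (non-interpolating) weighted median: the smallest
    value whose cumulative normalized weight exceeds 0.5.  With weights
    [1, 1, 2] on values [1, 2, 3] this gives 3 (no midpoint averaging)."""
    v = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    total = w.sum()
    if total <= 0:
        raise ValueError("weights sum to zero")
    order = np.argsort(v, kind="stable")
    cum = np.cumsum(w[order]) / total
    idx = np.searchsorted(cum, 0.5, side="right")
    return float(v[order][min(idx, v.size - 1)])


def trajectory(pma_days, values, statistic_kind: str = "weighted_mean",
               window_weeks: float = 4.0, grid_weeks=None) -> TrajectoryCurve:
    """Feature statistic as a function of central PMA.

    Continuous statistics use Gaussian age weights within the sliding
    window (weight ~0.5 one quarter-window from the centre); proportions
    use a hard ±half-window (±1.5 weeks for the default 3-week window)
    with a response defined as a value above 0.  Grid points with no
    contributing infant are masked (NaN).
    """
    pma_w = np.asarray(pma_days, dtype=float) / DAYS_PER_WEEK
    v = np.asarray(values, dtype=float)
    ok = np.isfinite(v)
    pma_w, v = pma_w[ok], v[ok]
    if grid_weeks is None:
        grid_weeks = np.arange(np.floor(pma_w.min()), np.ceil(pma_w.max()) + 1.0)
    grid_weeks = np.asarray(grid_weeks, dtype=float)
    out = np.full(grid_weeks.size, np.nan)
    neff = np.zeros(grid_weeks.size)
    for k, c in enumerate(grid_weeks):
        if statistic_kind == "proportion":
            sel = np.abs(pma_w - c) <= window_weeks / 2.0
            neff[k] = sel.sum()
            if sel.any():
                out[k] = float(np.mean(v[sel] > 0))
            continue
        w = gaussian_age_weight((pma_w - c) * DAYS_PER_WEEK,
                                window_weeks * DAYS_PER_WEEK)
        w = np.asarray(w, dtype=float)
        if w.sum() <= 0:
            continue
        neff[k] = w.sum() ** 2 / (w ** 2).sum()
        if statistic_kind == "weighted_mean":
            out[k] = float(np.average(v, weights=w))
        elif statistic_kind == "weighted_median":
            out[k] = weighted_median(v[w > 0], w[w > 0])
        else:
            raise ValueError(f"unknown statistic {statistic_kind!r}")
    return TrajectoryCurve(grid_weeks, out, statistic_kind, window_weeks, neff)


def _ols_t(y: np.ndarray, design: np.ndarray, col: int) -> tuple[float, float]:
    """OLS coefficient and t statistic for one design column."""
    beta, res, *_ = np.linalg.lstsq(design, y, rcond=None)
    fitted = design @ beta
    dof = y.size - design.shape[1]
    sigma2 = np.sum((y - fitted) ** 2) / dof
    xtx_inv = np.linalg.pinv(design.T @ design)
    se = np.sqrt(sigma2 * xtx_inv[col, col])
    t = beta[col] / se if se > 0 else np.inf * np.sign(beta[col])
    return float(beta[col]), float(t)


def permutation_lm(feature, pma_days, covariates=None, n_perm: int = 10_000,
                   seed: int = 0) -> RegressionResult:
    """Linear PMA-association model with a nonparametric two-sided p-value.

    The slope is per PMA week.  Without covariates the response is
    permuted directly; with covariates the Freedman–Lane scheme permutes
    the residuals of the nuisance-only model.  The observed statistic is
    included in both numerator and denominator: p = (1 + b) / (n_perm + 1).
    """
    y = np.asarray(feature, dtype=float)
    x = np.asarray(pma_days, dtype=float) / DAYS_PER_WEEK
    Z = (np.asarray(covariates, dtype=float).reshape(y.size, -1)
         if covariates is not None else np.empty((y.size, 0)))
    ok = np.isfinite(y) & np.isfinite(x)
    if Z.shape[1]:
        ok &= np.all(np.isfinite(Z), axis=1)
    y, x, Z = y[ok], x[ok], Z[ok]
    n = y.size
    if n < 5:
        raise ValueError("need n >= 5 after dropping missing values")
    if np.ptp(x) == 0:
        raise ValueError("constant predictor")
    ones = np.ones((n, 1))
    design = np.column_stack([x, Z, np.ones(n)])
    beta, t_obs = _ols_t(y, design, 0)

    rng = np.random.default_rng(seed)
    if Z.shape[1] == 0:
        # permuting y directly; |t| is monotone in |corr(y, x)|
        xc = (x - x.mean()) / np.linalg.norm(x - x.mean())
        yc = y - y.mean()
        denom = np.linalg.norm(yc)
        r_obs = abs(xc @ yc) / denom
        perm_idx = np.argsort(rng.random((n_perm, n)), axis=1)
        r_star = np.abs(yc[perm_idx] @ xc) / denom
        count = int(np.sum(r_star >= r_obs - 1e-12))
    else:
        nuis = np.column_stack([Z, np.ones(n)])
        gamma, *_ = np.linalg.lstsq(nuis, y, rcond=None)
        fitted_nuis = nuis @ gamma
        resid = y - fitted_nuis
        count = 0
        for _ in range(n_perm):
            y_star = fitted_nuis + resid[rng.permutation(n)]
            _, t_star = _ols_t(y_star, design, 0)
            if abs(t_star) >= abs(t_obs) - 1e-12:
                count += 1
    p = (1 + count) / (n_perm + 1)
    return RegressionResult(beta=beta, t_statistic=t_obs, p_perm=p, n=n)


def signflip_paired_test(noxious_vals, nonnoxious_vals, n_flips: int = 10_000,
                         seed: int = 0) -> RegressionResult:
    """Two-sided paired t-test with a sign-flip permutation p-value.

    Differences (noxious − nonnoxious) are sign-flipped; when 2^n does
    not exceed ``n_flips`` the full set of sign patterns is enumerated
    exactly instead of sampled.  Zero-variance differences give p = 1
    with a warning.
    """
    a = np.asarray(noxious_vals, dtype=float)
    b = np.asarray(nonnoxious_vals, dtype=float)
    ok = np.isfinite(a) & np.isfinite(b)
    d = (a - b)[ok]
    n = d.size
    if n < 5:
        raise ValueError("need n >= 5 pairs")

    def paired_t(dd):
        sd = dd.std(ddof=1, axis=-1)
        return np.where(sd > 0, dd.mean(axis=-1) / (sd / np.sqrt(n)), np.inf)

    if d.std(ddof=1) == 0:
        if np.all(d == 0):
            warnings.warn("zero-variance differences; p = 1")
            return RegressionResult(beta=0.0, t_statistic=0.0, p_perm=1.0, n=n)
        t_obs = float(paired_t(d))
    else:
        t_obs = float(paired_t(d))
    rng = np.random.default_rng(seed)
    if 2 ** n <= n_flips:  # exhaustive enumeration
        signs = np.array([[1 if (k >> i) & 1 else -1 for i in range(n)]
                          for k in range(2 ** n)], dtype=float)
        m = 2 ** n
        t_star = paired_t(signs * d)
        count = int(np.sum(np.abs(t_star) >= abs(t_obs) - 1e-12))
        p = count / m  # exact: the identity flip contributes the observed t
    else:
        signs = rng.choice([-1.0, 1.0], size=(n_flips, n))
        t_star = paired_t(signs * d)
        count = int(np.sum(np.abs(t_star) >= abs(t_obs) - 1e-12))
        p = (1 + count) / (n_flips + 1)
    return RegressionResult(beta=float(d.mean()), t_statistic=t_obs,
                            p_perm=p, n=n)


def holm_bonferroni(p_values) -> np.ndarray:
    """Holm–Bonferroni adjusted p-values, in the input order."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    if p.size == 1:
        return p.copy()
    return multipletests(p, method="holm")[1]


def save_trajectory_figure(table: pd.DataFrame, path,
                           features=("pc1_noxious", "pc2_noxious",
                                     "pc3_noxious", "heart_rate",
                                     "ipsi_reflex", "brow_bulge")) -> None:
    """Panel figure of developmental trajectories (one panel per feature).

    Continuous features show noxious and nonnoxious age-weighted curves
    with the per-infant noxious values; brow bulge shows response
    proportions in ±1.5-week windows.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, len(features), figsize=(3 * len(features), 3),
                             sharex=True)
    for ax, feat in zip(np.atleast_1d(axes), features):
        for cond, color in (("noxious", "tab:red"), ("nonnoxious", "0.6")):
            sub = table[table["label"] == cond]
            if feat == "brow_bulge":
                curve = trajectory(sub["pma"], sub[feat], "proportion", 3.0)
            elif feat in ("ipsi_reflex", "contra_reflex"):
                curve = trajectory(sub["pma"], sub[feat], "weighted_median")
            else:
                curve = trajectory(sub["pma"], sub[feat])
            ax.plot(curve.central_pma_weeks, curve.values, color=color,
                    label=cond)
            if cond == "noxious":
                ax.plot(sub["pma"] / DAYS_PER_WEEK, sub[feat], ".",
                        color=color, alpha=0.3, ms=3)
        ax.set_title(feat, fontsize=9)
        ax.set_xlabel("PMA (weeks)")
    np.atleast_1d(axes)[0].legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def pma_association_family(table: pd.DataFrame, features=None,
                           covariates=None, n_perm: int = 10_000,
                           seed: int = 0) -> dict[str, RegressionResult]:
    """PMA-association tests on the noxious rows for the canonical
    11-feature family, Holm-corrected across the family."""
    if features is None:
        features = PMA_TEST_FAMILY
    nox = table[table["label"] == "noxious"]
    results = {}
    for k, feat in enumerate(features):
        cov = nox[covariates].to_numpy(float) if covariates else None
        results[feat] = permutation_lm(nox[feat].to_numpy(float),
                                       nox["pma"].to_numpy(float),
                                       covariates=cov, n_perm=n_perm,
                                       seed=seed + 31 * k)
    if covariates is None:  # exploratory PNA-adjusted models stay unadjusted
        adj = holm_bonferroni([r.p_perm for r in results.values()])
        for r, pa in zip(results.values(), adj):
            r.p_holm = float(pa)
    return results


def trajectory_cluster_summary(table: pd.DataFrame, features=None,
                               window_weeks: float = 4.0,
                               grid_weeks=None) -> pd.DataFrame:
    """Z-scored age-weighted trajectory per feature, sorted by PMA slope.

    Each feature is z-scored across the noxious rows of all infants, an
    age-weighted mean curve is computed on the PMA grid, and rows are
    ordered by the OLS slope of the z-score on PMA (most negative
    first).  Cluster labels are not assigned; the ordering exposes the
    decreasing and increasing blocks.  Zero-variance features are
    excluded with a warning.
    """
    if features is None:
        features = [c for c in table.columns
                    if c not in ("infant_id", "label", "pma")]
    nox = table[table["label"] == "noxious"]
    pma = nox["pma"].to_numpy(float)
    rows, slopes = {}, {}
    for feat in features:
        v = nox[feat].to_numpy(float)
        ok = np.isfinite(v)
        if ok.sum() < 3 or np.nanstd(v) == 0:
            warnings.warn(f"feature {feat!r} excluded (insufficient variance)")
            continue
        z = (v - np.nanmean(v)) / np.nanstd(v)
        curve = trajectory(pma, z, "weighted_mean", window_weeks, grid_weeks)
        rows[feat] = curve.values
        design = np.column_stack([pma[ok] / DAYS_PER_WEEK, np.ones(ok.sum())])
        slopes[feat], _ = _ols_t(z[ok], design, 0)
        grid_weeks = curve.central_pma_weeks
    order = sorted(rows, key=lambda f: slopes[f])
    df = pd.DataFrame([rows[f] for f in order], index=order,
                      columns=[f"{w:g}" for w in grid_weeks])
    df.insert(0, "pma_slope", [slopes[f] for f in order])
    return df
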
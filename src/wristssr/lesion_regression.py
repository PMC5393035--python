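"""LASSO regression from EEG outcome metrics to SMT lesion volume.

A linear model predicts the sensory-and-motor-tract (SMT) lesion volume from
the per-participant outcome metrics (SNR_contra, SNR_ipsi, LI per task).
Predictors are standardized, the L1 penalty is selected by ten-fold
cross-validation on a log-spaced grid (minimum CV squared error), and the
model is refit on all data at the selected penalty.  Performance is the
variance accounted for, VAF = 100·(1 − var(y − ŷ)/var(y)); both the
in-sample and the cross-validated (out-of-fold) VAF are reported.
Significance comes from re-running the entire procedure on permuted targets,
with the add-one estimator p = (1 + #{VAF_perm ≥ VAF_obs}) / (1 + n_perm).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

DEFAULT_N_FOLDS = 10
DEFAULT_N_ALPHAS = 30
DEFAULT_N_PERMUTATIONS = 1000


def lasso_path_cd(x: np.ndarray, y: np.ndarray, alphas: np.ndarray,
                  tol: float = 1e-10, max_sweeps: int = 10_000):
    """Coordinate-descent LASSO path in covariance form.

    Minimizes ``||y - c - X w||^2 / (2 n) + alpha ||w||_1`` (the sklearn
    parameterization, with an unpenalized intercept ``c``) for every alpha
    at once; the permutation test refits this path thousands of times, so
    the whole grid is updated vectorized per coordinate sweep.  Returns
    ``(coefs (p, n_alphas), intercepts (n_alphas,))``.
    """
    n, p = x.shape
    xm, ym = x.mean(axis=0), y.mean()
    xc, yc = x - xm, y - ym
    gram = xc.T @ xc                      # (p, p)
    xty = xc.T @ yc                       # (p,)
    diag = np.diag(gram).copy()
    diag[diag == 0] = 1.0
    thresh = np.asarray(alphas) * n       # soft threshold on the rho scale
    w = np.zeros((p, len(alphas)))
    scale = np.max(np.abs(yc)) + 1e-30
    for _ in range(max_sweeps):
        delta = 0.0
        for j in range(p):
            rho = xty[j] - gram[j] @ w + diag[j] * w[j]
            new = np.sign(rho) * np.maximum(np.abs(rho) - thresh, 0.0) / diag[j]
            delta = max(delta, np.max(np.abs(new - w[j])))
            w[j] = new
        if delta < tol * scale:
            break
    intercepts = ym - xm @ w
    return w, intercepts


@dataclass
class RegressionResult:
    predictor_names: tuple[str, ...]
    coefficients: np.ndarray            # on standardized predictors
    intercept: float
    lambda_: float
    vaf_percent: float                  # in-sample, final refit
    vaf_cv_percent: float               # pooled out-of-fold predictions
    permutation_p: Optional[float] = None
    n: int = 0


def _quantile_stratified_folds(y: np.ndarray, n_folds: int, seed: int) -> np.ndarray:
    """Fold labels balanced over the target's quantiles (seeded tie-breaks)."""
    rng = np.random.default_rng(seed)
    order = np.argsort(y + 1e-12 * rng.standard_normal(len(y)))
    folds = np.empty(len(y), int)
    fold_cycle = np.arange(len(y)) % n_folds
    # shuffle fold assignment within consecutive quantile blocks
    for start in range(0, len(y), n_folds):
        block = fold_cycle[start:start + n_folds]
        rng.shuffle(block)
        fold_cycle[start:start + n_folds] = block
    folds[order] = fold_cycle
    return folds


def _vaf(y, yhat) -> float:
    vy = np.var(y)
    if vy == 0:
        raise ValueError("constant target: VAF undefined")
    return 100.0 * (1.0 - np.var(y - yhat) / vy)


def fit_lasso_cv(
    features,
    target,
    n_folds: int = DEFAULT_N_FOLDS,
    seed: int = 0,
    n_alphas: int = DEFAULT_N_ALPHAS,
    alpha_min_ratio: float = 1e-3,
) -> RegressionResult:
    """Cross-validated LASSO fit of lesion volume on outcome metrics.

    ``features`` is a participant × predictor DataFrame (or array); rows with
    missing values are not allowed.  λ is chosen by minimum cross-validated
    squared error over a log grid from the data-derived λ_max down by
    ``alpha_min_ratio``; fold assignment is seeded and stratified by target
    quantile.
    """
    if isinstance(features, pd.DataFrame):
        names = tuple(features.columns)
        x = features.to_numpy(float)
    else:
        x = np.asarray(features, float)
        names = tuple(f"x{i}" for i in range(x.shape[1]))
    y = np.asarray(target, float)
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValueError("missing values in features or target")
    n = len(y)
    if n < n_folds:
        raise ValueError(f"need at least n_folds={n_folds} participants, got {n}")
    if np.var(y) == 0:
        raise ValueError("constant target: regression undefined")

    mu, sd = x.mean(axis=0), x.std(axis=0)
    sd[sd == 0] = 1.0
    xs = (x - mu) / sd

    alpha_max = np.max(np.abs(xs.T @ (y - y.mean()))) / n
    if alpha_max <= 0:
        alpha_max = 1.0
    alphas = np.geomspace(alpha_max, alpha_max * alpha_min_ratio, n_alphas)

    folds = _quantile_stratified_folds(y, n_folds, seed)
    cv_pred = np.empty((n, n_alphas))
    for k in range(n_folds):
        test = folds == k
        train = ~test
        coefs, intercepts = lasso_path_cd(xs[train], y[train], alphas)
        cv_pred[test] = xs[test] @ coefs + intercepts
    mse = np.mean((cv_pred - y[:, None]) ** 2, axis=0)
    best = int(np.argmin(mse))
    alpha = float(alphas[best])

    coefs, intercepts = lasso_path_cd(xs, y, np.array([alpha]))
    coef, intercept = coefs[:, 0], float(intercepts[0])
    yhat = xs @ coef + intercept
    return RegressionResult(
        predictor_names=names,
        coefficients=coef,
        intercept=intercept,
        lambda_=alpha,
        vaf_percent=_vaf(y, yhat),
        vaf_cv_percent=_vaf(y, cv_pred[:, best]),
        n=n,
    )


def permutation_significance(
    features,
    target,
    n_permutations: int = DEFAULT_N_PERMUTATIONS,
    seed: int = 0,
    n_folds: int = DEFAULT_N_FOLDS,
) -> tuple[float, RegressionResult, np.ndarray]:
    """Permutation p-value for the LASSO model performance.

    The full selection-and-refit procedure is re-run on every permuted
    target; p = (1 + #{permuted VAF ≥ observed}) / (1 + n_permutations).
    Performance is the cross-validated VAF: the in-sample VAF collapses to
    exactly zero whenever selection shrinks every coefficient away, which
    under a null target produces massive ties and a non-uniform p-value,
    while the out-of-fold VAF is continuous.  Returns (p, observed result,
    permuted VAFs).
    """
    if n_permutations < 100:
        raise ValueError("use at least 100 permutations")
    rng = np.random.default_rng(seed)
    y = np.asarray(target, float)
    observed = fit_lasso_cv(features, y, n_folds=n_folds,
                            seed=int(rng.integers(2**31)))
    perm_vaf = np.empty(n_permutations)
    for i in range(n_permutations):
        yp = rng.permutation(y)
        res = fit_lasso_cv(features, yp, n_folds=n_folds,
                           seed=int(rng.integers(2**31)))
        perm_vaf[i] = res.vaf_cv_percent
    p = (1.0 + np.sum(perm_vaf >= observed.vaf_cv_percent)) / (1.0 + n_permutations)
    observed.permutation_p = p
    return p, observed, perm_vaf


def build_feature_tables(metrics_table: pd.DataFrame, tasks="passive") -> pd.DataFrame:
    """One row per participant, columns per (task, metric).

    ``metrics_table`` is tidy with columns participant, task, snr_contra,
    snr_ipsi, li (one row per participant × valid task).  ``tasks`` is
    "passive", "active" or "both"; participants lacking a requested task
    (active excluded for too few valid periods) are dropped.
    """
    wanted = ("passive", "active") if tasks == "both" else (tasks,)
    for t in wanted:
        if t not in ("passive", "active"):
            raise ValueError(f"unknown task {t!r}")
    pieces = []
    for t in wanted:
        sub = metrics_table[metrics_table["task"] == t]
        sub = sub.set_index("participant")[["snr_contra", "snr_ipsi", "li"]]
        sub.columns = [f"{t}_{c}" for c in sub.columns]
        pieces.append(sub)
    table = pd.concat(pieces, axis=1, join="inner").dropna()
    if table.empty:
        raise ValueError("no participants with all requested tasks")
    return table
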
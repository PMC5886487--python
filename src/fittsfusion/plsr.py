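"""Partial least squares regression (NIPALS) and the four difficulty models.

The difficulty index is regressed on each predictor set through a PLS
decomposition

    X = T P' + E,      Y = U Q' + F,

where successive latent components maximize the covariance between the X-
and Y-score vectors; after each component X and Y are deflated by the
extracted rank-one part.  Regression coefficients are assembled from the
weight, loading, and Y-loading matrices by the standard PLS algebra
``B = W (P'W)^{-1} q``.  At the full component count on full-rank data the
fit coincides with ordinary least squares.

Model assessment follows six criteria per cross-validation fold — R^2,
RMSE, MAE, NRMSE = RMSE / y_max, NMAE = MAE / y_max, and MAPE — averaged
over 10 stratified folds.  The model comparison reports all criteria for
the movement-time, fusion, kinematic, and physiological predictor sets plus
the percent RMSE reduction of the fusion and kinematic models relative to
the movement-time baseline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import KFold, StratifiedKFold

from .screening import FeatureSets, ZScoreParams, fit_zscore, zscore

__all__ = [
    "pls_fit",
    "pls_predict",
    "choose_components",
    "evaluate",
    "kfold_cv",
    "compare_models",
    "percent_improvement",
    "normalized_error",
    "PLSModel",
    "EvalReport",
    "ModelComparison",
]

CRITERIA = ("r2", "rmse", "mae", "nrmse", "nmae", "mape")


# ---------------------------------------------------------------------------
# NIPALS core
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PLSModel:
    """A fitted PLS-1 regression with its full decomposition.

    T and U are the X- and Y-score matrices, P and Q the corresponding
    loadings, W the X-weights, E and F the final deflation residuals.  The
    training centering/scaling parameters are carried so prediction maps raw
    predictor rows back onto the training scale.
    """

    n_components: int
    weights: np.ndarray  # W, (p, A)
    x_loadings: np.ndarray  # P, (p, A)
    y_loadings: np.ndarray  # Q, (A,)
    x_scores: np.ndarray  # T, (n, A)
    y_scores: np.ndarray  # U, (n, A)
    x_residual: np.ndarray  # E
    y_residual: np.ndarray  # F
    coef: np.ndarray  # (p,) on the standardized scale
    coef_path: np.ndarray  # (p, A): coefficients after 1..A components
    x_params: ZScoreParams
    y_mean: float
    columns: tuple | None = None


def pls_fit(
    X,
    y,
    n_components: int,
    *,
    standardized: bool = False,
    columns=None,
    tol: float = 1e-12,
) -> PLSModel:
    """Fit a PLS-1 regression by NIPALS with deflation.

    ``X`` (n, p) predictors and ``y`` (n,) response.  With
    ``standardized=False`` (default) X is z-scored internally (population
    SD) and y centered; the parameters are stored on the model.  Components
    must satisfy ``1 <= A <= min(n - 1, p)``.  Deterministic given the input
    order.  Raises on constant predictor columns and on a degenerate
    component (no remaining covariance) with the component index.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("X must be (n, p) with y of length n")
    n, p = X.shape
    if not 1 <= n_components <= min(n - 1, p):
        raise ValueError(
            f"n_components must be in [1, min(n-1, p)] = [1, {min(n - 1, p)}]"
        )
    if standardized:
        # caller scaled the columns already; centering is still part of the
        # algorithm and must use this training set's means
        x_params = ZScoreParams(mean=X.mean(axis=0), std=np.ones(p))
        Xw = X - x_params.mean
    else:
        x_params = fit_zscore(X)  # raises on constant columns
        Xw = zscore(X, x_params)
    y_mean = float(y.mean())
    yw = y - y_mean

    W = np.zeros((p, n_components))
    P = np.zeros((p, n_components))
    Q = np.zeros(n_components)
    T = np.zeros((n, n_components))
    U = np.zeros((n, n_components))

    # With a single response column the NIPALS inner iteration converges in
    # one pass: w = X'y is already the covariance-maximizing direction, so
    # each component is extracted directly and then deflated.
    Xd, yd = Xw.copy(), yw.copy()
    for a in range(n_components):
        u = yd.copy()
        w = Xd.T @ u
        wn = float(np.linalg.norm(w))
        if wn < tol:
            raise ValueError(
                f"degenerate component {a + 1}: no covariance left to extract"
            )
        w /= wn
        t = Xd @ w
        tt = float(t @ t)
        if tt < tol:
            raise ValueError(f"degenerate component {a + 1}: zero X-scores")
        q = float(yd @ t) / tt
        p_load = (Xd.T @ t) / tt
        W[:, a], P[:, a], Q[a], T[:, a] = w, p_load, q, t
        U[:, a] = yd * q  # Y-scores: projection of the response block
        Xd = Xd - np.outer(t, p_load)
        yd = yd - q * t

    # Coefficients for every truncation 1..A in one pass: B_A = W (P'W)^-1 q.
    coef_path = np.zeros((p, n_components))
    PtW = P.T @ W  # upper triangular with unit-ish diagonal structure
    for a in range(n_components):
        r = np.linalg.solve(PtW[: a + 1, : a + 1], Q[: a + 1])
        coef_path[:, a] = W[:, : a + 1] @ r

    return PLSModel(
        n_components=n_components,
        weights=W,
        x_loadings=P,
        y_loadings=Q,
        x_scores=T,
        y_scores=U,
        x_residual=Xd,
        y_residual=yd,
        coef=coef_path[:, -1],
        coef_path=coef_path,
        x_params=x_params,
        y_mean=y_mean,
        columns=tuple(columns) if columns is not None else None,
    )


def pls_predict(model: PLSModel, X_new, n_components: int | None = None) -> np.ndarray:
    """Predict the response for new predictor rows, in original units.

    ``n_components`` may truncate the model to fewer components than fitted.
    Raises on a column-count mismatch with the training predictors.
    """
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    p = model.weights.shape[0]
    if X_new.shape[1] != p:
        raise ValueError(
            f"predictor column mismatch: model has {p}, input has {X_new.shape[1]}"
        )
    a = model.n_components if n_components is None else n_components
    if not 1 <= a <= model.n_components:
        raise ValueError("n_components out of fitted range")
    Xs = zscore(X_new, model.x_params)
    return model.y_mean + Xs @ model.coef_path[:, a - 1]


# ---------------------------------------------------------------------------
# Component selection and evaluation criteria
# ---------------------------------------------------------------------------

def _fit_truncating(X, y, n_components: int) -> PLSModel:
    """Fit with as many components as the data supports, up to the request.

    Rank-deficient training folds cannot yield the full component count; the
    fit is retried with fewer components until the decomposition succeeds.
    """
    a = n_components
    while True:
        try:
            return pls_fit(X, y, a, standardized=False)
        except ValueError:
            if a <= 1:
                raise
            a -= 1


def choose_components(
    X, y, max_components: int, k_inner: int = 5, seed: int = 0
) -> int:
    """Pick the latent-component count by inner k-fold CV RMSE.

    Returns the count (1..max_components) minimizing the mean held-out
    RMSE; ties break toward fewer components.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    a_max = min(max_components, n - 1 - math.ceil(n / k_inner), p)
    a_max = max(a_max, 1)
    if a_max == 1:
        return 1
    kf = KFold(n_splits=k_inner, shuffle=True, random_state=seed)
    sse = np.zeros(a_max)
    count = np.zeros(a_max)
    a_common = a_max
    for tr, te in kf.split(X):
        a_fit = min(a_max, len(tr) - 1)
        model = _fit_truncating(X[tr], y[tr], a_fit)
        a_common = min(a_common, model.n_components)
        for a in range(1, model.n_components + 1):
            resid = y[te] - pls_predict(model, X[te], n_components=a)
            sse[a - 1] += float(resid @ resid)
            count[a - 1] += len(te)
    # compare only counts every fold could evaluate
    rmse = np.sqrt(sse[:a_common] / np.maximum(count[:a_common], 1))
    best = float(np.min(rmse))
    # parsimony tie-break: the smallest count within numerical slack of the
    # minimum (exact-fit data leaves all counts at machine-epsilon RMSE)
    slack = best + max(1e-10, 1e-8 * best)
    return int(np.argmax(rmse <= slack)) + 1


@dataclass(frozen=True)
class EvalReport:
    """The six criteria for one prediction set (one fold, or aggregated)."""

    r2: float
    rmse: float
    mae: float
    nrmse: float
    nmae: float
    mape: float
    n: int

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in CRITERIA} | {"n": self.n}


def normalized_error(error: float, y_max: float) -> float:
    """Scale-free error: an RMSE or MAE divided by the maximum observed
    response (NRMSE / NMAE)."""
    if not y_max > 0:
        raise ValueError("y_max must be > 0")
    return error / y_max


def percent_improvement(rmse_baseline: float, rmse_model: float) -> float:
    """Percent RMSE reduction relative to a baseline:
    ``100 * (RMSE_base - RMSE_model) / RMSE_base``."""
    if not rmse_baseline > 0:
        raise ValueError("baseline RMSE must be > 0")
    return 100.0 * (rmse_baseline - rmse_model) / rmse_baseline


def evaluate(y, y_pred, y_max: float | None = None) -> EvalReport:
    """Compute the six criteria for observed vs predicted responses.

    ``R^2 = 1 - SSres/SStot`` around the observed mean; RMSE carries the 1/n
    factor inside the radical; NRMSE and NMAE divide by ``y_max`` (the
    maximum observed response unless supplied, e.g. the full-design maximum
    when evaluating a single fold); MAPE requires strictly nonzero y.
    """
    y = np.asarray(y, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if y.shape != y_pred.shape:
        raise ValueError("y and y_pred must have equal length")
    n = y.shape[0]
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("zero total sum of squares: R^2 undefined")
    if np.any(y == 0):
        raise ValueError("zero observed response: MAPE undefined")
    resid = y - y_pred
    rmse = math.sqrt(float(np.mean(resid**2)))
    mae = float(np.mean(np.abs(resid)))
    ymax = float(np.max(y)) if y_max is None else float(y_max)
    return EvalReport(
        r2=1.0 - float(resid @ resid) / ss_tot,
        rmse=rmse,
        mae=mae,
        nrmse=normalized_error(rmse, ymax),
        nmae=normalized_error(mae, ymax),
        mape=float(100.0 * np.mean(np.abs(resid) / np.abs(y))),
        n=n,
    )


# ---------------------------------------------------------------------------
# Cross-validation and model comparison
# ---------------------------------------------------------------------------

def _aggregate(folds: list[EvalReport]) -> EvalReport:
    """Unweighted mean of each criterion across folds."""
    return EvalReport(
        **{k: float(np.mean([getattr(f, k) for f in folds])) for k in CRITERIA},
        n=int(sum(f.n for f in folds)),
    )


def kfold_cv(
    X,
    y,
    k: int = 10,
    seed: int = 0,
    *,
    max_components: int = 10,
    n_components: int | None = None,
    k_inner: int = 5,
    standardization: str = "fold",
    stratify_levels=None,
) -> tuple[EvalReport, list[EvalReport]]:
    """Stratified k-fold cross-validation of a PLS difficulty model.

    Folds are stratified by difficulty level so every fold sees all
    conditions; standardization and latent-component choice are refit on
    each training fold (``standardization="global"`` instead z-scores once
    on all data before splitting, replicating a normalize-then-CV protocol).
    ``n_components`` fixes the component count; otherwise it is chosen per
    training fold by inner ``k_inner``-fold CV.  Returns the fold-mean
    report and the per-fold reports.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if k > n:
        raise ValueError(f"k = {k} exceeds the number of observations {n}")
    if standardization not in ("fold", "global"):
        raise ValueError("standardization must be 'fold' or 'global'")
    if standardization == "global":
        X = zscore(X)
    levels = y if stratify_levels is None else np.asarray(stratify_levels)
    _, strata = np.unique(levels, return_inverse=True)
    if np.min(np.bincount(strata)) >= k:
        kf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        splits = kf.split(X, strata)
    else:  # too few per level to stratify (tiny fixtures): plain shuffle
        kf = KFold(n_splits=k, shuffle=True, random_state=seed)
        splits = kf.split(X)
    y_max = float(np.max(y))
    fold_reports = []
    for i, (tr, te) in enumerate(splits):
        Xtr, Xte = X[tr], X[te]
        if standardization == "fold":
            params = fit_zscore(Xtr)
            Xtr, Xte = zscore(Xtr, params), zscore(Xte, params)
        a = n_components
        if a is None:
            a = choose_components(
                Xtr, y[tr], max_components=min(max_components, p), k_inner=k_inner,
                seed=seed + i,
            )
        a = min(a, p, len(tr) - 1)
        model = pls_fit(Xtr, y[tr], a, standardized=True)
        y_hat = pls_predict(model, Xte)
        fold_reports.append(evaluate(y[te], y_hat, y_max=y_max))
    return _aggregate(fold_reports), fold_reports


@dataclass(frozen=True)
class ModelComparison:
    """Aggregated criteria for Models I-IV plus RMSE improvements over I."""

    reports: dict  # set id -> aggregated EvalReport
    fold_reports: dict  # set id -> list[EvalReport]
    improvement_vs_mt: dict  # set id ("II", "III") -> percent RMSE reduction
    metric_sets: dict  # set id -> tuple of metric names


def compare_models(
    features,
    response,
    feature_sets: FeatureSets,
    k: int = 10,
    seed: int = 0,
    *,
    n_components: int | None = None,
    standardization: str = "fold",
) -> ModelComparison:
    """Fit and cross-validate the four difficulty models on a feature table.

    ``features`` is a DataFrame with one row per trial and the metric
    columns; ``response`` the difficulty index per trial.  Raises naming any
    metric column a set requires but the table lacks.
    """
    y = np.asarray(response, dtype=float)
    reports, folds = {}, {}
    for mset in feature_sets:
        missing = [m for m in mset.metrics if m not in features]
        if missing:
            raise ValueError(f"feature table lacks columns for Set {mset.set_id}: {missing}")
        X = np.column_stack([np.asarray(features[m], dtype=float) for m in mset.metrics])
        agg, per_fold = kfold_cv(
            X,
            y,
            k=k,
            seed=seed,
            n_components=n_components,
            standardization=standardization,
        )
        reports[mset.set_id] = agg
        folds[mset.set_id] = per_fold
    base = reports["I"].rmse
    improvement = {
        sid: percent_improvement(base, reports[sid].rmse) for sid in ("II", "III")
    }
    return ModelComparison(
        reports=reports,
        fold_reports=folds,
        improvement_vs_mt=improvement,
        metric_sets={s.set_id: s.metrics for s in feature_sets},
    )
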
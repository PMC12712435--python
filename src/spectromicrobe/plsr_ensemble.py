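"""Ensemble partial least squares regression for spectra-to-microbiome retrieval.

This module implements the predictive workflow at the heart of the
package: single-response PLSR on mean-centred spectra, PRESS-based
selection of the number of latent components, MAE-based outlier
screening, a 200-member subset ensemble with per-plot predictive mean and
SD, standard evaluation metrics (R-squared, RMSE, NRMSE = RMSE/range,
bias), VIP-score interpretation (informative wavelengths have VIP > 1)
and simple NDVI/NDWI linear baselines.

PLSR algorithm
--------------
For a single response the NIPALS weight vector needs no inner iteration:
at each step ``w = E'f / ||E'f||``, scores ``t = Ew``, loadings
``p = E't / t't`` and ``q = f't / t't``, followed by deflation of both
``E`` and ``f``. Regression coefficients on the original predictor scale
are ``B_k = W (P'W)^{-1} q`` accumulated per component, so a single fit
yields predictions for every component count ``1..k`` (used by the PRESS
curve at no extra cost). Predictors are mean-centred but not
variance-scaled: vector-normalized spectra are already on a common scale
and unit-scaling would re-weight absorption features.

VIP
---
``VIP_j = sqrt(p * sum_a SS_a (w_ja/||w_a||)^2 / sum_a SS_a)`` with
``SS_a = q_a^2 t_a' t_a``; the mean of squared VIPs over predictors is 1
by construction, making 1 the natural "informative" threshold.

Randomness
----------
Every stochastic step takes a seed; sub-seeds for ensemble members and
resampling runs are derived from a master ``numpy.random.SeedSequence``
so results are reproducible and members independent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError

logger = logging.getLogger(__name__)


def _child_seeds(seed: int | None, n: int) -> list[int]:
    ss = np.random.SeedSequence(0 if seed is None else seed)
    return [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(n)]


# --------------------------------------------------------------------------
# Single PLSR model
# --------------------------------------------------------------------------


@dataclass
class PLSRModel:
    """A fitted single-response PLSR model.

    Attributes
    ----------
    coef_path : (p, A) array
        Regression coefficients using the first ``k+1`` components in
        column ``k`` (original predictor scale).
    """

    n_components: int
    x_mean: np.ndarray
    y_mean: float
    weights: np.ndarray      # W, p x A
    x_loadings: np.ndarray   # P, p x A
    y_loadings: np.ndarray   # q, A
    scores: np.ndarray       # T, n x A
    coef_path: np.ndarray    # p x A
    vip: np.ndarray          # p

    @property
    def coefficients(self) -> np.ndarray:
        return self.coef_path[:, self.n_components - 1]

    @property
    def intercept(self) -> float:
        return float(self.y_mean - self.x_mean @ self.coefficients)

    def predict(self, X: np.ndarray, n_components: int | None = None) -> np.ndarray:
        k = self.n_components if n_components is None else n_components
        k = min(k, self.n_components)
        b = self.coef_path[:, k - 1]
        return (np.asarray(X, dtype=float) - self.x_mean) @ b + self.y_mean

    def predict_path(self, X: np.ndarray) -> np.ndarray:
        """Predictions for every component count; shape (n, A)."""
        Xc = np.asarray(X, dtype=float) - self.x_mean
        return Xc @ self.coef_path + self.y_mean


def fit_plsr(X: np.ndarray, y: np.ndarray, n_components: int) -> PLSRModel:
    """Fit single-response PLSR on mean-centred data (no variance scaling).

    Component extraction stops early if the residual predictor or
    response variance collapses; the model then carries fewer components
    than requested, with the coefficient path padded by its last column.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if y.size != n:
        raise DataError("X and y sizes disagree")
    if not (np.isfinite(X).all() and np.isfinite(y).all()):
        raise DataError("X and y must be finite")
    if n_components < 1 or n_components > min(n - 1, p):
        raise DataError(f"n_components must be in [1, min(n-1, p)]; got {n_components}")
    if np.var(y) == 0:
        raise DataError("response has zero variance")

    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    E = X - x_mean
    f = y - y_mean

    W = np.zeros((p, n_components))
    P = np.zeros((p, n_components))
    Q = np.zeros(n_components)
    T = np.zeros((n, n_components))
    n_used = 0
    for _ in range(n_components):
        w = E.T @ f
        nw = float(np.linalg.norm(w))
        # Cauchy-Schwarz-relative tolerance on the covariance direction
        bound = float(np.sqrt((E**2).sum() * (f**2).sum()))
        if nw <= 1e-12 * bound or bound == 0.0:
            break
        w /= nw
        t = E @ w
        tt = float(t @ t)
        if tt <= 1e-28:
            break
        pvec = E.T @ t / tt
        q = float(f @ t) / tt
        E = E - np.outer(t, pvec)
        f = f - q * t
        W[:, n_used], P[:, n_used], Q[n_used], T[:, n_used] = w, pvec, q, t
        n_used += 1
    if n_used == 0:
        # degenerate predictors: fall back to the mean-only model
        coef_path = np.zeros((p, n_components))
        vip = np.zeros(p)
        return PLSRModel(
            n_components=1, x_mean=x_mean, y_mean=y_mean,
            weights=W[:, :1], x_loadings=P[:, :1], y_loadings=Q[:1],
            scores=T[:, :1], coef_path=coef_path, vip=vip,
        )
    W, P, Q, T = W[:, :n_used], P[:, :n_used], Q[:n_used], T[:, :n_used]

    # R = W (P'W)^{-1}; coef for k comps = R[:, :k] @ Q[:k]
    ptw = P.T @ W
    R = np.linalg.solve(ptw.T, W.T).T
    coef_path = np.cumsum(R * Q[None, :], axis=1)
    if n_used < n_components:
        pad = np.repeat(coef_path[:, -1:], n_components - n_used, axis=1)
        coef_path = np.hstack([coef_path, pad])

    # VIP
    ss = Q**2 * (T**2).sum(axis=0)
    wnorm2 = (W**2).sum(axis=0)
    wnorm2[wnorm2 == 0] = 1.0
    vip = np.sqrt(p * ((W**2 / wnorm2) @ ss) / ss.sum())

    return PLSRModel(
        n_components=n_used,
        x_mean=x_mean,
        y_mean=y_mean,
        weights=W,
        x_loadings=P,
        y_loadings=Q,
        scores=T,
        coef_path=coef_path,
        vip=vip,
    )


# --------------------------------------------------------------------------
# Component selection, outlier screening, splits
# --------------------------------------------------------------------------


@dataclass
class PressSelection:
    n_components: int
    press_mean: np.ndarray
    press_se: np.ndarray
    rule: str
    n_perm: int


def press_select(
    X: np.ndarray,
    y: np.ndarray,
    max_components: int | None = None,
    n_perm: int = 200,
    split_fraction: float = 0.7,
    seed: int | None = 0,
    rule: str = "one_se",
) -> PressSelection:
    """Choose the number of PLSR components by a jackknife PRESS curve.

    For each of ``n_perm`` random splits, a model is trained on a
    ``split_fraction`` subset and held-out squared errors are accumulated
    per component count (the PRESS statistic). ``rule='min'`` picks the
    global PRESS minimum; ``rule='one_se'`` (default) picks the smallest
    component count whose mean PRESS is within one standard error of that
    minimum — a parsimony rule that drops to one component for pure-noise
    responses.
    """
    if n_perm < 2:
        raise DataError("n_perm must be >= 2")
    if rule not in ("one_se", "min"):
        raise DataError(f"unknown selection rule: {rule}")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = X.shape[0]
    n_train = int(np.floor(split_fraction * n))
    if n_train < 2 or n_train >= n:
        raise DataError("split_fraction leaves no training or no validation rows")
    cap = min(n_train - 1, X.shape[1])
    if max_components is None:
        max_components = min(15, cap)
    if max_components > cap:
        logger.warning("max_components capped at %d for subset size", cap)
        max_components = cap

    press = np.zeros((n_perm, max_components))
    rng = np.random.default_rng(seed)
    for i in range(n_perm):
        perm = rng.permutation(n)
        tr, te = perm[:n_train], perm[n_train:]
        model = fit_plsr(X[tr], y[tr], max_components)
        pred = model.predict_path(X[te])
        press[i] = ((pred - y[te][:, None]) ** 2).sum(axis=0)
    mean = press.mean(axis=0)
    se = press.std(axis=0, ddof=1) / np.sqrt(n_perm)
    k_min = int(np.argmin(mean))
    if rule == "min":
        k = k_min + 1
    else:
        within = np.nonzero(mean <= mean[k_min] + se[k_min])[0]
        k = int(within[0]) + 1
    return PressSelection(k, mean, se, rule, n_perm)


@dataclass
class OutlierScreen:
    kept_indices: np.ndarray
    removed_indices: np.ndarray
    mae: np.ndarray
    n_runs: int


def outlier_screen(
    X: np.ndarray,
    y: np.ndarray,
    n_runs: int = 200,
    remove_fraction: float = 0.05,
    n_components: int | None = None,
    split_fraction: float = 0.7,
    seed: int | None = 0,
) -> OutlierScreen:
    """Flag observations with the largest held-out mean absolute error.

    Each run fits a model on a random ``split_fraction`` subset; held-out
    absolute errors are averaged per observation across runs, and the top
    ``floor(remove_fraction * n)`` observations by MAE are removed (ties
    broken by larger response value, then index). Observations never held
    out fall back to in-sample errors, with a warning.
    """
    if not (0 <= remove_fraction < 1):
        raise DataError("remove_fraction must be in [0, 1)")
    if n_runs < 1:
        raise DataError("n_runs must be >= 1")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = X.shape[0]
    n_train = int(np.floor(split_fraction * n))
    cap = min(n_train - 1, X.shape[1])
    k_comp = min(10, cap) if n_components is None else min(n_components, cap)

    err_sum = np.zeros(n)
    err_cnt = np.zeros(n)
    in_sum = np.zeros(n)
    in_cnt = np.zeros(n)
    rng = np.random.default_rng(seed)
    for _ in range(n_runs):
        perm = rng.permutation(n)
        tr, te = perm[:n_train], perm[n_train:]
        model = fit_plsr(X[tr], y[tr], k_comp)
        err = np.abs(model.predict(X[te]) - y[te])
        err_sum[te] += err
        err_cnt[te] += 1
        ein = np.abs(model.predict(X[tr]) - y[tr])
        in_sum[tr] += ein
        in_cnt[tr] += 1
    never = err_cnt == 0
    if never.any():
        logger.warning(
            "%d observations never held out; using in-sample errors", int(never.sum())
        )
    mae = np.where(never, in_sum / np.maximum(in_cnt, 1), err_sum / np.maximum(err_cnt, 1))
    n_remove = int(np.floor(remove_fraction * n))
    order = np.lexsort((np.arange(n), -y, -mae))  # mae desc, y desc, index asc
    removed = np.sort(order[:n_remove])
    kept = np.sort(order[n_remove:])
    return OutlierScreen(kept, removed, mae, n_runs)


def split_calibration(
    n: int, calibration_fraction: float = 0.7, seed: int | None = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Random disjoint calibration/validation partition of ``range(n)``.

    Calibration size is ``floor(fraction * n)``; the validation remainder
    must not touch any fitting step.
    """
    if not (0 < calibration_fraction < 1):
        raise DataError("calibration_fraction must be in (0, 1)")
    if n < 10:
        logger.warning("n=%d is small; the split will be unstable", n)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_cal = int(np.floor(calibration_fraction * n))
    return np.sort(perm[:n_cal]), np.sort(perm[n_cal:])


# --------------------------------------------------------------------------
# Ensemble
# --------------------------------------------------------------------------


@dataclass
class PLSREnsemble:
    members: list[PLSRModel]
    member_indices: list[np.ndarray]
    n_components: int
    n_predictors: int
    response_name: str = "response"

    @property
    def n_models(self) -> int:
        return len(self.members)

    def coefficient_summary(self) -> tuple[np.ndarray, np.ndarray]:
        coefs = np.stack([m.coefficients for m in self.members])
        return coefs.mean(axis=0), coefs.std(axis=0, ddof=1)

    def vip_mean(self) -> np.ndarray:
        return np.stack([m.vip for m in self.members]).mean(axis=0)


def ensemble_fit(
    X: np.ndarray,
    y: np.ndarray,
    n_components: int,
    n_models: int = 200,
    subset_fraction: float = 0.7,
    seed: int | None = 0,
    response_name: str = "response",
) -> PLSREnsemble:
    """Fit ``n_models`` PLSR members on independent random calibration subsets."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = X.shape[0]
    n_sub = int(np.floor(subset_fraction * n))
    if n_sub <= n_components:
        raise DataError("subset too small for the requested component count")
    members, subsets = [], []
    for s in _child_seeds(seed, n_models):
        rng = np.random.default_rng(s)
        idx = np.sort(rng.choice(n, size=n_sub, replace=False))
        members.append(fit_plsr(X[idx], y[idx], n_components))
        subsets.append(idx)
    return PLSREnsemble(members, subsets, n_components, X.shape[1], response_name)


def ensemble_predict(ens: PLSREnsemble, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-row mean and sample SD of member predictions (prediction uncertainty)."""
    X = np.asarray(X, dtype=float)
    if X.shape[1] != ens.n_predictors:
        raise DataError(
            f"predictor count mismatch: model has {ens.n_predictors}, got {X.shape[1]}"
        )
    preds = np.stack([m.predict(X) for m in ens.members])
    sd = preds.std(axis=0, ddof=1) if preds.shape[0] > 1 else np.zeros(X.shape[0])
    return preds.mean(axis=0), sd


# --------------------------------------------------------------------------
# Evaluation, VIP interpretation, baselines
# --------------------------------------------------------------------------


@dataclass
class ModelMetrics:
    r2: float          # squared Pearson correlation (prediction-plot R^2)
    rmse: float
    nrmse: float       # rmse / observed range
    bias: float        # mean(predicted - observed)
    n: int
    r2_one_to_one: float = float("nan")  # Nash-Sutcliffe, for transparency


def evaluate(observed: np.ndarray, predicted: np.ndarray) -> ModelMetrics:
    """Standard retrieval metrics between observed and predicted values."""
    obs = np.asarray(observed, dtype=float).ravel()
    pred = np.asarray(predicted, dtype=float).ravel()
    if obs.size != pred.size or obs.size < 2:
        raise DataError("observed/predicted must be equal-length with n >= 2")
    rng_obs = float(obs.max() - obs.min())
    rmse = float(np.sqrt(np.mean((pred - obs) ** 2)))
    bias = float(np.mean(pred - obs))
    if np.std(obs) == 0 or np.std(pred) == 0:
        r2 = float("nan")
    else:
        r2 = float(np.corrcoef(obs, pred)[0, 1] ** 2)
    nrmse = rmse / rng_obs if rng_obs > 0 else float("nan")
    denom = float(((obs - obs.mean()) ** 2).sum())
    nse = 1.0 - float(((pred - obs) ** 2).sum()) / denom if denom > 0 else float("nan")
    return ModelMetrics(r2, rmse, nrmse, bias, obs.size, nse)


def vip_informative(
    model_or_ensemble: PLSRModel | PLSREnsemble, threshold: float = 1.0
) -> tuple[np.ndarray, np.ndarray]:
    """Per-wavelength VIP (ensemble mean) and the VIP > threshold mask."""
    if isinstance(model_or_ensemble, PLSREnsemble):
        vip = model_or_ensemble.vip_mean()
    else:
        vip = model_or_ensemble.vip
    return vip, vip > threshold


def baseline_index_model(
    index_values: np.ndarray, y: np.ndarray
) -> tuple[ModelMetrics, float, float]:
    """OLS of the response on a single vegetation index (NDVI/NDWI baseline).

    Returns (metrics, slope, intercept); metrics are in-sample on the
    fitted line, matching how index baselines are reported.
    """
    x = np.asarray(index_values, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size < 3:
        raise DataError("need at least 3 plots for the baseline model")
    if np.std(x) == 0:
        raise DataError("constant index; baseline undefined")
    res = stats.linregress(x, y)
    pred = res.intercept + res.slope * x
    return evaluate(y, pred), float(res.slope), float(res.intercept)


# --------------------------------------------------------------------------
# Full per-response workflow
# --------------------------------------------------------------------------


@dataclass
class WorkflowResult:
    """Everything the per-response ensemble workflow produces."""

    metrics: ModelMetrics
    selection: PressSelection
    screen: OutlierScreen
    ensemble: PLSREnsemble
    calibration_indices: np.ndarray
    validation_indices: np.ndarray
    predictions: pd.DataFrame          # validation rows: observed, mean, sd
    vip: np.ndarray
    informative_mask: np.ndarray
    coefficients_mean: np.ndarray = field(repr=False, default=None)
    coefficients_sd: np.ndarray = field(repr=False, default=None)


def run_plsr_workflow(
    X: np.ndarray,
    y: np.ndarray,
    seed: int | None = 0,
    n_models: int = 200,
    outlier_fraction: float = 0.05,
    outlier_runs: int = 200,
    calibration_fraction: float = 0.7,
    press_permutations: int = 200,
    max_components: int | None = None,
    press_rule: str = "one_se",
    response_name: str = "response",
) -> WorkflowResult:
    """Outlier screen -> calibration split -> PRESS selection -> ensemble.

    The validation rows are withheld from screening-informed fitting,
    component selection and ensemble training; metrics are computed on
    ensemble-mean predictions for those rows.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    seeds = _child_seeds(seed, 4)
    screen = outlier_screen(
        X, y, n_runs=outlier_runs, remove_fraction=outlier_fraction, seed=seeds[0]
    )
    Xk, yk = X[screen.kept_indices], y[screen.kept_indices]
    cal, val = split_calibration(len(yk), calibration_fraction, seed=seeds[1])
    selection = press_select(
        Xk[cal], yk[cal], max_components=max_components,
        n_perm=press_permutations, seed=seeds[2], rule=press_rule,
    )
    ens = ensemble_fit(
        Xk[cal], yk[cal], selection.n_components, n_models=n_models,
        seed=seeds[3], response_name=response_name,
    )
    mean, sd = ensemble_predict(ens, Xk[val])
    metrics = evaluate(yk[val], mean)
    vip, mask = vip_informative(ens)
    cmean, csd = ens.coefficient_summary()
    predictions = pd.DataFrame(
        {"observed": yk[val], "predicted_mean": mean, "predicted_sd": sd},
        index=val,
    )
    return WorkflowResult(
        metrics=metrics,
        selection=selection,
        screen=screen,
        ensemble=ens,
        calibration_indices=cal,
        validation_indices=val,
        predictions=predictions,
        vip=vip,
        informative_mask=mask,
        coefficients_mean=cmean,
        coefficients_sd=csd,
    )
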
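"""Association analyses between environmental predictor groups and the
soil microbiome.

Implements the community-ecology toolkit used to dissect how foliar
traits, land cover, soil properties and climate/location jointly explain
microbial variation:

* PCA with leading-axis selection (axes explaining > 80% of variance by
  default) to decorrelate predictor groups before variation partitioning.
* Variation partitioning over an arbitrary number of predictor groups via
  inclusion-exclusion on redundancy-analysis (RDA) R-squared, with the
  Ezekiel adjustment; all ``2^g - 1`` unique/shared Venn fractions and the
  residual are reported.
* Permutation tests of each group's unique contribution through partial
  RDA with Freedman-Lane permutation of reduced-model residuals.
* Spearman and partial Spearman correlation tables with Bonferroni
  correction; partial correlations invert the rank-correlation matrix.
* Greedy pairwise collinearity screening (caret ``findCorrelation`` style).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError

logger = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# PCA leading axes
# --------------------------------------------------------------------------


@dataclass
class PCAResult:
    scores: pd.DataFrame
    loadings: pd.DataFrame
    explained_ratio: np.ndarray
    n_axes: int
    dropped_constant: list[str] = field(default_factory=list)


def pca_leading_axes(block: pd.DataFrame, variance_threshold: float = 0.8) -> PCAResult:
    """PCA on standardized variables, keeping the leading axes.

    Returns the smallest number of axes whose cumulative explained
    variance strictly exceeds ``variance_threshold``. Constant variables
    are dropped with a warning.
    """
    if block.shape[1] < 1:
        raise DataError("PCA needs at least one variable")
    x = block.astype(float)
    sd = x.std(ddof=1)
    dropped = list(sd.index[(sd == 0) | sd.isna()])
    if dropped:
        logger.warning("dropping constant variables before PCA: %s", dropped)
        x = x.drop(columns=dropped)
    if x.shape[1] == 0:
        raise DataError("all variables constant; PCA undefined")
    z = (x - x.mean()) / x.std(ddof=1)
    u, s, vt = np.linalg.svd(z.to_numpy(), full_matrices=False)
    var = s**2
    ratio = var / var.sum()
    cum = np.cumsum(ratio)
    n_axes = int(np.searchsorted(cum, variance_threshold, side="right")) + 1
    n_axes = min(n_axes, ratio.size)
    scores = pd.DataFrame(
        (u * s)[:, :n_axes], index=block.index,
        columns=[f"PC{i + 1}" for i in range(n_axes)],
    )
    loadings = pd.DataFrame(
        vt[:n_axes].T, index=x.columns, columns=scores.columns
    )
    return PCAResult(scores, loadings, ratio, n_axes, dropped)


# --------------------------------------------------------------------------
# RDA R^2, variation partitioning, partial RDA permutation test
# --------------------------------------------------------------------------


def _design(X: np.ndarray | None) -> np.ndarray | None:
    if X is None or X.size == 0:
        return None
    X = np.asarray(X, dtype=float)
    return X - X.mean(axis=0)


def _qr_basis(X: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the column space (rank-revealing)."""
    q, r = np.linalg.qr(X)
    diag = np.abs(np.diag(r))
    tol = max(X.shape) * np.finfo(float).eps * (diag.max() if diag.size else 0.0)
    return q[:, diag > tol]


def rda_r2(Y: np.ndarray, X: np.ndarray) -> tuple[float, int]:
    """RDA R^2 = trace of explained variance over total (centred) variance.

    Returns ``(r2, rank_of_X)``. ``Y`` may be multivariate.
    """
    Yc = np.asarray(Y, dtype=float)
    Yc = Yc - Yc.mean(axis=0)
    total = float((Yc**2).sum())
    if total == 0:
        raise DataError("response has zero variance")
    q = _qr_basis(_design(X))
    fitted = q @ (q.T @ Yc)
    return float((fitted**2).sum()) / total, q.shape[1]


def ezekiel_adjust(r2: float, n: int, p: int) -> float:
    """Ezekiel's adjusted R^2: 1 - (1 - R^2)(n - 1)/(n - p - 1)."""
    if n - p - 1 <= 0:
        return float("nan")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


@dataclass
class VariationPartition:
    """Unique/shared explained-variance fractions across predictor groups."""

    groups: list[str]
    fractions: dict[frozenset, float]          # adjusted, one per Venn region
    fractions_unadjusted: dict[frozenset, float]
    residual: float                            # adjusted residual = 1 - adjR2(all)
    residual_unadjusted: float
    subset_r2: dict[frozenset, float]
    subset_r2_adjusted: dict[frozenset, float]
    tests: dict[str, "RDATestResult"] = field(default_factory=dict)

    def unique(self, group: str, adjusted: bool = True) -> float:
        src = self.fractions if adjusted else self.fractions_unadjusted
        return src[frozenset([group])]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for region in sorted(self.fractions, key=lambda m: (len(m), sorted(m))):
            adj = self.fractions[region]
            rows.append(
                {
                    "region": "&".join(sorted(region)),
                    "fraction_adjusted": adj,
                    "fraction_unadjusted": self.fractions_unadjusted[region],
                    "fraction_display": max(0.0, adj),
                }
            )
        rows.append(
            {
                "region": "residual",
                "fraction_adjusted": self.residual,
                "fraction_unadjusted": self.residual_unadjusted,
                "fraction_display": max(0.0, self.residual),
            }
        )
        return pd.DataFrame(rows)


def varpart(Y: pd.DataFrame | np.ndarray, groups: dict[str, pd.DataFrame]) -> VariationPartition:
    """Variation partitioning of ``Y`` across named predictor groups.

    Computes RDA R^2 for every non-empty subset of groups, then resolves
    the ``2^g - 1`` Venn-region fractions by inclusion-exclusion using
    Ezekiel-adjusted R^2 (unadjusted also kept). The unadjusted fractions
    plus the unadjusted residual sum to one exactly. Negative (adjusted)
    fractions are reported as-is; ``to_frame`` adds a zero-floored display
    column.
    """
    names = list(groups)
    if not names:
        raise DataError("need at least one predictor group")
    Ymat = np.asarray(Y, dtype=float)
    n = Ymat.shape[0]
    blocks = {g: np.asarray(groups[g], dtype=float) for g in names}
    for g, b in blocks.items():
        if b.shape[0] != n:
            raise DataError(f"group {g} row count differs from response")
    total_p = sum(b.shape[1] for b in blocks.values())
    if n <= total_p + 1:
        raise DataError(
            f"too few rows (n={n}) for {total_p} predictors; rank-deficient fit"
        )

    r2_raw: dict[frozenset, float] = {frozenset(): 0.0}
    r2_adj: dict[frozenset, float] = {frozenset(): 0.0}
    for r in range(1, len(names) + 1):
        for combo in itertools.combinations(names, r):
            key = frozenset(combo)
            X = np.hstack([blocks[g] for g in names if g in key])
            r2, rank = rda_r2(Ymat, X)
            r2_raw[key] = r2
            r2_adj[key] = ezekiel_adjust(r2, n, rank)

    allset = frozenset(names)

    def regions(r2_of: dict[frozenset, float]) -> dict[frozenset, float]:
        out: dict[frozenset, float] = {}
        for r in range(1, len(names) + 1):
            for combo in itertools.combinations(names, r):
                m = frozenset(combo)
                total = 0.0
                for cr in range(len(combo) + 1):
                    for sub in itertools.combinations(combo, cr):
                        c = frozenset(sub)
                        sign = (-1) ** (len(m) - len(c))
                        total += sign * (r2_of[allset] - r2_of[allset - c])
                out[m] = total
        return out

    fr_adj = regions(r2_adj)
    fr_raw = regions(r2_raw)
    return VariationPartition(
        groups=names,
        fractions=fr_adj,
        fractions_unadjusted=fr_raw,
        residual=1.0 - r2_adj[allset],
        residual_unadjusted=1.0 - r2_raw[allset],
        subset_r2={k: v for k, v in r2_raw.items() if k},
        subset_r2_adjusted={k: v for k, v in r2_adj.items() if k},
    )


@dataclass
class RDATestResult:
    f_statistic: float
    p_value: float
    n_permutations: int
    df_model: int
    df_residual: int


def partial_rda_test(
    Y: np.ndarray | pd.DataFrame,
    X: np.ndarray | pd.DataFrame,
    Z: np.ndarray | pd.DataFrame | None = None,
    n_perm: int = 999,
    seed: int | None = 0,
) -> RDATestResult:
    """Permutation test of a predictor group conditioned on covariates.

    Both response and focal block are residualized on the conditioning
    block; the pseudo-F compares constrained to residual variance.
    Permutations shuffle the reduced-model residuals (Freedman-Lane), and
    each permuted response is re-residualized on the conditioners.
    p = (1 + #{F* >= F_obs}) / (1 + n_perm), so p is never zero.
    """
    if n_perm < 1:
        raise DataError("n_perm must be >= 1")
    Ymat = np.asarray(Y, dtype=float)
    if Ymat.ndim == 1:
        Ymat = Ymat[:, None]
    Ymat = Ymat - Ymat.mean(axis=0)
    n = Ymat.shape[0]
    Xc = _design(np.asarray(X, dtype=float))
    if Z is not None and np.asarray(Z).size:
        Zc = _design(np.asarray(Z, dtype=float))
        qz = _qr_basis(Zc)
        rank_z = qz.shape[1]
        Yr = Ymat - qz @ (qz.T @ Ymat)
        Xr = Xc - qz @ (qz.T @ Xc)
    else:
        qz = None
        rank_z = 0
        Yr = Ymat
        Xr = Xc
    qx = _qr_basis(Xr)
    rank_x = qx.shape[1]
    df_res = n - rank_z - rank_x - 1
    if df_res <= 0:
        raise DataError("no residual degrees of freedom")

    def pseudo_f(resp: np.ndarray) -> float:
        fitted = qx @ (qx.T @ resp)
        ss_fit = float((fitted**2).sum())
        ss_res = float((resp**2).sum()) - ss_fit
        if ss_res <= 0:
            raise DataError("zero residual variance; p undefined")
        return (ss_fit / rank_x) / (ss_res / df_res)

    f_obs = pseudo_f(Yr)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        Yp = Yr[perm]
        if qz is not None:
            Yp = Yp - qz @ (qz.T @ Yp)
        if pseudo_f(Yp) >= f_obs:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return RDATestResult(f_obs, p, n_perm, rank_x, df_res)


def varpart_with_tests(
    Y: pd.DataFrame | np.ndarray,
    groups: dict[str, pd.DataFrame],
    n_perm: int = 999,
    seed: int | None = 0,
) -> VariationPartition:
    """Variation partitioning plus a partial-RDA permutation test per group,
    each conditioned on all remaining groups."""
    part = varpart(Y, groups)
    names = list(groups)
    ss = np.random.SeedSequence(seed if seed is not None else 0)
    children = ss.spawn(len(names))
    for g, child in zip(names, children):
        others = [groups[o] for o in names if o != g]
        Z = np.hstack([np.asarray(o, dtype=float) for o in others]) if others else None
        part.tests[g] = partial_rda_test(
            Y, groups[g], Z, n_perm=n_perm, seed=child.generate_state(1)[0] % (2**31)
        )
    return part


# --------------------------------------------------------------------------
# Spearman / partial Spearman correlation tables
# --------------------------------------------------------------------------


def _midranks(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _corr_p(rho: float, df: int) -> float:
    if df <= 0:
        return float("nan")
    rho = min(1.0, max(-1.0, rho))
    if abs(rho) == 1.0:
        return 0.0
    t = rho * np.sqrt(df / (1.0 - rho**2))
    return float(2 * stats.t.sf(abs(t), df))


def spearman_matrix(
    X: pd.DataFrame, Y: pd.DataFrame, alpha: float = 0.05
) -> pd.DataFrame:
    """All X-by-Y Spearman correlations with Bonferroni-corrected flags.

    Mid-ranks handle ties; two-sided p-values use the t approximation with
    n - 2 df; Bonferroni uses m = number of emitted pairs. Constant
    columns yield NaN rho and a ``degenerate`` flag.
    """
    rows = []
    m = X.shape[1] * Y.shape[1]
    for xc in X.columns:
        for yc in Y.columns:
            pair = pd.concat([X[xc], Y[yc]], axis=1).dropna()
            n = len(pair)
            if n < 3 or pair[xc].nunique() < 2 or pair[yc].nunique() < 2:
                rows.append(
                    dict(x=xc, y=yc, rho=np.nan, p=np.nan, n=n,
                         significant=False, degenerate=True)
                )
                continue
            rx = _midranks(pair[xc].to_numpy())
            ry = _midranks(pair[yc].to_numpy())
            rho = float(np.corrcoef(rx, ry)[0, 1])
            p = _corr_p(rho, n - 2)
            rows.append(
                dict(x=xc, y=yc, rho=rho, p=p, n=n,
                     significant=bool(p <= alpha / m), degenerate=False)
            )
    out = pd.DataFrame(rows)
    out["m_tests"] = m
    out["alpha"] = alpha
    return out


def partial_spearman(
    X: pd.DataFrame,
    Y: pd.DataFrame,
    Z: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Partial Spearman correlations of X with Y controlling for Z.

    All variables are rank-transformed (mid-ranks); the partial
    correlation comes from inverting the rank-Pearson correlation matrix
    of (x, y, Z). p-values use a t distribution with n - 2 - |Z| df.
    With an empty Z this reduces exactly to the Spearman table.
    """
    if Z is None or Z.shape[1] == 0:
        out = spearman_matrix(X, Y, alpha)
        out["confounders"] = ""
        return out
    conf = ",".join(map(str, Z.columns))
    rows = []
    m = X.shape[1] * Y.shape[1]
    k = Z.shape[1]
    for xc in X.columns:
        for yc in Y.columns:
            cols = pd.concat([X[[xc]], Y[[yc]], Z], axis=1).dropna()
            n = len(cols)
            if n < k + 3 or cols[xc].nunique() < 2 or cols[yc].nunique() < 2:
                rows.append(
                    dict(x=xc, y=yc, rho=np.nan, p=np.nan, n=n,
                         significant=False, degenerate=True, confounders=conf)
                )
                continue
            ranks = np.column_stack([_midranks(cols[c].to_numpy()) for c in cols.columns])
            corr = np.corrcoef(ranks, rowvar=False)
            corr_z = corr[2:, 2:]
            if np.linalg.cond(corr_z) > 1e10:
                raise DataError(
                    f"singular rank-correlation matrix among confounders {conf}"
                )
            if np.linalg.cond(corr) > 1e10:
                # x or y fully explained by the confounders: degenerate pair
                rows.append(
                    dict(x=xc, y=yc, rho=np.nan, p=np.nan, n=n,
                         significant=False, degenerate=True, confounders=conf)
                )
                continue
            prec = np.linalg.inv(corr)
            denom = np.sqrt(prec[0, 0] * prec[1, 1])
            rho = float(-prec[0, 1] / denom) if denom > 0 else np.nan
            if not np.isfinite(rho):
                rows.append(
                    dict(x=xc, y=yc, rho=np.nan, p=np.nan, n=n,
                         significant=False, degenerate=True, confounders=conf)
                )
                continue
            p = _corr_p(rho, n - 2 - k)
            rows.append(
                dict(x=xc, y=yc, rho=rho, p=p, n=n,
                     significant=bool(p <= alpha / m), degenerate=False,
                     confounders=conf)
            )
    out = pd.DataFrame(rows)
    out["m_tests"] = m
    out["alpha"] = alpha
    return out


# --------------------------------------------------------------------------
# Collinearity screening
# --------------------------------------------------------------------------


def collinearity_screen(
    X: pd.DataFrame, cutoff: float = 0.7, method: str = "spearman"
) -> tuple[list[str], list[str]]:
    """Greedy removal of highly correlated variables (|rho| >= cutoff).

    While any pair exceeds the cutoff, the member of the worst pair with
    the larger mean absolute correlation against everything else is
    dropped. Deterministic given column order. Returns (kept, dropped).
    """
    if X.shape[1] < 2:
        return list(X.columns), []
    cols = list(X.columns)
    corr = X.corr(method=method).abs()
    dropped: list[str] = []
    while True:
        sub = corr.loc[cols, cols].copy()
        np.fill_diagonal(sub.values, 0.0)
        worst = sub.stack().idxmax()
        if sub.loc[worst] < cutoff:
            break
        a, b = worst
        mean_a = sub.loc[a].mean()
        mean_b = sub.loc[b].mean()
        victim = a if mean_a >= mean_b else b
        cols.remove(victim)
        dropped.append(victim)
        if len(cols) < 2:
            break
    return cols, dropped
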
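"""Core-to-plot aggregation and temporal alignment of multi-source tables.

Field measurements arrive at the soil-core level while imagery and models
operate on plots, so core values must be aggregated upward. Two estimators
are provided:

* ``mean`` — the arithmetic mean of a plot's cores.
* ``shrinkage`` — empirical-Bayes normal-normal partial pooling: each
  plot's core mean is pulled toward the across-plot (site-level) mean with
  weight set by the within-plot variance (pooled across plots) and a
  method-of-moments estimate of the between-plot variance. Plots with a
  single core are prior-dominated; an infinitely wide prior recovers the
  simple mean. This is a documented closed-form approximation of
  hierarchical Bayesian plot averaging.

Temporal alignment keeps a plot-year only when the soil sampling date is
within a window of the airborne image date (inclusive, default +/-60 d)
and every other table has an observation within a wider cross-table window
(default +/-120 d) of the image. Among multiple qualifying years, the one
minimizing the |soil - image| gap wins (ties -> earliest year).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError


@dataclass(frozen=True)
class AlignmentRule:
    max_offset_days: int = 60
    cross_table_offset_days: int = 120

    def __post_init__(self) -> None:
        if self.max_offset_days <= 0 or self.cross_table_offset_days <= 0:
            raise DataError("alignment offsets must be positive")


def shrink_estimates(
    plot_means: np.ndarray,
    n_cores: np.ndarray,
    within_var: float,
    between_var: float,
    grand_mean: float,
) -> np.ndarray:
    """Normal-normal posterior means for plot values.

    estimate_i = (n_i/s2 * xbar_i + mu/t2) / (n_i/s2 + 1/t2). Degenerate
    limits: t2 = inf (or s2 = 0) returns the plot means; t2 = 0 returns the
    grand mean. Every estimate lies between its plot mean and the grand mean.
    """
    plot_means = np.asarray(plot_means, dtype=float)
    n_cores = np.asarray(n_cores, dtype=float)
    if within_var <= 0:
        return plot_means.copy()
    if not np.isfinite(between_var):
        return plot_means.copy()
    if between_var <= 0:
        return np.full_like(plot_means, grand_mean)
    w_data = n_cores / within_var
    w_prior = 1.0 / between_var
    return (w_data * plot_means + w_prior * grand_mean) / (w_data + w_prior)


def _moments(values: pd.Series, plots: pd.Series) -> tuple[pd.Series, pd.Series, float, float, float]:
    grouped = values.groupby(plots)
    means = grouped.mean()
    ns = grouped.count()
    # pooled within-plot variance from plots with >= 2 cores
    multi = ns[ns >= 2].index
    if len(multi):
        ss = sum(
            ((values[plots == p] - means[p]) ** 2).sum() for p in multi
        )
        dof = int((ns[multi] - 1).sum())
        s2 = ss / dof if dof > 0 else 0.0
    else:
        s2 = 0.0
    mu = float(means.mean())
    var_means = float(means.var(ddof=1)) if len(means) > 1 else 0.0
    t2 = max(0.0, var_means - s2 * float((1.0 / ns).mean()))
    return means, ns, s2, t2, mu


def aggregate_cores(
    cores: pd.DataFrame,
    method: str = "mean",
    plot_col: str = "plot_id",
    variable_col: str = "variable",
    value_col: str = "value",
) -> pd.DataFrame:
    """Aggregate a long core-level table to one row per plot.

    ``cores`` columns: plot, variable name, value. Returns a wide plot x
    variable table. ``method='mean'`` takes arithmetic means;
    ``method='shrinkage'`` applies empirical-Bayes partial pooling per
    variable (see module docstring). Missing plot/variable combinations
    are NaN.
    """
    if method not in ("mean", "shrinkage"):
        raise DataError(f"unknown aggregation method: {method}")
    data = cores.dropna(subset=[value_col])
    plots = sorted(cores[plot_col].astype(str).unique())
    out = pd.DataFrame(index=pd.Index(plots, name=plot_col))
    for var, sub in data.groupby(variable_col):
        means, ns, s2, t2, mu = _moments(
            sub[value_col].astype(float), sub[plot_col].astype(str)
        )
        if method == "mean":
            est = means
        else:
            est = pd.Series(
                shrink_estimates(means.to_numpy(), ns.to_numpy(), s2, t2, mu),
                index=means.index,
            )
        out[var] = est.reindex(out.index)
    return out


def average_asv_matrix(counts: pd.DataFrame, plot_of_sample: pd.Series) -> pd.DataFrame:
    """Plot-level ASV matrix by simple averaging of core samples.

    ASV matrices are always aggregated by plain means (partial pooling per
    ASV is impractical at tens of thousands of columns).
    """
    plots = plot_of_sample.reindex(counts.index)
    if plots.isna().any():
        raise DataError("every sample needs a plot assignment")
    return counts.groupby(plots).mean()


def align_observations(
    candidates: pd.DataFrame,
    other_tables: dict[str, pd.DataFrame] | None = None,
    rule: AlignmentRule = AlignmentRule(),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Select one temporally aligned observation year per plot.

    ``candidates`` has one row per plot-year with columns
    ``plot_id, image_date, soil_date``. Each table in ``other_tables``
    (name -> DataFrame with ``plot_id, date``) must supply an observation
    within ``cross_table_offset_days`` of the candidate's image date.

    Returns ``(kept, exclusions)``: ``kept`` has one row per surviving plot
    with the winning dates and the soil-image gap in days; ``exclusions``
    logs every rejected candidate row with the rule violated and offsets.
    Kept and excluded candidates partition the input.
    """
    other_tables = other_tables or {}
    cand = candidates.copy()
    cand["image_date"] = pd.to_datetime(cand["image_date"]).dt.normalize()
    cand["soil_date"] = pd.to_datetime(cand["soil_date"]).dt.normalize()
    cand["gap_days"] = (cand["soil_date"] - cand["image_date"]).dt.days.abs()

    excl_rows = []
    ok = cand["gap_days"] <= rule.max_offset_days
    for _, row in cand[~ok].iterrows():
        excl_rows.append(
            {
                "plot_id": row["plot_id"],
                "rule": f"soil_image_gap>{rule.max_offset_days}d",
                "offset_days": int(row["gap_days"]),
            }
        )
    cand = cand[ok]

    for name, table in other_tables.items():
        tbl = table.copy()
        tbl["date"] = pd.to_datetime(tbl["date"]).dt.normalize()
        keep_mask = []
        for _, row in cand.iterrows():
            dates = tbl.loc[tbl["plot_id"] == row["plot_id"], "date"]
            if dates.empty:
                offsets = None
            else:
                offsets = (dates - row["image_date"]).dt.days.abs().min()
            within = offsets is not None and offsets <= rule.cross_table_offset_days
            if not within:
                excl_rows.append(
                    {
                        "plot_id": row["plot_id"],
                        "rule": f"{name}_gap>{rule.cross_table_offset_days}d",
                        "offset_days": None if offsets is None else int(offsets),
                    }
                )
            keep_mask.append(within)
        cand = cand[np.array(keep_mask, dtype=bool)] if len(keep_mask) else cand

    # among qualifying years per plot: smallest soil-image gap, ties -> earliest
    cand = cand.sort_values(["plot_id", "gap_days", "image_date"], kind="mergesort")
    winners = cand.groupby("plot_id", as_index=False).first()
    losers = cand.loc[~cand.index.isin(cand.groupby("plot_id").head(1).index)]
    for _, row in losers.iterrows():
        excl_rows.append(
            {
                "plot_id": row["plot_id"],
                "rule": "superseded_by_smaller_gap_year",
                "offset_days": int(row["gap_days"]),
            }
        )
    exclusions = pd.DataFrame(excl_rows, columns=["plot_id", "rule", "offset_days"])
    return winners.reset_index(drop=True), exclusions
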
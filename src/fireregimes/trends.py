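"""Burned-area trend analysis: regime-wide and rainfall-decoupled.

Two complementary views of change over the analysis span:

* regime-wide ordinary least squares trends in annual burned area summed
  over a regime x region cell set, with the relative change over the span
  expressed against the fitted first-year value;
* pixel-wise trends *decoupled from rainfall*: annual burned area is
  regressed on the year index together with antecedent 6-month (drought
  effect) and 24-month (fuel build-up effect) precipitation sums, and the
  year coefficient — the trend left over once precipitation-driven
  variation is absorbed — is read as the anthropogenic component.  The
  per-pixel t-value of that coefficient is the map statistic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm


@dataclass
class TrendResult:
    slope: float
    t_value: float
    p_value: float
    relative_change_pct: float
    n_years: int
    significant: bool
    degenerate: bool = False


@dataclass
class PrecipFeatures:
    """Antecedent precipitation sums per cell and analysis year (mm)."""

    p6: np.ndarray     # (n_cells, n_years)
    p24: np.ndarray
    years: list[int]


def regime_annual_series(
    burned_area: np.ndarray,
    cell_mask: np.ndarray,
) -> np.ndarray:
    """Yearly total burned area over a cell set; input (n_cells, n_years, 12)."""
    mask = np.asarray(cell_mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty cell set")
    return burned_area[mask].sum(axis=(0, 2))


def ols_trend(yearly: np.ndarray, alpha: float = 0.05) -> TrendResult:
    """OLS trend of an annual series with a two-sided slope t-test.

    ``relative_change_pct`` is 100 * slope * (n_years - 1) divided by the
    fitted value at the first year, i.e. the fitted-endpoint change over
    the span as a percentage of the fitted start.
    """
    y = np.asarray(yearly, dtype=float)
    n = y.size
    if n < 5:
        raise ValueError("need at least 5 years")
    t = np.arange(n, dtype=float)
    if np.ptp(y) == 0:
        return TrendResult(0.0, 0.0, 1.0, 0.0, n, False, degenerate=True)
    fit = sm.OLS(y, sm.add_constant(t)).fit()
    slope, tval, pval = fit.params[1], fit.tvalues[1], fit.pvalues[1]
    start = fit.params[0]  # fitted value at t = 0
    rel = 100.0 * slope * (n - 1) / start if start != 0 else np.nan
    return TrendResult(float(slope), float(tval), float(pval), float(rel),
                       n, bool(pval < alpha))


def lagged_precip_features(
    precip: np.ndarray,
    anchor_month: np.ndarray | int,
    n_years: int,
    lead_months: int = 24,
    years: list[int] | None = None,
) -> PrecipFeatures:
    """Antecedent 6- and 24-month precipitation sums per analysis year.

    ``precip`` is (n_cells, n_months) monthly precipitation beginning
    ``lead_months`` before the first analysis year.  ``anchor_month``
    (0-based calendar month, scalar or per-cell) anchors each fire year;
    the sums cover the 6 and 24 months strictly preceding it.
    """
    P = np.asarray(precip, dtype=float)
    n_cells = P.shape[0]
    anchors = np.broadcast_to(np.asarray(anchor_month, dtype=int), (n_cells,))
    first = lead_months + anchors.min()
    if first < 24:
        raise ValueError("need at least 24 months of history before the first analysis year")
    if lead_months + (n_years - 1) * 12 + anchors.max() > P.shape[1]:
        raise ValueError("precipitation record too short for the analysis span")

    csum = np.concatenate([np.zeros((n_cells, 1)), np.cumsum(P, axis=1)], axis=1)
    rows = np.arange(n_cells)[:, None]
    idx = lead_months + np.arange(n_years)[None, :] * 12 + anchors[:, None]
    p6 = csum[rows, idx] - csum[rows, idx - 6]
    p24 = csum[rows, idx] - csum[rows, idx - 24]
    yrs = years if years is not None else list(range(n_years))
    return PrecipFeatures(p6=p6, p24=p24, years=yrs)


def decoupled_trend(
    yearly: np.ndarray,
    p6: np.ndarray,
    p24: np.ndarray,
    alpha: float = 0.05,
) -> TrendResult:
    """Anthropogenic (rainfall-decoupled) trend for one cell.

    Multiple regression of annual burned area on {year index, antecedent
    6-month sum, antecedent 24-month sum}; returns the year coefficient
    and its t-test.  Constant (collinear) precipitation regressors are
    dropped with a warning, reducing to the plain OLS trend.
    """
    y = np.asarray(yearly, dtype=float)
    n = y.size
    if n < 8:
        raise ValueError("need at least 8 years")
    if not (p6.size == p24.size == n):
        raise ValueError("misaligned years between burned area and precipitation")
    if np.ptp(y) == 0:
        return TrendResult(0.0, 0.0, 1.0, 0.0, n, False, degenerate=True)

    t = np.arange(n, dtype=float)
    cols, names = [t], ["year"]
    for feat, name in ((np.asarray(p6, float), "p6"), (np.asarray(p24, float), "p24")):
        if np.ptp(feat) == 0:
            warnings.warn(f"constant precipitation feature {name} dropped")
        else:
            cols.append(feat)
            names.append(name)
    X = sm.add_constant(np.column_stack(cols))
    fit = sm.OLS(y, X).fit()
    slope, tval, pval = fit.params[1], fit.tvalues[1], fit.pvalues[1]
    start = fit.params[0]
    rel = 100.0 * slope * (n - 1) / start if start != 0 else np.nan
    return TrendResult(float(slope), float(tval), float(pval), float(rel),
                       n, bool(pval < alpha))


def pixel_decoupled_trends(
    burned_area: np.ndarray,
    features: PrecipFeatures,
    cell_mask: np.ndarray | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Rainfall-decoupled trend per cell; the t-value column is the map.

    ``burned_area`` is (n_cells, n_years, 12); cells outside the mask or
    with no fire at all get NaN statistics.
    """
    annual = burned_area.sum(axis=2)
    n_cells = annual.shape[0]
    mask = np.ones(n_cells, bool) if cell_mask is None else np.asarray(cell_mask, bool)
    rows = []
    for c in range(n_cells):
        if not mask[c] or annual[c].sum() == 0:
            rows.append({"cell_id": c, "slope": np.nan, "t_value": np.nan,
                         "p_value": np.nan, "significant": False})
            continue
        r = decoupled_trend(annual[c], features.p6[c], features.p24[c], alpha=alpha)
        rows.append({"cell_id": c, "slope": r.slope, "t_value": r.t_value,
                     "p_value": r.p_value, "significant": r.significant})
    return pd.DataFrame(rows).set_index("cell_id")


def regime_trend_table(
    burned_area: np.ndarray,
    regime_labels: np.ndarray,
    region_label: np.ndarray,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Regime-wide OLS trend for every regime x region stratum."""
    regimes = sorted(set(np.asarray(regime_labels)[np.asarray(regime_labels) > 0]))
    rows = []
    for regime in regimes:
        for region in ("focal", "continental", "other"):
            mask = (regime_labels == regime) & (region_label == region)
            if not mask.any():
                continue
            r = ols_trend(regime_annual_series(burned_area, mask), alpha=alpha)
            rows.append({"regime": int(regime), "region": region, "slope": r.slope,
                         "t": r.t_value, "p": r.p_value,
                         "relative_change_pct": r.relative_change_pct,
                         "n_years": r.n_years, "significant": r.significant})
    return pd.DataFrame(rows)
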
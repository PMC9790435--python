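"""Vegetation classification from NDVI and tree-loss anomaly summaries.

Vegetation classes are read off three normalised NDVI statistics —
mean, annual (year-to-year) CV, and monthly (seasonal) CV, each
expressed relative to the domain-wide maximum mean NDVI:

* forest: normalised mean > 0.80 and annual CV < 0.08 (high, stable
  canopy);
* grassy: 0.06 <= normalised mean < 0.80 and monthly CV > 0.08 (open,
  seasonally variable canopy; the 6% floor excludes barren surfaces);
* other: everything else.

Degradation is indexed by the tree-loss fraction (summed loss over
summed baseline cover) of a stratum relative to the all-tropics value;
a ratio above 1 marks anomalously high loss.  Population density ratios
are computed the same way from area-weighted stratum means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .characteristics import coefficient_of_variation

FOREST_MEAN_MIN = 0.80
FOREST_ANNUAL_CV_MAX = 0.08
GRASSY_MEAN_MIN = 0.06
GRASSY_MONTHLY_CV_MIN = 0.08


def smooth_ndvi(series: np.ndarray, window: int = 5) -> np.ndarray:
    """Centred rolling-median smoothing of a per-scene NDVI series.

    NaNs are ignored within each window (a window of all NaNs stays
    NaN); a window of 1 is the identity.  Used to knock single-scene
    noise spikes out of dense NDVI records before computing statistics.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    s = pd.Series(np.asarray(series, dtype=float))
    if s.isna().all():
        raise ValueError("all-missing series")
    if window == 1:
        return s.to_numpy()
    return s.rolling(window, center=True, min_periods=1).median().to_numpy()


@dataclass
class VegetationProfile:
    """Normalised NDVI statistics per cell plus the derived class."""

    mean_norm: np.ndarray
    annual_cv: np.ndarray
    monthly_cv: np.ndarray
    veg_class: np.ndarray


def ndvi_statistics(ndvi: np.ndarray) -> pd.DataFrame:
    """Mean, annual CV and monthly (climatology) CV of a (cells, years, 12) record."""
    arr = np.asarray(ndvi, dtype=float)
    yearly = arr.mean(axis=2)                       # (cells, years)
    clim = arr.mean(axis=1)                         # (cells, 12)
    return pd.DataFrame({
        "ndvi_mean": yearly.mean(axis=1),
        "ndvi_annual_cv": [coefficient_of_variation(y) for y in yearly],
        "ndvi_monthly_cv": [coefficient_of_variation(c) for c in clim],
    })


def classify_vegetation(
    mean_ndvi: np.ndarray,
    annual_cv: np.ndarray,
    monthly_cv: np.ndarray,
    normalise: bool = True,
) -> VegetationProfile:
    """Partition cells into forest / grassy / other from NDVI statistics.

    ``normalise=True`` divides mean NDVI by its domain-wide maximum so
    the thresholds act on [0, 1] values; pass ``False`` if the inputs
    are already normalised.  The rules are exhaustive and mutually
    exclusive: forest is checked first, then grassy, else other.
    """
    m = np.asarray(mean_ndvi, dtype=float)
    acv = np.asarray(annual_cv, dtype=float)
    mcv = np.asarray(monthly_cv, dtype=float)
    mn = m / m.max() if normalise and m.max() > 0 else m

    forest = (mn > FOREST_MEAN_MIN) & (acv < FOREST_ANNUAL_CV_MAX)
    grassy = (~forest & (mn >= GRASSY_MEAN_MIN) & (mn < FOREST_MEAN_MIN)
              & (mcv > GRASSY_MONTHLY_CV_MIN))
    cls = np.where(forest, "forest", np.where(grassy, "grassy", "other"))
    return VegetationProfile(mean_norm=mn, annual_cv=acv, monthly_cv=mcv,
                             veg_class=cls.astype(object))


def tree_loss_fraction(tree_loss: np.ndarray, tree_cover: np.ndarray,
                       mask: np.ndarray | None = None) -> float:
    """Summed tree loss over summed baseline cover for a cell set.

    Returns NaN (undefined, reported as missing) when the set has zero
    baseline cover.
    """
    loss = np.asarray(tree_loss, dtype=float)
    cover = np.asarray(tree_cover, dtype=float)
    if mask is not None:
        m = np.asarray(mask, dtype=bool)
        loss, cover = loss[m], cover[m]
    denom = cover.sum()
    if denom <= 0:
        return float("nan")
    return float(loss.sum() / denom)


def anomaly_ratio(subset_value: float, baseline_value: float) -> float:
    """Subset statistic over the all-tropics baseline; > 1 is anomalous."""
    if not baseline_value > 0:
        raise ValueError("baseline must be positive")
    return float(subset_value / baseline_value)


def summarize_degradation(
    regime_labels: np.ndarray,
    region_label: np.ndarray,
    veg_class: np.ndarray,
    tree_cover: np.ndarray,
    tree_loss: np.ndarray,
    population: np.ndarray,
    cell_area: float = 1.0,
) -> pd.DataFrame:
    """Tree-loss and population summary per regime x region x class.

    One row per (regime in {0..K}, region in {focal, continental, other,
    all}, vegetation class in {forest, grassy, all}); empty strata are
    kept as missing rows.  Ratios are computed against the all-tropics,
    all-regime, all-class baseline, which therefore has ratio exactly 1.
    Population means are area-weighted; with a uniform lattice that is
    the plain mean.
    """
    labels = np.asarray(regime_labels, dtype=int)
    region = np.asarray(region_label, dtype=object)
    veg = np.asarray(veg_class, dtype=object)
    cover = np.asarray(tree_cover, dtype=float)
    loss = np.asarray(tree_loss, dtype=float)
    pop = np.asarray(population, dtype=float)

    base_loss = tree_loss_fraction(loss, cover)
    base_pop = float(pop.mean())

    regimes = sorted(set(labels[labels >= 0]))
    rows = []
    for regime in [None] + list(regimes):
        for reg in ("all", "focal", "continental", "other"):
            for cls in ("all", "forest", "grassy"):
                m = np.ones(labels.size, dtype=bool)
                if regime is not None:
                    m &= labels == regime
                if reg != "all":
                    m &= region == reg
                if cls != "all":
                    m &= veg == cls
                row = {"regime": -999 if regime is None else regime,
                       "region": reg, "veg_class": cls, "n_cells": int(m.sum())}
                if m.any():
                    lf = tree_loss_fraction(loss, cover, m)
                    row.update({
                        "tree_cover_fraction": float(cover[m].mean()),
                        "tree_loss_fraction": lf,
                        "tree_loss_anomaly": lf / base_loss if np.isfinite(lf) else np.nan,
                        "population_mean": float(pop[m].mean()),
                        "population_ratio": float(pop[m].mean() / base_pop),
                    })
                else:
                    row.update({k: np.nan for k in (
                        "tree_cover_fraction", "tree_loss_fraction",
                        "tree_loss_anomaly", "population_mean", "population_ratio")})
                rows.append(row)
    df = pd.DataFrame(rows)
    df["regime"] = df["regime"].replace(-999, "all")
    df["anomalous"] = df["tree_loss_anomaly"] > 1
    return df
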
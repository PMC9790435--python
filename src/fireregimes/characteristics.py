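"""Per-cell fire characteristics from a gridded monthly fire record.

Each cell of a multi-year monthly record of burned area, fire count and
mean fire size is summarised by 12 characteristics — monthly and yearly
mean and coefficient of variation (CV) of each of the three fields —
plus the average fire-season length (months burned per year).  Monthly
statistics are taken over the 12-value climatological cycle and so
measure seasonality; yearly statistics are taken over per-year annual
aggregates and measure interannual variability.  Cells with zero burned
area over the whole span are flagged NLSF ("no landscape-scale fire")
and excluded from clustering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Column order of the 12-characteristic table used for clustering,
#: similarity surfaces and the fire PCA.
CHARACTERISTIC_COLUMNS = [
    "ba_month_mean", "ba_year_mean", "ba_month_cv", "ba_year_cv",
    "nfire_month_mean", "nfire_year_mean", "nfire_month_cv", "nfire_year_cv",
    "fsize_month_mean", "fsize_year_mean", "fsize_month_cv", "fsize_year_cv",
]


@dataclass
class GriddedFireSeries:
    """Monthly burned area, fire count and mean fire size per cell.

    Arrays are shaped ``(n_cells, n_years, 12)``.  ``mean_fire_size`` is
    zero exactly where ``fire_count`` is zero.
    """

    burned_area: np.ndarray
    fire_count: np.ndarray
    mean_fire_size: np.ndarray
    years: list[int]
    cell_area: float

    def __post_init__(self) -> None:
        ba = np.asarray(self.burned_area, dtype=float)
        nf = np.asarray(self.fire_count)
        fs = np.asarray(self.mean_fire_size, dtype=float)
        if not (ba.shape == nf.shape == fs.shape):
            raise ValueError("field shapes differ")
        if ba.ndim != 3 or ba.shape[2] != 12:
            raise ValueError(f"expected (n_cells, n_years, 12), got {ba.shape}")
        if ba.shape[1] != len(self.years):
            raise ValueError("years list does not match array shape")
        if (ba < 0).any() or (nf < 0).any():
            raise ValueError("negative burned area or fire count")
        if ba.max(initial=0.0) > self.cell_area * (1 + 1e-9):
            raise ValueError("burned area exceeds cell area")
        zero_count = nf == 0
        if not np.allclose(fs[zero_count], 0.0):
            raise ValueError("mean_fire_size must be 0 where fire_count is 0")
        self.burned_area, self.fire_count, self.mean_fire_size = ba, nf, fs

    @property
    def n_cells(self) -> int:
        return self.burned_area.shape[0]

    @property
    def n_years(self) -> int:
        return self.burned_area.shape[1]


def coefficient_of_variation(values) -> float:
    """Sample (ddof=1) standard deviation divided by the mean.

    A zero mean (which on this pipeline only happens for all-zero series)
    returns 0 by convention, keeping NLSF-adjacent cells finite.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty value list")
    m = v.mean()
    if m == 0:
        return 0.0
    sd = v.std(ddof=1) if v.size > 1 else 0.0
    return float(sd / m)


def monthly_climatology(series: np.ndarray) -> np.ndarray:
    """Mean over years of each calendar month; input ``(n_years, 12)``."""
    s = np.asarray(series, dtype=float)
    if s.ndim != 2 or s.shape[1] != 12:
        raise ValueError("series must be (n_years, 12) — complete years only")
    if s.shape[0] < 1:
        raise ValueError("need at least one complete year")
    return s.mean(axis=0)


def _mean_cv(values: np.ndarray) -> tuple[float, float]:
    return float(np.mean(values)), coefficient_of_variation(values)


def compute_fire_characteristics(ba: np.ndarray, nfire: np.ndarray, fsize: np.ndarray) -> dict:
    """Characterise one cell; inputs are ``(n_years, 12)`` monthly fields.

    Annual aggregates are: burned area and fire count summed over months;
    annual mean fire size = annual burned area / annual fire count (0 for
    fire-free years).  Season length is the mean over years of the number
    of months with any burned area.
    """
    ba = np.asarray(ba, dtype=float)
    nfire = np.asarray(nfire, dtype=float)
    fsize = np.asarray(fsize, dtype=float)

    ba_clim = monthly_climatology(ba)
    nf_clim = monthly_climatology(nfire)
    fs_clim = monthly_climatology(fsize)

    ba_year = ba.sum(axis=1)
    nf_year = nfire.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        fs_year = np.where(nf_year > 0, ba_year / np.maximum(nf_year, 1e-300), 0.0)

    out = {}
    out["ba_month_mean"], out["ba_month_cv"] = _mean_cv(ba_clim)
    out["ba_year_mean"], out["ba_year_cv"] = _mean_cv(ba_year)
    out["nfire_month_mean"], out["nfire_month_cv"] = _mean_cv(nf_clim)
    out["nfire_year_mean"], out["nfire_year_cv"] = _mean_cv(nf_year)
    out["fsize_month_mean"], out["fsize_month_cv"] = _mean_cv(fs_clim)
    out["fsize_year_mean"], out["fsize_year_cv"] = _mean_cv(fs_year)
    out["season_length"] = float((ba > 0).sum(axis=1).mean())
    out["is_nlsf"] = bool(ba.sum() == 0)
    return out


def characteristics_table(series: GriddedFireSeries) -> pd.DataFrame:
    """The full characteristics table, one row per cell.

    Columns are :data:`CHARACTERISTIC_COLUMNS` plus ``season_length`` and
    ``is_nlsf``.
    """
    rows = [
        compute_fire_characteristics(
            series.burned_area[i], series.fire_count[i], series.mean_fire_size[i]
        )
        for i in range(series.n_cells)
    ]
    df = pd.DataFrame(rows)
    df.index.name = "cell_id"
    return df[CHARACTERISTIC_COLUMNS + ["season_length", "is_nlsf"]]


@dataclass
class NormalisationParams:
    """Per-column min/max fitted on a reference domain.

    Projection data must be transformed with the *reference* parameters so
    similarity scores are comparable; values outside the reference range
    map outside [0, 1] and are deliberately not clipped.
    """

    col_min: pd.Series
    col_max: pd.Series
    constant_cols: list[str] = field(default_factory=list)

    def transform(self, table: pd.DataFrame) -> pd.DataFrame:
        out = table[self.col_min.index].copy().astype(float)
        span = self.col_max - self.col_min
        for c in out.columns:
            if c in self.constant_cols:
                out[c] = 0.0
            else:
                out[c] = (out[c] - self.col_min[c]) / span[c]
        return out


def normalise_characteristics(
    table: pd.DataFrame,
    domain: np.ndarray | None = None,
    columns: list[str] | None = None,
) -> tuple[pd.DataFrame, NormalisationParams]:
    """Min-max scale each characteristic to [0, 1] over a reference domain.

    Parameters
    ----------
    table : DataFrame
        Characteristics, one row per cell.
    domain : boolean array, optional
        Reference cells (typically burned cells of the focal region); the
        scaling min/max are fitted there.  Defaults to all rows.
    columns : list of str, optional
        Columns to scale; defaults to the 12 clustering characteristics.

    Returns the transformed full table and the fitted parameters.  A column
    constant over the domain has no defined scale and is set to 0 with a
    warning.
    """
    cols = columns if columns is not None else CHARACTERISTIC_COLUMNS
    dom = np.ones(len(table), dtype=bool) if domain is None else np.asarray(domain, dtype=bool)
    if not dom.any():
        raise ValueError("empty normalisation domain")
    ref = table.loc[dom, cols]
    cmin, cmax = ref.min(), ref.max()
    constant = [c for c in cols if cmax[c] == cmin[c]]
    if constant:
        warnings.warn(f"constant characteristic(s) over domain set to 0: {constant}")
    params = NormalisationParams(cmin, cmax, constant)
    return params.transform(table), params
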
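"""Synthetic tropics with planted fire regimes and a truth record.

This module generates a small three-region "tropics" (a focal island,
a continental region, and the remaining tropics) whose every parameter is
known, so the analysis pipeline can be tested by parameter recovery:
planted regime labels, planted anthropogenic burned-area trends, planted
tree-loss anomaly ratios, and planted vegetation classes.

Fire is generated at *event* level: each cell-month receives individual
fire events (sizes drawn around the archetype's mean fire size), events
below the 0.21 km^2 landscape-scale detection floor are dropped, and the
monthly burned area / fire count / mean fire size fields are aggregated
from the surviving events.  Burned area therefore equals fire count times
mean fire size exactly, and the detection floor acts where it does in the
source data: on individual fires.

Burned area responds linearly to antecedent 6- and 24-month precipitation
anomalies, so the trend-decoupling regression is correctly specified on
these data; a multiplicative mis-specified variant is available for
robustness experiments.  All randomness flows from one seeded generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .characteristics import GriddedFireSeries
from .grid import GridSpec, REGIONS

#: Landscape-scale detection floor: individual fires below this size (km^2)
#: are invisible to the 500-m burned-area product being emulated (~21 ha).
EVENT_FLOOR_KM2 = 0.21

VEG_CLASSES = ("forest", "grassy")


@dataclass(frozen=True)
class RegimeArchetype:
    """Generative description of one planted fire regime.

    Parameters
    ----------
    label : int
        Regime label (1..K); 0 is reserved for NLSF.
    climatology : array of 12 floats
        Expected burned area (km^2) per calendar month in an average year.
    cv_year : float
        Target year-to-year coefficient of variation of annual burned area
        (lognormal multiplier on whole years).
    mean_fire_size : float
        Mean individual fire size (km^2); must exceed the detection floor
        for the regime to register as burned.
    fire_size_cv : float
        Within-month dispersion of individual fire sizes.
    beta6, beta24 : float
        Linear response of annual burned area (km^2) to the antecedent
        6- and 24-month precipitation anomalies (per mm).
    trend : float
        Planted anthropogenic trend, fractional change per year; annual
        burned area carries a (1 + trend)^t geometric factor.
    forest_fraction : float
        Probability that a cell of this regime is planted as forest
        (vs grassy) vegetation.
    precip_mean : float
        Mean monthly precipitation (mm) for cells of this regime.
    """

    label: int
    climatology: np.ndarray
    cv_year: float = 0.3
    mean_fire_size: float = 1.0
    fire_size_cv: float = 0.5
    beta6: float = 0.0
    beta24: float = 0.0
    trend: float = 0.0
    forest_fraction: float = 0.1
    precip_mean: float = 100.0

    def __post_init__(self) -> None:
        clim = np.asarray(self.climatology, dtype=float)
        if clim.shape != (12,):
            raise ValueError("climatology must have 12 monthly values")
        if (clim < 0).any():
            raise ValueError("climatology values must be non-negative")
        if self.cv_year < 0:
            raise ValueError("cv_year must be non-negative")
        object.__setattr__(self, "climatology", clim)

    @property
    def total_burned_area(self) -> float:
        return float(self.climatology.sum())


def default_archetypes() -> list[RegimeArchetype]:
    """Five regimes spanning the low-variable -> high-stable gradient.

    Labels ascend with fire activity: 1-2 are low-fire, high-variability
    regimes (1 forest-associated, 2 forest-savanna boundary), 3-4 are
    medium-fire medium-variability grassy regimes, and 5 is the
    high-burned-area, annually stable grassy regime with the largest
    fires and the longest season.
    """
    def clim(peak: int, width: int, total: float) -> np.ndarray:
        m = np.arange(12)
        d = np.minimum(np.abs(m - peak), 12 - np.abs(m - peak))
        w = np.where(d <= width, 1.0 - d / (width + 1.0), 0.0)
        return total * w / w.sum()

    return [
        RegimeArchetype(1, clim(peak=10, width=1, total=4.0), cv_year=0.30,
                        mean_fire_size=0.6, fire_size_cv=0.3,
                        forest_fraction=0.70, precip_mean=170.0),
        RegimeArchetype(2, clim(peak=9, width=2, total=12.0), cv_year=0.22,
                        mean_fire_size=2.4, fire_size_cv=0.3,
                        forest_fraction=0.45, precip_mean=140.0),
        RegimeArchetype(3, clim(peak=8, width=3, total=36.0), cv_year=0.15,
                        mean_fire_size=1.2, fire_size_cv=0.3,
                        forest_fraction=0.10, precip_mean=110.0),
        RegimeArchetype(4, clim(peak=7, width=4, total=108.0), cv_year=0.10,
                        mean_fire_size=4.8, fire_size_cv=0.3,
                        forest_fraction=0.05, precip_mean=95.0),
        RegimeArchetype(5, clim(peak=6, width=5, total=216.0), cv_year=0.05,
                        mean_fire_size=9.0, fire_size_cv=0.3,
                        forest_fraction=0.02, precip_mean=80.0),
    ]


@dataclass
class TruthRecord:
    """Planted ground truth so any synthetic dataset is exactly auditable."""

    regime_label: np.ndarray          # (n_cells,) int; 0 = NLSF
    trend: np.ndarray                 # (n_cells,) planted fraction/year
    veg_class: np.ndarray             # (n_cells,) str in VEG_CLASSES
    anomaly: dict[tuple[int, str], float]  # (regime, veg class) -> planted tree-loss ratio
    seed: int
    archetypes: list[RegimeArchetype] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "cell_id": np.arange(self.regime_label.size),
            "regime_label": self.regime_label,
            "trend": self.trend,
            "veg_class": self.veg_class,
        })


@dataclass
class EnvironmentBundle:
    """Environmental fields accompanying a synthetic fire archive.

    ``ndvi`` is (n_cells, n_years, 12); ``precip`` is
    (n_cells, n_months_total) monthly and starts ``lead_months`` before
    the first fire year so 24-month antecedent windows are defined.
    """

    ndvi: np.ndarray
    precip: np.ndarray
    lead_months: int
    climate: pd.DataFrame             # temp_mean, temp_cv, precip_annual, precip_cv
    population: np.ndarray
    tree_cover: np.ndarray
    tree_loss: np.ndarray


def _lognormal_multipliers(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Unit-mean lognormal draws with the requested coefficient of variation."""
    if cv <= 0:
        return np.ones(size)
    sigma2 = np.log1p(cv ** 2)
    return rng.lognormal(mean=-sigma2 / 2, sigma=np.sqrt(sigma2), size=size)


def generate_precipitation(
    grid: GridSpec,
    regime_label: np.ndarray,
    archetypes: list[RegimeArchetype],
    n_months: int,
    seed: int,
    seasonal_amplitude: float = 0.6,
    interannual_cv: float = 0.15,
    peak_month: int = 1,
) -> np.ndarray:
    """Monthly precipitation (mm), seasonal cycle plus interannual noise.

    Deterministic in (inputs, seed); the fire generator and the
    environment generator call this with the same seed so the planted
    fire-rainfall coupling is consistent across the bundle.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 7001]))
    by_label = {a.label: a for a in archetypes}
    base = np.array([by_label[r].precip_mean if r in by_label else 120.0
                     for r in regime_label])
    base = base * rng.normal(1.0, 0.08, size=grid.n_cells).clip(0.5)
    months = np.arange(n_months)
    cycle = 1.0 + seasonal_amplitude * np.cos(2 * np.pi * (months - peak_month) / 12.0)
    n_years = int(np.ceil(n_months / 12))
    yr_mult = _lognormal_multipliers(rng, interannual_cv, (grid.n_cells, n_years))
    yr_full = np.repeat(yr_mult, 12, axis=1)[:, :n_months]
    return np.maximum(base[:, None] * cycle[None, :] * yr_full, 0.0)


def _antecedent_sums(precip: np.ndarray, anchor_idx: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """6- and 24-month sums strictly preceding each anchor month index."""
    csum = np.concatenate([np.zeros((precip.shape[0], 1)), np.cumsum(precip, axis=1)], axis=1)
    rows = np.arange(precip.shape[0])[:, None]
    p6 = csum[rows, anchor_idx] - csum[rows, anchor_idx - 6]
    p24 = csum[rows, anchor_idx] - csum[rows, anchor_idx - 24]
    return p6, p24


def generate_fire_archive(
    grid: GridSpec,
    archetypes: list[RegimeArchetype] | None = None,
    years: int = 14,
    nlsf_fraction: float = 0.25,
    seed: int = 0,
    region_weights: dict[str, np.ndarray] | None = None,
    noise: bool = True,
    event_floor: float = EVENT_FLOOR_KM2,
    multiplicative_coupling: bool = False,
    shared_interannual: bool = True,
    start_year: int = 2003,
) -> tuple[GriddedFireSeries, TruthRecord]:
    """Generate the gridded monthly fire record plus its truth record.

    Parameters
    ----------
    grid : GridSpec
        Lattice with region labels.
    archetypes : list of RegimeArchetype, optional
        Planted regimes; defaults to :func:`default_archetypes`.
    years : int
        Number of fire years (>= 3).
    nlsf_fraction : float in [0, 1)
        Fraction of cells planted with no landscape-scale fire.
    seed : int
        Root seed; identical inputs and seed give bit-identical output.
    region_weights : dict, optional
        Per-region sampling weights over the archetype list, e.g. to make
        a regime absent from the focal region.  Keys are region names,
        values length-K weight arrays.
    noise : bool
        If False, year-to-year multipliers, precipitation coupling and
        fire-size dispersion are all switched off (exact climatologies).
    multiplicative_coupling : bool
        Mis-specified variant where precipitation scales burned area
        multiplicatively instead of adding linearly (robustness tests).
    shared_interannual : bool
        If True (default), year-to-year multipliers are drawn per
        regime-year and shared across the regime's cells (climate-
        synchronised fire years) with small cell-level jitter; if False,
        every cell draws its own independent multipliers at the full
        target CV, which is the right configuration for pixel-wise
        trend statistics that assume independent cells.
    """
    if archetypes is None:
        archetypes = default_archetypes()
    if not archetypes:
        raise ValueError("need at least one archetype")
    labels = [a.label for a in archetypes]
    if len(set(labels)) != len(labels):
        raise ValueError("archetype labels must be distinct")
    if years < 3:
        raise ValueError("years must be >= 3")
    if not (0 <= nlsf_fraction < 1):
        raise ValueError("nlsf_fraction must be in [0, 1)")

    ss = np.random.SeedSequence([seed, 1001])
    rng = np.random.default_rng(ss)
    n = grid.n_cells

    # --- plant regimes ------------------------------------------------
    regime_label = np.zeros(n, dtype=int)
    is_nlsf = rng.random(n) < nlsf_fraction
    for region in REGIONS:
        mask = grid.region_mask(region) & ~is_nlsf
        w = None
        if region_weights is not None and region in region_weights:
            w = np.asarray(region_weights[region], dtype=float)
            w = w / w.sum()
        idx = rng.choice(len(archetypes), size=mask.sum(), p=w)
        regime_label[mask] = np.asarray(labels)[idx]

    by_label = {a.label: a for a in archetypes}
    trend = np.array([by_label[r].trend if r else 0.0 for r in regime_label])
    veg_class = np.empty(n, dtype=object)
    for c in range(n):
        ff = by_label[regime_label[c]].forest_fraction if regime_label[c] else 0.5
        veg_class[c] = "forest" if rng.random() < ff else "grassy"

    truth = TruthRecord(regime_label=regime_label, trend=trend,
                        veg_class=veg_class, anomaly={}, seed=seed,
                        archetypes=list(archetypes))

    # --- precipitation with a 24-month lead ---------------------------
    lead = 24
    precip = generate_precipitation(grid, regime_label, archetypes,
                                    n_months=lead + years * 12, seed=seed)

    ba = np.zeros((n, years, 12))
    nf = np.zeros((n, years, 12), dtype=int)
    fs = np.zeros((n, years, 12))
    events: list[tuple[int, int, int, float]] = []

    # Interannual variability is regionally coherent (climate-synchronised
    # fire years), so the year multipliers are drawn once per regime-year
    # and shared by all cells of the regime; cells add a small idiosyncratic
    # jitter on top.
    regime_year_mult = {
        a.label: _lognormal_multipliers(
            rng, a.cv_year if (noise and shared_interannual) else 0.0, years)
        for a in archetypes
    }
    # jitter is expressed as a fraction of each archetype's cv_year
    cell_jitter_cv = 0.0 if not noise else (0.2 if shared_interannual else 1.0)

    t_idx = np.arange(years)
    for c in range(n):
        r = regime_label[c]
        if r == 0:
            continue
        a = by_label[r]
        clim = a.climatology
        total = clim.sum()
        if total == 0:
            continue
        # anchor each fire year at its climatological peak month
        peak = int(np.argmax(clim))
        anchors = lead + t_idx * 12 + peak
        p6, p24 = _antecedent_sums(precip[c:c + 1], anchors[None, :])
        p6, p24 = p6[0], p24[0]

        yr_mult = regime_year_mult[r] * _lognormal_multipliers(
            rng, a.cv_year * cell_jitter_cv, years)
        annual = total * yr_mult * (1.0 + a.trend) ** t_idx
        if noise:
            if multiplicative_coupling:
                annual = annual * (1.0 + a.beta6 * (p6 - p6.mean()) / max(total, 1e-12)) \
                                * (1.0 + a.beta24 * (p24 - p24.mean()) / max(total, 1e-12))
            else:
                annual = annual + a.beta6 * (p6 - p6.mean()) + a.beta24 * (p24 - p24.mean())
        annual = np.clip(annual, 0.0, 12 * grid.cell_area)

        shape = clim / total
        target = annual[:, None] * shape[None, :]          # (years, 12)
        for y in range(years):
            for m in range(12):
                tgt = target[y, m]
                if tgt <= 0:
                    continue
                # stochastic rounding keeps E[count] proportional to the
                # target without rounding-cliff artifacts in the count CVs
                x = tgt / a.mean_fire_size
                n_ev = int(x) + (1 if rng.random() < (x - int(x)) else 0)
                n_ev = max(1, n_ev)
                sizes = (a.mean_fire_size *
                         _lognormal_multipliers(rng, a.fire_size_cv if noise else 0.0, n_ev))
                sizes = sizes * (tgt / sizes.sum())        # exact monthly total
                sizes = sizes[sizes >= event_floor]        # detection floor
                if sizes.size == 0:
                    continue
                if sizes.sum() > grid.cell_area:
                    sizes = sizes * (grid.cell_area / sizes.sum())
                ba[c, y, m] = sizes.sum()
                nf[c, y, m] = sizes.size
                fs[c, y, m] = sizes.mean()
                events.extend((c, start_year + y, m + 1, s) for s in sizes)

    series = GriddedFireSeries(
        burned_area=ba, fire_count=nf, mean_fire_size=fs,
        years=[start_year + y for y in range(years)], cell_area=grid.cell_area,
    )
    series.events = pd.DataFrame(events, columns=["cell_id", "year", "month", "size_km2"])
    return series, truth


def generate_environment(
    grid: GridSpec,
    truth: TruthRecord,
    seed: int | None = None,
    n_years: int = 14,
    anomaly: dict[tuple[int, str], float] | None = None,
    base_loss_rate: float = 0.05,
) -> EnvironmentBundle:
    """Generate NDVI, climate, precipitation, population and tree fields.

    Forest cells receive a high-mean, low-variability NDVI cycle and
    grassy cells a lower-mean, strongly seasonal one, so the NDVI
    thresholds recover the planted classes.  Tree-loss rates are set so
    the cover-weighted all-domain mean anomaly is exactly 1; a stratum
    planted with anomaly ``r`` then has, in expectation, ``r`` times the
    all-domain loss fraction — the quantity the degradation summary
    estimates.

    ``anomaly`` maps (regime label, vegetation class) to the planted
    tree-loss anomaly ratio; missing strata default to 1.  It is recorded
    on the returned truth record.
    """
    if truth.regime_label.size != grid.n_cells:
        raise ValueError("truth record does not match grid")
    if seed is None:
        seed = truth.seed
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2001]))
    n = grid.n_cells
    anomaly = dict(anomaly or {})
    truth.anomaly = anomaly

    # --- NDVI ----------------------------------------------------------
    months = np.arange(12)
    forest = truth.veg_class == "forest"
    ndvi = np.empty((n, n_years, 12))
    mean_f = rng.normal(0.88, 0.015, n).clip(0.75, 0.98)
    mean_g = rng.normal(0.45, 0.05, n).clip(0.15, 0.65)
    cell_mean = np.where(forest, mean_f, mean_g)
    seas_amp = np.where(forest, 0.02, 0.30)
    cycle = np.cos(2 * np.pi * (months - 2) / 12.0)
    yr_cv = np.where(forest, 0.02, 0.10)
    for c in range(n):
        ymult = _lognormal_multipliers(rng, yr_cv[c], n_years)
        ndvi[c] = (cell_mean[c] * ymult[:, None]
                   * (1.0 + seas_amp[c] * cycle[None, :]))
    ndvi = ndvi.clip(0.0, 1.0)

    # --- precipitation (same seed path as the fire generator) ----------
    precip = generate_precipitation(grid, truth.regime_label, truth.archetypes,
                                    n_months=24 + n_years * 12, seed=seed)

    # --- climate summaries ---------------------------------------------
    annual_precip = precip[:, 24:].reshape(n, n_years, 12).sum(axis=2).mean(axis=1)
    pm = precip[:, 24:24 + 12]
    precip_cv = pm.std(axis=1, ddof=1) / np.maximum(pm.mean(axis=1), 1e-9)
    temp_mean = rng.normal(24.0, 1.5, n) - 0.004 * (annual_precip - annual_precip.mean())
    temp_cv = rng.normal(0.12, 0.02, n).clip(0.02)
    climate = pd.DataFrame({
        "temp_mean": temp_mean, "temp_cv": temp_cv,
        "precip_annual": annual_precip, "precip_cv": precip_cv,
    })

    # --- population -----------------------------------------------------
    pop_base = np.where(forest, 60.0, 25.0)
    population = pop_base * _lognormal_multipliers(rng, 0.8, n)

    # --- tree cover and loss -------------------------------------------
    tree_cover = np.where(forest,
                          rng.normal(0.70, 0.08, n),
                          rng.normal(0.15, 0.05, n)).clip(0.01, 1.0)
    planted = np.array([anomaly.get((int(r), v), 1.0)
                        for r, v in zip(truth.regime_label, truth.veg_class)])
    # normalise so the cover-weighted mean anomaly is exactly 1
    planted = planted / (np.sum(planted * tree_cover) / np.sum(tree_cover))
    loss_rate = base_loss_rate * planted * _lognormal_multipliers(rng, 0.3, n)
    tree_loss = np.minimum(loss_rate * tree_cover, tree_cover)

    return EnvironmentBundle(ndvi=ndvi, precip=precip, lead_months=24,
                             climate=climate, population=population,
                             tree_cover=tree_cover, tree_loss=tree_loss)
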
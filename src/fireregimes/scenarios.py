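"""Canonical synthetic experiments with planted, recoverable truth.

Each scenario fixes the generative conditions of one recovery question —
regime-label recovery by clustering, tropical projection coverage,
rainfall-decoupled trend inference, tree-loss anomaly recovery — and
returns both the generated data and the planted values, so the analysis
answer can be scored against truth.  The scenarios are used by the test
suite and by the reproduction script; their parameters are part of the
experimental design and are documented in the methods note.
"""

from __future__ import annotations

import numpy as np
from sklearn.metrics import adjusted_rand_score

from .characteristics import (CHARACTERISTIC_COLUMNS, characteristics_table,
                              normalise_characteristics)
from .clustering import assign_nlsf, complete_linkage_cluster
from .degradation import summarize_degradation
from .grid import make_grid
from .mess import classify_tropics, mess_surface, similarity_coverage
from .synthetic import (RegimeArchetype, default_archetypes,
                        generate_environment, generate_fire_archive)
from .trends import lagged_precip_features, pixel_decoupled_trends


def clustering_recovery(seed: int = 1, n_rows: int = 20, n_cols: int = 20,
                        years: int = 14) -> dict:
    """Cluster ~300 burned cells from the five default archetypes.

    Returns the adjusted Rand index of the recovered regime labels
    against the planted ones, plus the intermediate objects.
    """
    grid = make_grid(n_rows, n_cols)
    series, truth = generate_fire_archive(grid, years=years,
                                          nlsf_fraction=0.25, seed=seed)
    chars = characteristics_table(series)
    nlsf = assign_nlsf(chars["ba_year_mean"].to_numpy())
    normed, _ = normalise_characteristics(chars, domain=~nlsf)
    regime_map, Z = complete_linkage_cluster(
        normed[CHARACTERISTIC_COLUMNS], K=5, nlsf_mask=nlsf,
        ba_year_mean=chars["ba_year_mean"].to_numpy())
    ari = adjusted_rand_score(truth.regime_label[~nlsf],
                              regime_map.labels[~nlsf])
    return {"ari": float(ari), "n_cells": int((~nlsf).sum()),
            "labels": regime_map.labels, "truth": truth, "linkage": Z,
            "characteristics": chars, "normalised": normed, "nlsf": nlsf}


def absent_archetype(label: int = 6) -> RegimeArchetype:
    """A fire regime deliberately outside the focal archetypes' envelope.

    Very high, stable burned area with very large fires — the kind of
    high-rainfall savanna regime the focal island does not host — so its
    cells land outside every focal reference range on the mean burned
    area and fire size characteristics.
    """
    m = np.arange(12)
    d = np.minimum(np.abs(m - 6), 12 - np.abs(m - 6))
    w = np.where(d <= 5, 1.0 - d / 6.0, 0.0)
    return RegimeArchetype(label, 432.0 * w / w.sum(), cv_year=0.05,
                           mean_fire_size=27.0, fire_size_cv=0.3,
                           forest_fraction=0.05, precip_mean=150.0)


def _absent_weight(archetypes, absent, focal_frac: float, share: float) -> float:
    """Weight for the absent archetype in non-focal regions so that the
    expected fraction of total burned area it contributes equals ``share``."""
    tbar = np.mean([a.total_burned_area for a in archetypes])
    t6 = absent.total_burned_area
    q = 1.0 - focal_frac
    # share = q w t6 / (tbar (1 - q w) + q w t6), solved for w
    return float(share * tbar / (q * (t6 * (1 - share) + share * tbar)))


def coverage_recovery(seed: int = 1, n_rows: int = 160, n_cols: int = 160,
                      years: int = 14, absent_share: float = 0.10) -> dict:
    """Project focal regimes tropics-wide with one archetype absent at home.

    The non-focal regions carry an extra archetype contributing (in
    expectation) ``absent_share`` of total burned area; those cells have
    no focal analogue, so ideal similarity coverage is ``1 - absent_share``.
    Also reports the exclusivity-mask purity: the fraction of exclusively
    similar non-focal cells whose assigned regime matches the planted one.
    """
    focal_frac = 0.45
    grid = make_grid(n_rows, n_cols,
                     fractions=(focal_frac, (1 - focal_frac) / 2, (1 - focal_frac) / 2))
    archetypes = default_archetypes()
    absent = absent_archetype()
    all_arch = archetypes + [absent]
    w6 = _absent_weight(archetypes, absent, focal_frac, absent_share)
    w_rest = (1.0 - w6) / len(archetypes)
    weights = np.array([w_rest] * len(archetypes) + [w6])
    region_weights = {
        "focal": np.array([1.0] * len(archetypes) + [0.0]),
        "continental": weights,
        "other": weights,
    }
    series, truth = generate_fire_archive(
        grid, all_arch, years=years, nlsf_fraction=0.25, seed=seed,
        region_weights=region_weights)

    chars = characteristics_table(series)
    nlsf = assign_nlsf(chars["ba_year_mean"].to_numpy())
    focal = grid.region_mask("focal")
    normed, _ = normalise_characteristics(chars, domain=focal & ~nlsf)
    regime_map, _ = complete_linkage_cluster(
        normed.loc[focal, CHARACTERISTIC_COLUMNS], K=5, nlsf_mask=nlsf[focal],
        ba_year_mean=chars.loc[focal, "ba_year_mean"].to_numpy())
    surface = mess_surface(normed.loc[focal, CHARACTERISTIC_COLUMNS].to_numpy(),
                           regime_map.labels,
                           normed[CHARACTERISTIC_COLUMNS].to_numpy())
    tropics, exclusive = classify_tropics(surface, nlsf)
    labels = tropics.labels.copy()
    labels[focal] = regime_map.labels
    coverage = similarity_coverage(labels, chars["ba_year_mean"].to_numpy())

    # exclusivity purity on non-focal burned cells, judged against truth
    focal_ari = adjusted_rand_score(truth.regime_label[focal & ~nlsf],
                                    regime_map.labels[~nlsf[focal]])
    exc = exclusive & ~focal & ~nlsf & (truth.regime_label > 0) \
        & (truth.regime_label <= len(archetypes))
    purity = float((labels[exc] == truth.regime_label[exc]).mean()) if exc.any() else np.nan
    planted_share = float(
        chars.loc[truth.regime_label == absent.label, "ba_year_mean"].sum()
        / chars["ba_year_mean"].sum())
    return {"coverage": coverage["burned_area_fraction"],
            "cell_coverage": coverage["burned_cell_fraction"],
            "exclusive_purity": purity, "n_exclusive": int(exc.sum()),
            "planted_absent_share": planted_share, "focal_ari": float(focal_ari),
            "labels": labels, "truth": truth, "exclusive": exclusive}


def _trend_archetype(trend: float = 0.0, cv_year: float = 0.04) -> RegimeArchetype:
    m = np.arange(12)
    d = np.minimum(np.abs(m - 7), 12 - np.abs(m - 7))
    w = np.where(d <= 4, 1.0 - d / 5.0, 0.0)
    return RegimeArchetype(1, 108.0 * w / w.sum(), cv_year=cv_year,
                           mean_fire_size=4.8, fire_size_cv=0.3,
                           beta6=0.05, beta24=0.01, trend=trend,
                           precip_mean=100.0)


def trend_inference(seed: int = 1, n_cells: int = 500, years: int = 15,
                    planted_slope: float = 0.0, alpha: float = 0.05) -> dict:
    """Pixel-wise rainfall-decoupled trends on independent cells.

    With ``planted_slope`` 0, burned area varies only through antecedent
    precipitation and independent year noise, so the fraction of cells
    flagged as significant anthropogenic trends estimates the type-I
    error (nominal ``alpha``).  With a planted slope (km^2/yr, applied as
    the equivalent per-year fractional trend), the mean recovered year
    coefficient and the t < -2 rate measure recovery power.
    """
    side = int(np.ceil(np.sqrt(n_cells)))
    grid = make_grid(side, side, fractions=(1.0, 0.0, 0.0))
    arch = _trend_archetype(trend=planted_slope / 108.0)
    series, truth = generate_fire_archive(
        grid, [arch], years=years, nlsf_fraction=0.0, seed=seed,
        shared_interannual=False, start_year=2005)
    precip = _regenerate_precip(grid, truth, years)
    peak = series.burned_area.mean(axis=1).argmax(axis=1)
    feats = lagged_precip_features(precip, peak, years, lead_months=24)
    table = pixel_decoupled_trends(series.burned_area, feats, alpha=alpha)
    table = table.iloc[:n_cells]
    sig_rate = float(table["significant"].mean())
    return {"table": table, "significant_rate": sig_rate,
            "mean_slope": float(table["slope"].mean()),
            "t_below_minus2_rate": float((table["t_value"] < -2).mean()),
            "n_cells": int(len(table))}


def _regenerate_precip(grid, truth, years):
    from .synthetic import generate_precipitation
    return generate_precipitation(grid, truth.regime_label, truth.archetypes,
                                  n_months=24 + years * 12, seed=truth.seed)


def degradation_recovery(seed: int = 1, n_per_stratum: int = 1000) -> dict:
    """Recover planted tree-loss anomaly ratios {1, 2, 4} from the summary.

    Four equal-cover strata are planted as regimes 1-3 (anomalies 1, 2
    and 4) plus a four-times larger zero-loss background, so the
    cover-weighted mean anomaly is exactly 1 and each planted ratio is
    recoverable as the stratum's loss fraction over the all-domain
    baseline.  Fire itself is irrelevant here; the strata are vegetation
    strata keyed by planted regime labels.
    """
    n_total = 7 * n_per_stratum
    side = int(np.ceil(np.sqrt(n_total)))
    grid = make_grid(side, side, fractions=(1.0, 0.0, 0.0))
    zero = np.zeros(12)
    archs = [RegimeArchetype(k, zero, forest_fraction=0.0) for k in (1, 2, 3, 4)]
    weights = {"focal": np.array([1.0, 1.0, 1.0, 4.0]) / 7.0}
    series, truth = generate_fire_archive(
        grid, archs, years=3, nlsf_fraction=0.0, seed=seed,
        region_weights=weights)
    anomaly = {(1, "grassy"): 1.0, (2, "grassy"): 2.0, (3, "grassy"): 4.0,
               (4, "grassy"): 0.0}
    env = generate_environment(grid, truth, n_years=3, anomaly=anomaly)
    summary = summarize_degradation(truth.regime_label, grid.region_label,
                                    truth.veg_class, env.tree_cover,
                                    env.tree_loss, env.population)
    rows = summary[(summary.region == "all") & (summary.veg_class == "all")]
    recovered = {int(r.regime): float(r.tree_loss_anomaly)
                 for r in rows.itertuples() if r.regime in (1, 2, 3)}
    baseline = float(rows.loc[rows.regime == "all", "tree_loss_anomaly"].iloc[0])
    return {"recovered": recovered, "planted": {1: 1.0, 2: 2.0, 3: 4.0},
            "baseline_ratio": baseline, "summary": summary,
            "n_per_stratum": n_per_stratum}
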
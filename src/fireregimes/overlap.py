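"""Reduced environmental spaces and niche overlap between regions.

Three PCA-reduced "tropical environments" (fire: 12 characteristics;
vegetation: 6; climate: 4) are each fit on the pooled tropics and
truncated to two axes, so regional score clouds are directly comparable.
Overlap between two regions' occupancy of a space is quantified with
Schoener's D, ``D = 1 - 0.5 * sum |w_a - w_b|``, over a shared R x R
discretisation of the score plane — by default on *binary* occupancy
(a bin counts once no matter how many cells it holds), with the
classical density weighting available as a mode.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from scipy.ndimage import gaussian_filter


@dataclass
class EnvSpace:
    """A 2-axis reduced environment: loadings, variance shares, scores."""

    variables: list[str]
    loadings: np.ndarray          # (n_variables, 2), orthonormal columns
    explained_variance: np.ndarray
    scores: np.ndarray            # (n_cells, 2)
    mean: np.ndarray
    scale: np.ndarray

    def transform(self, table: pd.DataFrame) -> np.ndarray:
        X = (table[self.variables].to_numpy(float) - self.mean) / self.scale
        return X @ self.loadings


def pca_reduce(table: pd.DataFrame, variables: list[str] | None = None) -> EnvSpace:
    """Standardise variables and keep the top two principal axes.

    Zero-variance variables are dropped with a warning (they carry no
    gradient to reduce).  Requires at least 3 cells.
    """
    if variables is None:
        variables = list(table.columns)
    X = table[variables].to_numpy(dtype=float)
    if X.shape[0] < 3:
        raise ValueError("need at least 3 cells for a PCA")
    sd = X.std(axis=0, ddof=0)
    keep = sd > 0
    if not keep.all():
        dropped = [v for v, k in zip(variables, keep) if not k]
        warnings.warn(f"dropping constant variable(s): {dropped}")
        variables = [v for v, k in zip(variables, keep) if k]
        X, sd = X[:, keep], sd[keep]
    mean = X.mean(axis=0)
    Xs = (X - mean) / sd
    pca = PCA(n_components=2).fit(Xs)
    return EnvSpace(
        variables=variables,
        loadings=pca.components_.T.copy(),
        explained_variance=pca.explained_variance_ratio_.copy(),
        scores=pca.transform(Xs),
        mean=mean,
        scale=sd,
    )


@dataclass
class OccupancyGrid:
    """Normalised occupancy weights over an R x R score grid."""

    weights: np.ndarray
    bounds: tuple[float, float, float, float]   # xmin, xmax, ymin, ymax
    mode: str

    def compatible(self, other: "OccupancyGrid") -> bool:
        return (self.weights.shape == other.weights.shape
                and self.bounds == other.bounds and self.mode == other.mode)


def occupancy_grid(
    scores: np.ndarray,
    bounds: tuple[float, float, float, float],
    R: int = 100,
    mode: str = "binary",
    smooth_sigma: float = 0.0,
) -> OccupancyGrid:
    """Bin 2-D scores into an R x R occupancy distribution.

    Binary mode gives every occupied bin equal weight before
    normalisation; density mode uses bin counts (optionally Gaussian
    smoothed).  The bounds must be shared by any two grids compared.
    """
    s = np.asarray(scores, dtype=float)
    if s.size == 0:
        raise ValueError("empty cell set")
    if R < 10:
        raise ValueError("R must be >= 10")
    xmin, xmax, ymin, ymax = bounds
    if (s[:, 0] < xmin).any() or (s[:, 0] > xmax).any() \
            or (s[:, 1] < ymin).any() or (s[:, 1] > ymax).any():
        raise ValueError("scores fall outside the stated bounds")
    H, _, _ = np.histogram2d(s[:, 0], s[:, 1], bins=R,
                             range=[[xmin, xmax], [ymin, ymax]])
    if mode == "binary":
        W = (H > 0).astype(float)
    elif mode == "density":
        W = H
        if smooth_sigma > 0:
            W = gaussian_filter(W, sigma=smooth_sigma)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return OccupancyGrid(weights=W / W.sum(), bounds=bounds, mode=mode)


def schoener_D(grid_a: OccupancyGrid, grid_b: OccupancyGrid) -> float:
    """Schoener's D overlap in [0, 1]; 1 identical, 0 disjoint."""
    if not grid_a.compatible(grid_b):
        raise ValueError("occupancy grids are not comparable")
    return float(1.0 - 0.5 * np.abs(grid_a.weights - grid_b.weights).sum())


def score_bounds(*score_sets: np.ndarray, pad: float = 1e-9) -> tuple[float, float, float, float]:
    """Joint bounds covering every score set (shared grid frame)."""
    allpts = np.vstack(score_sets)
    return (float(allpts[:, 0].min() - pad), float(allpts[:, 0].max() + pad),
            float(allpts[:, 1].min() - pad), float(allpts[:, 1].max() + pad))


def regional_overlap(
    space: EnvSpace,
    labels: np.ndarray,
    region_label: np.ndarray,
    regime: int,
    region_a: str,
    region_b: str,
    R: int = 100,
    mode: str = "binary",
) -> float | None:
    """Schoener's D between two regions' occupancy for one regime.

    Returns ``None`` (overlap undefined, not 0) when the regime is absent
    from either region.
    """
    labels = np.asarray(labels)
    in_a = (labels == regime) & (region_label == region_a)
    in_b = (labels == regime) & (region_label == region_b)
    if not in_a.any() or not in_b.any():
        return None
    sa, sb = space.scores[in_a], space.scores[in_b]
    bounds = score_bounds(sa, sb)
    ga = occupancy_grid(sa, bounds, R=R, mode=mode)
    gb = occupancy_grid(sb, bounds, R=R, mode=mode)
    return schoener_D(ga, gb)


def regime_region_proportions(labels: np.ndarray, region_label: np.ndarray) -> pd.DataFrame:
    """Proportion of each region's classified cells attributed to each regime."""
    df = pd.DataFrame({"regime": np.asarray(labels), "region": np.asarray(region_label)})
    df = df[df.regime > 0]
    out = (df.groupby(["region", "regime"]).size()
             / df.groupby("region").size()).rename("proportion").reset_index()
    return out


def overlap_table(
    space: EnvSpace,
    labels: np.ndarray,
    region_label: np.ndarray,
    focal_region: str = "focal",
    other_regions: tuple[str, ...] = ("continental", "other"),
    R: int = 100,
    modes: tuple[str, ...] = ("binary", "density"),
) -> pd.DataFrame:
    """Per-regime overlap of the focal region against each other region."""
    rows = []
    for regime in sorted(set(np.asarray(labels)[np.asarray(labels) > 0])):
        for region in other_regions:
            for mode in modes:
                d = regional_overlap(space, labels, region_label, int(regime),
                                     focal_region, region, R=R, mode=mode)
                rows.append({"regime": int(regime), "region_pair": f"{focal_region}-{region}",
                             "mode": mode, "schoener_D": d})
    return pd.DataFrame(rows)
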
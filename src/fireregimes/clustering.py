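"""Fire-regime definition by agglomerative complete-linkage clustering.

Regimes are defined on the normalised 12-characteristic vectors of
burned (non-NLSF) cells with Euclidean distance and complete linkage
(each merge scored by the maximum pairwise dissimilarity between the
clusters), cut to a chosen K.  Cluster labels are renumbered so they
ascend with cluster-mean total burned area: label K is always the
highest-fire regime, label 1 the lowest.  NLSF cells keep label 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist


@dataclass
class RegimeMap:
    """Per-cell regime labels: 0 = NLSF, 1..K = regime, -1 = dissimilar."""

    labels: np.ndarray
    K: int
    merge_heights: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        clustered = self.labels[self.labels > 0]
        if clustered.size and clustered.max() > self.K:
            raise ValueError("label exceeds K")


def assign_nlsf(total_burned_area: np.ndarray) -> np.ndarray:
    """NLSF mask: true where total burned area over the span is zero.

    Sub-detection fires (< 0.21 km^2 events) are dropped upstream at
    event level, so a cell whose only fires fall below the floor is NLSF.
    """
    return np.asarray(total_burned_area, dtype=float) <= 0


def complete_linkage_cluster(
    vectors: pd.DataFrame | np.ndarray,
    K: int,
    nlsf_mask: np.ndarray | None = None,
    ba_year_mean: np.ndarray | None = None,
    method: str = "complete",
) -> tuple[RegimeMap, np.ndarray]:
    """Cluster normalised characteristic vectors into K fire regimes.

    Parameters
    ----------
    vectors : (n_cells, 12) table
        Normalised characteristics for all cells.
    K : int
        Number of regimes; 2 <= K <= number of clustered cells.
    nlsf_mask : bool array, optional
        Cells excluded from clustering and labelled 0.
    ba_year_mean : array, optional
        Per-cell mean annual burned area used to order labels; falls back
        to the sum of each cell's characteristic vector.
    method : str
        ``"complete"`` (default) or ``"ward"`` for the supplementary
        within-variance linkage.

    Returns the regime map and the full linkage matrix (scipy format).
    """
    X_all = np.asarray(vectors, dtype=float)
    n_all = X_all.shape[0]
    mask = np.zeros(n_all, dtype=bool) if nlsf_mask is None else np.asarray(nlsf_mask, bool)
    X = X_all[~mask]
    if not np.isfinite(X).all():
        raise ValueError("non-finite characteristic vectors")
    if K < 2:
        raise ValueError("K must be >= 2")
    if K > X.shape[0]:
        raise ValueError(f"K={K} exceeds {X.shape[0]} clustered cells")

    Z = linkage(X, method=method, metric="euclidean")
    raw = fcluster(Z, t=K, criterion="maxclust")

    order_stat = (np.asarray(ba_year_mean, float)[~mask]
                  if ba_year_mean is not None else X.sum(axis=1))
    means = pd.Series(order_stat).groupby(raw).mean()
    # ascending burned area -> ascending label; ties broken by cluster id
    rank = {old: i + 1 for i, old in enumerate(means.sort_values(kind="stable").index)}
    relabelled = np.array([rank[r] for r in raw])

    labels = np.zeros(n_all, dtype=int)
    labels[~mask] = relabelled
    return RegimeMap(labels=labels, K=K, merge_heights=Z[:, 2].copy()), Z


def cut_height_diagnostics(Z: np.ndarray, k_range: range | list[int] = range(2, 11),
                           flag_ratio: float = 0.5) -> pd.DataFrame:
    """Relative dendrogram cut height for each candidate K.

    For each K the cut height is the merge height at which K clusters
    collapse to K-1, expressed relative to the final (maximum) merge.
    K values cutting above ``flag_ratio`` (default 50% of tree height)
    sit at a natural break in dataset variability and are flagged.
    """
    heights = np.asarray(Z)[:, 2]
    n = heights.size + 1
    hmax = heights[-1] if heights[-1] > 0 else np.inf
    rows = []
    for k in k_range:
        if k < 2 or k > n - 1:
            continue
        ratio = float(heights[n - k] / hmax)
        rows.append({"K": k, "cut_height": float(heights[n - k]),
                     "relative_height": ratio, "flagged": ratio > flag_ratio})
    return pd.DataFrame(rows)
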
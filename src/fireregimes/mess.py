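"""Multivariate environmental similarity surface (MESS) projection.

For each regime, every target cell is scored against the regime's
reference cells (the focal region's members) on each of the 12
characteristics; the cell's MESS value is the minimum of the per-variable
scores.  Positive values mean the cell lies inside the reference range on
every variable; 100 is the maximum (at the per-variable median).  Cells
positive for at least one regime are "similar", cells non-positive for
all regimes are "dissimilar", and cells positive above the exclusivity
threshold (default 24) for exactly one regime form the mutually
exclusive subset used for clean cross-region comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .clustering import RegimeMap

#: Similarity threshold above which a single-regime match is "exclusive".
EXCLUSIVE_THRESHOLD = 24.0
#: Sentinel for a point off the value of a zero-range reference variable.
DEGENERATE_SCORE = -1.0e6


def mess_variable(reference: np.ndarray, points: np.ndarray,
                  ties_below: bool = False) -> np.ndarray:
    """Per-variable MESS score of ``points`` against a reference sample.

    With ``f`` the percentage of reference values strictly below the
    point (ties count as not-below by default), the score is::

        f = 0        ->  100 * (point - min) / (max - min)   (<= 0)
        0 < f <= 50  ->  2 f
        50 < f < 100 ->  2 (100 - f)
        f = 100      ->  100 * (max - point) / (max - min)   (<= 0)

    A degenerate reference (max == min) scores 100 where the point equals
    the constant and a large negative sentinel elsewhere.
    """
    ref = np.asarray(reference, dtype=float)
    if ref.size == 0:
        raise ValueError("empty reference set")
    pts = np.atleast_1d(np.asarray(points, dtype=float))
    rmin, rmax = ref.min(), ref.max()
    if rmax == rmin:
        out = np.where(pts == rmin, 100.0, DEGENERATE_SCORE)
        return out if np.ndim(points) else float(out[0])

    sorted_ref = np.sort(ref)
    side = "left" if not ties_below else "right"
    f = 100.0 * np.searchsorted(sorted_ref, pts, side=side) / ref.size

    span = rmax - rmin
    out = np.empty_like(pts)
    lo = f == 0
    hi = f == 100
    mid_lo = (f > 0) & (f <= 50)
    mid_hi = (f > 50) & (f < 100)
    out[lo] = 100.0 * (pts[lo] - rmin) / span
    out[mid_lo] = 2.0 * f[mid_lo]
    out[mid_hi] = 2.0 * (100.0 - f[mid_hi])
    out[hi] = 100.0 * (rmax - pts[hi]) / span
    return out if np.ndim(points) else float(out[0])


@dataclass
class MESSSurface:
    """Per-cell similarity to each regime's reference set.

    ``values`` is (n_cells, K); column j holds similarity to regime j+1.
    """

    values: np.ndarray
    regimes: list[int]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values,
                            columns=[f"regime_{r}" for r in self.regimes])


def mess_surface(
    reference_vectors: pd.DataFrame | np.ndarray,
    reference_labels: np.ndarray,
    target_vectors: pd.DataFrame | np.ndarray,
    ties_below: bool = False,
) -> MESSSurface:
    """One similarity surface per regime over the target cells.

    ``reference_vectors``/``target_vectors`` must be normalised with the
    *same* (reference-domain) scaling parameters.  Reference sets with
    fewer than 2 cells are rejected.
    """
    ref = np.asarray(reference_vectors, dtype=float)
    tgt = np.asarray(target_vectors, dtype=float)
    labels = np.asarray(reference_labels, dtype=int)
    if ref.shape[1] != tgt.shape[1]:
        raise ValueError("reference and target variable counts differ")
    regimes = sorted(int(r) for r in np.unique(labels) if r > 0)
    out = np.empty((tgt.shape[0], len(regimes)))
    for j, r in enumerate(regimes):
        sub = ref[labels == r]
        if sub.shape[0] < 2:
            raise ValueError(f"regime {r} has fewer than 2 reference cells")
        per_var = np.column_stack([
            mess_variable(sub[:, v], tgt[:, v], ties_below=ties_below)
            for v in range(sub.shape[1])
        ])
        out[:, j] = per_var.min(axis=1)
    return MESSSurface(values=out, regimes=regimes)


def classify_tropics(
    surface: MESSSurface,
    nlsf_mask: np.ndarray,
    exclusive_threshold: float = EXCLUSIVE_THRESHOLD,
) -> tuple[RegimeMap, np.ndarray]:
    """Label every cell from its similarity surface.

    NLSF cells get 0; burned cells non-positive for every regime get -1
    (dissimilar — fire conditions absent from the focal region); the
    rest take the regime of maximum similarity.  The exclusivity mask is
    true where exactly one regime exceeds the threshold.
    """
    nlsf = np.asarray(nlsf_mask, dtype=bool)
    vals = surface.values
    if nlsf.size != vals.shape[0]:
        raise ValueError("mask and surface grids differ")
    regimes = np.asarray(surface.regimes)

    labels = np.full(nlsf.size, -1, dtype=int)
    similar = (vals > 0).any(axis=1)
    best = regimes[np.argmax(vals, axis=1)]
    labels[similar] = best[similar]
    labels[nlsf] = 0

    exclusive = ((vals > exclusive_threshold).sum(axis=1) == 1) & ~nlsf
    return RegimeMap(labels=labels, K=int(regimes.max())), exclusive


def similarity_coverage(labels: np.ndarray, total_burned_area: np.ndarray) -> dict:
    """Fraction of burned area (and of burned cells) in similar classes.

    The headline projection statistic: how much of the domain's burned
    area falls in cells classified as some focal regime (1..K) rather
    than dissimilar (-1).  NLSF cells carry no burned area and drop out.
    """
    labels = np.asarray(labels, dtype=int)
    ba = np.asarray(total_burned_area, dtype=float)
    burned = ba > 0
    if not burned.any():
        raise ValueError("zero total burned area")
    similar = labels > 0
    return {
        "burned_area_fraction": float(ba[similar].sum() / ba[burned].sum()),
        "burned_cell_fraction": float((similar & burned).sum() / burned.sum()),
    }
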
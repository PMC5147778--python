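"""Correlation-integral (fractal) dimensionality of a point cloud.

A nonlinear cross-check on PCA dimensionality: for a growing radius r,
count the mean number of other points N(r) within distance r of each
point; the slope of log N versus log r inside a scaling region is the
correlation dimension.  Natural logarithms are used on both axes (the
slope is base-invariant).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist
from scipy.stats import linregress

from .errors import DegenerateDataError, InvalidInputError


@dataclass
class NeighborCurve:
    """Mean neighbor counts at a grid of radii, on log axes."""

    radii: np.ndarray
    log_counts: np.ndarray        # ln of mean neighbors, -inf where zero
    n_points: int

    def __post_init__(self) -> None:
        self.radii = np.asarray(self.radii, dtype=float)
        self.log_counts = np.asarray(self.log_counts, dtype=float)


def neighbor_curve(points: np.ndarray,
                   radii: np.ndarray | None = None,
                   n_radii: int = 50) -> NeighborCurve:
    """Mean number of neighbors within each radius (self excluded).

    With no explicit grid, radii are log-spaced between the 1st and 99th
    percentiles of the pairwise distances.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    n = points.shape[0]
    if n < 2:
        raise InvalidInputError("need at least two points")
    d = pdist(points)
    if np.all(d == 0):
        raise DegenerateDataError("all points are identical")
    if radii is None:
        lo, hi = np.percentile(d[d > 0], [1, 99])
        radii = np.geomspace(lo, hi, n_radii)
    else:
        radii = np.sort(np.asarray(radii, dtype=float))
        if np.any(radii <= 0):
            raise InvalidInputError("radii must be positive")
    d.sort()
    # pairs within r, each pair contributes a neighbor to both endpoints
    pair_counts = np.searchsorted(d, radii, side="right")
    mean_neighbors = 2.0 * pair_counts / n
    with np.errstate(divide="ignore"):
        log_counts = np.log(mean_neighbors)
    return NeighborCurve(radii=radii, log_counts=log_counts, n_points=n)


def fractal_dimensionality(curve: NeighborCurve,
                           bounds: tuple[float, float] = (6.0, 12.0)) -> float:
    """Least-squares slope of log N versus log r inside the bounds.

    ``bounds`` delimit the log-neighbor axis (not the radius axis); the
    conventional windows are (6, 12) for pixel clouds with ~750 points of
    high ambient dimension and (4, 10) for smaller population-activity
    clouds.  The window excludes the saturated large-r regime and the
    sparse small-r regime.
    """
    lo, hi = bounds
    sel = np.isfinite(curve.log_counts) & (curve.log_counts >= lo) \
        & (curve.log_counts <= hi)
    if np.count_nonzero(sel) < 2:
        raise InvalidInputError(
            f"fewer than 2 curve points with log N in [{lo}, {hi}]")
    fit = linregress(np.log(curve.radii[sel]), curve.log_counts[sel])
    return float(fit.slope)
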
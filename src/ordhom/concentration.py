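"""Lorenz-curve concentration index and true diversity.

The Concentration Index (CI) measures the *evenness* of the category shares
irrespective of their order: 0 for the uniform distribution, 1 when the whole
population sits in a single category.  It is defined as twice the area
between the Lorenz curve of the (ascending-sorted) proportions and the line
of equality, rescaled so the singleton attains exactly 1.  For a discrete
distribution the Lorenz curve is piecewise linear, so the trapezoid area is
exact and the index coincides with the pairwise mean-absolute-difference
(Gini) form ``sum_{i<j} |p_i - p_j| / (n - 1)``.

The CI converts to an *effective number of categories* (true diversity, s):
the number of equally abundant categories whose CI matches the observed one.
Because a block of s equal categories has ``CI = (n - s)/(n - 1)``, the
conversion is ``s = n - (n - 1) * CI`` — exact for integer blocks,
continuous and decreasing in concentration in between.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .distributions import OrdinalDistribution

__all__ = ["LorenzCurve", "lorenz_curve", "concentration_index", "true_diversity"]


@dataclass(frozen=True)
class LorenzCurve:
    """Piecewise-linear Lorenz curve as (cumulative category share,
    cumulative population share) pairs from (0, 0) to (1, 1).

    With proportions sorted ascending both coordinates are nondecreasing and
    the curve lies on or below the line of equality.
    """

    points: np.ndarray  # shape (n + 1, 2)

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError("points must be an (m, 2) array")
        if not (np.allclose(pts[0], [0, 0]) and np.allclose(pts[-1], [1, 1])):
            raise ValueError("curve must run from (0,0) to (1,1)")
        if np.any(np.diff(pts, axis=0) < -1e-12):
            raise ValueError("both coordinates must be nondecreasing")
        pts.setflags(write=False)
        object.__setattr__(self, "points", pts)

    def twice_area_below_diagonal(self) -> float:
        """Twice the area between the line of equality and the curve (exact
        trapezoid integration of a piecewise-linear curve)."""
        x = self.points[:, 0]
        y = self.points[:, 1]
        area_under = float(np.trapezoid(y, x))
        return 2.0 * (0.5 - area_under)


def lorenz_curve(d: OrdinalDistribution) -> LorenzCurve:
    """Lorenz curve of the ascending-sorted proportions.

    Sorting canonicalises the curve: the concentration index is symmetric
    under permutation of the shares, and on sorted shares the curve is convex
    and lies below the diagonal.
    """
    p = np.sort(d.proportions)
    n = d.n
    x = np.arange(n + 1) / n
    y = np.concatenate([[0.0], np.cumsum(p)])
    y[-1] = 1.0
    return LorenzCurve(np.column_stack([x, y]))


def concentration_index(d: OrdinalDistribution) -> float:
    """Twice the Lorenz area, normalised so the singleton scores exactly 1.

    Symmetric in the proportions and strictly Schur-convex: any transfer of
    share from a smaller to a larger proportion increases the index.
    """
    raw = lorenz_curve(d).twice_area_below_diagonal()
    n = d.n
    singleton_raw = (n - 1) / n  # twice-area of the one-category distribution
    ci = raw / singleton_raw
    # guard float round-off at the boundaries
    return float(min(1.0, max(0.0, ci)))


def true_diversity(d: OrdinalDistribution) -> float:
    """Effective number of categories ``s = n - (n - 1) * CI`` in [1, n]."""
    return float(d.n - (d.n - 1) * concentration_index(d))
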
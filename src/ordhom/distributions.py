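"""Probability vectors over ordered categories.

The central object is :class:`OrdinalDistribution`: the share of an area's
population falling in each of ``n`` ordered categories (for example the ten
deciles of a socioeconomic index).  Categories are labelled 1..n in all
user-facing output.  Two canonical families recur throughout the package:

* the **uniform** distribution ``(1/n, ..., 1/n)`` — every category equally
  abundant, the most heterogeneous shape;
* the **block** distribution — ``s`` consecutive categories each carrying
  ``1/s`` — the reference shape of "s equally abundant consecutive
  categories" that anchors the homogeneity classification.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "OrdinalDistribution",
    "AreaRecord",
    "from_counts",
    "from_proportions",
    "uniform",
    "block",
]

#: tolerance on the sum of proportions at construction (CSV inputs carry rounding)
SUM_ATOL = 1e-9

MIN_CATEGORIES = 3


class ValidationError(ValueError):
    """Input violates a structural contract (shape, sign, range)."""


class DegenerateInputError(ValueError):
    """Input is structurally valid but carries no information (e.g. all-zero counts)."""


@dataclass(frozen=True)
class OrdinalDistribution:
    """Proportions over ``n`` ordered categories.

    Parameters
    ----------
    proportions:
        Nonnegative shares summing to 1 (within ``atol``; renormalised
        exactly on construction).
    labels:
        Optional ordered category names; defaults to ``["1", ..., "n"]``.
    population:
        Optional nonnegative total count behind the proportions.
    """

    proportions: np.ndarray
    labels: Optional[tuple[str, ...]] = None
    population: Optional[float] = None
    atol: float = field(default=SUM_ATOL, repr=False, compare=False)

    def __post_init__(self) -> None:
        p = np.asarray(self.proportions, dtype=float)
        if p.ndim != 1:
            raise ValidationError("proportions must be a 1-d sequence")
        if p.size < MIN_CATEGORIES:
            raise ValidationError(
                f"need at least {MIN_CATEGORIES} ordered categories, got {p.size}"
            )
        if np.any(p < 0):
            raise ValidationError("proportions must be nonnegative")
        total = p.sum()
        if not np.isfinite(total) or total <= 0:
            raise DegenerateInputError("proportions must have a positive finite sum")
        if abs(total - 1.0) > self.atol:
            raise ValidationError(
                f"proportions sum to {total:.12g}, outside tolerance {self.atol:g} of 1"
            )
        p = p / total  # exact renormalisation
        p.setflags(write=False)
        object.__setattr__(self, "proportions", p)
        if self.labels is not None:
            lab = tuple(str(x) for x in self.labels)
            if len(lab) != p.size:
                raise ValidationError("labels length must match number of categories")
            object.__setattr__(self, "labels", lab)
        if self.population is not None and self.population < 0:
            raise ValidationError("population must be nonnegative")

    @property
    def n(self) -> int:
        """Number of ordered categories."""
        return int(self.proportions.size)

    @property
    def categories(self) -> np.ndarray:
        """1-based category positions ``[1, ..., n]``."""
        return np.arange(1, self.n + 1)

    def cumulative(self) -> np.ndarray:
        """Cumulative proportions ``F_i`` through category i (last entry 1)."""
        F = np.cumsum(self.proportions)
        F[-1] = 1.0
        return F

    def reverse(self) -> "OrdinalDistribution":
        """The distribution with category order flipped (used by symmetry tests)."""
        lab = self.labels[::-1] if self.labels is not None else None
        return OrdinalDistribution(self.proportions[::-1].copy(), lab, self.population)

    def is_singleton(self) -> bool:
        return bool(np.max(self.proportions) == 1.0)

    def __len__(self) -> int:
        return self.n


@dataclass(frozen=True)
class AreaRecord:
    """One geographic area: identifier, its ordinal distribution, optional score.

    ``score`` carries a conventional summary value such as the population
    weighted average of subunit index scores, when available.
    """

    area_id: str
    distribution: OrdinalDistribution
    score: Optional[float] = None

    def __post_init__(self) -> None:
        if not str(self.area_id):
            raise ValidationError("area_id must be non-empty")


def from_counts(
    counts: Sequence[float],
    labels: Optional[Sequence[str]] = None,
) -> OrdinalDistribution:
    """Build a distribution from raw per-category counts.

    Scale invariant: multiplying every count by a positive constant yields the
    identical distribution.  Preserves the total as ``population``.
    """
    c = np.asarray(counts, dtype=float)
    if c.ndim != 1 or c.size < MIN_CATEGORIES:
        raise ValidationError(
            f"counts must be a 1-d sequence of length >= {MIN_CATEGORIES}"
        )
    if np.any(c < 0):
        raise ValidationError("counts must be nonnegative")
    total = c.sum()
    if total <= 0:
        raise DegenerateInputError("all-zero counts carry no distribution")
    return OrdinalDistribution(c / total, labels, population=float(total))


def from_proportions(
    proportions: Sequence[float],
    labels: Optional[Sequence[str]] = None,
    population: Optional[float] = None,
    atol: float = SUM_ATOL,
) -> OrdinalDistribution:
    """Build a distribution from shares, renormalising within ``atol`` of 1."""
    return OrdinalDistribution(np.asarray(proportions, float), labels, population, atol)


def uniform(n: int) -> OrdinalDistribution:
    """The equally-abundant distribution ``(1/n, ..., 1/n)``."""
    if n < MIN_CATEGORIES:
        raise ValidationError(f"n must be >= {MIN_CATEGORIES}, got {n}")
    return OrdinalDistribution(np.full(n, 1.0 / n))


def block(s: int, n: int, start: int = 1) -> OrdinalDistribution:
    """``s`` consecutive categories each carrying ``1/s``, the rest zero.

    ``start`` is the 1-based position of the first nonzero category.
    """
    if n < MIN_CATEGORIES:
        raise ValidationError(f"n must be >= {MIN_CATEGORIES}, got {n}")
    if not 1 <= s <= n:
        raise ValidationError(f"block size s={s} must lie in [1, {n}]")
    if not 1 <= start <= n - s + 1:
        raise ValidationError(
            f"block [{start}, {start + s - 1}] exceeds the category range [1, {n}]"
        )
    p = np.zeros(n)
    p[start - 1 : start - 1 + s] = 1.0 / s
    return OrdinalDistribution(p)
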
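"""Synthetic area generators for testing and demonstration.

The generators emulate the kinds of decile distributions seen in area-level
disadvantage data, without any external download:

* ``block`` — s equally populated consecutive categories at a random start
  (idealised homogeneous areas);
* ``dirichlet`` — symmetric Dirichlet(alpha) draws: small alpha gives
  concentrated, spiky areas; large alpha near-uniform, heterogeneous ones;
* ``long_tail`` — a dominant block with a geometrically decaying tail
  (homogeneous areas in practice are mostly long-tailed skewed shapes);
* ``bimodal_extreme`` — mass split between the first and last categories,
  the maximally polarized shape.

Area populations are drawn log-uniformly in [1e3, 1e5], the scale of
mid-size census reporting units.  A single integer seed determines every
draw; no global random state is touched.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .distributions import AreaRecord, OrdinalDistribution, ValidationError

__all__ = ["SyntheticSpec", "generate_areas", "generate_hierarchy"]

FAMILIES = ("block", "dirichlet", "long_tail", "bimodal_extreme")

POP_RANGE = (1e3, 1e5)


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for a reproducible set of synthetic areas.

    ``params`` per family: block -> ``s`` (block size); dirichlet ->
    ``alpha`` (concentration); long_tail -> ``s`` (dominant block size) and
    ``tail_mass`` (total mass in the tail); bimodal_extreme -> ``end_share``
    (share in the first category; the rest goes to the last).
    """

    n_categories: int
    n_areas: int
    family: str
    params: Mapping[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_categories < 3:
            raise ValidationError("n_categories must be >= 3")
        if self.n_areas < 1:
            raise ValidationError("n_areas must be >= 1")
        if self.family not in FAMILIES:
            raise ValidationError(f"unknown family {self.family!r}; choose from {FAMILIES}")


def _draw_proportions(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    n = spec.n_categories
    p = np.zeros(n)
    if spec.family == "block":
        s = int(spec.params.get("s", 3))
        if not 1 <= s <= n:
            raise ValidationError(f"block size s={s} out of [1, {n}]")
        start = int(rng.integers(0, n - s + 1))
        p[start : start + s] = 1.0 / s
    elif spec.family == "dirichlet":
        alpha = float(spec.params.get("alpha", 1.0))
        if alpha <= 0:
            raise ValidationError("alpha must be positive")
        p = rng.dirichlet(np.full(n, alpha))
    elif spec.family == "long_tail":
        s = int(spec.params.get("s", 3))
        tail_mass = float(spec.params.get("tail_mass", 0.05))
        if not 1 <= s < n:
            raise ValidationError(f"dominant block s={s} out of [1, {n})")
        if not 0 <= tail_mass < 1:
            raise ValidationError("tail_mass must lie in [0, 1)")
        left = bool(rng.integers(0, 2))  # tail direction
        core = np.arange(s)
        p[core] = (1.0 - tail_mass) / s
        tail = np.arange(s, n)
        w = 0.5 ** np.arange(tail.size)
        p[tail] = tail_mass * w / w.sum()
        if left:
            p = p[::-1].copy()
    else:  # bimodal_extreme
        end_share = float(spec.params.get("end_share", 0.5))
        if not 0 < end_share < 1:
            raise ValidationError("end_share must lie in (0, 1)")
        p[0], p[-1] = end_share, 1.0 - end_share
    return p


def generate_areas(spec: SyntheticSpec) -> list[AreaRecord]:
    """Draw ``spec.n_areas`` areas; bit-identical for identical specs."""
    rng = np.random.default_rng(spec.seed)
    areas = []
    width = len(str(spec.n_areas))
    for i in range(spec.n_areas):
        p = _draw_proportions(spec, rng)
        pop = float(np.round(10 ** rng.uniform(np.log10(POP_RANGE[0]), np.log10(POP_RANGE[1]))))
        areas.append(
            AreaRecord(
                area_id=f"SYN{i + 1:0{width}d}",
                distribution=OrdinalDistribution(p, population=pop),
            )
        )
    return areas


def _integer_split(total: int, weights: np.ndarray) -> np.ndarray:
    """Largest-remainder apportionment of ``total`` units over ``weights``."""
    quota = total * weights / weights.sum()
    base = np.floor(quota).astype(int)
    rem = total - base.sum()
    if rem > 0:
        order = np.argsort(-(quota - base), kind="stable")
        base[order[:rem]] += 1
    return base


def generate_hierarchy(spec: SyntheticSpec, subunits_per_area: int) -> pd.DataFrame:
    """Subunit table (subunit_id, area_id, category, population) whose
    per-area aggregation reproduces each area's distribution within
    integer-rounding error, conserving total population exactly.

    Each subunit carries a single category label, mirroring small census
    blocks nested in a reporting area.  Subunit counts per category follow a
    largest-remainder split of ``subunits_per_area``; every populated
    category receives at least one subunit, so very small requested counts
    may be exceeded.
    """
    if subunits_per_area < 1:
        raise ValidationError("subunits_per_area must be >= 1")
    areas = generate_areas(spec)
    rows = []
    for a in areas:
        p = a.distribution.proportions
        total = int(a.distribution.population or 1000)
        cat_pop = _integer_split(total, p)
        # drop zero-population categories; split the rest across subunits
        nonzero = np.flatnonzero(cat_pop > 0)
        counts = _integer_split(max(subunits_per_area, nonzero.size), p[nonzero])
        counts = np.maximum(counts, 1)
        j = 0
        for cat_idx, n_sub in zip(nonzero, counts):
            sub_pop = _integer_split(int(cat_pop[cat_idx]), np.ones(n_sub))
            for sp in sub_pop:
                rows.append(
                    {
                        "subunit_id": f"{a.area_id}.{j + 1:04d}",
                        "area_id": a.area_id,
                        "category": int(cat_idx + 1),
                        "population": int(sp),
                    }
                )
                j += 1
    return pd.DataFrame(rows, columns=["subunit_id", "area_id", "category", "population"])
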
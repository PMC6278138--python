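"""Homogeneity Index, guideline thresholds and the A-D classification.

The Homogeneity Index of a distribution P over n >= 3 ordered categories is

    HI(P) = 100 * [ CI(P) + DI(U_n) - DI(P) ] / [ 1 + DI(U_n) ],

where CI is the concentration index, DI the divergence index and U_n the
uniform distribution.  HI is 0 for the uniform distribution and 100 for a
singleton: concentration raises it, polarization beyond the uniform level
lowers it.  (A thin set of end-loaded near-uniform shapes would score
marginally below 0 under the calibrated DI; HI is clamped at the
heterogeneous floor 0 — see docs/methods.md.)

Areas are graded by comparing HI with the index values of *block*
distributions — s equally populated consecutive categories:

=====  ==========================  =======================================
class  range                       reading
=====  ==========================  =======================================
A      HI(4) <= HI <= 100          acceptably homogeneous
B      HI(5) <= HI < HI(4)         marginal; some reassignment may help
C      HI(6) <= HI < HI(5)         judgement required
D      0 <= HI < HI(6)             heterogeneous; reassignment needed
=====  ==========================  =======================================

The thresholds HI(s) = HI(block(s, n)) are recomputed from the block
distributions for any n (decile scale: 68.53 / 57.62 / 46.62), never
hard-coded in the classification logic.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .concentration import concentration_index, true_diversity
from .distributions import (
    AreaRecord,
    OrdinalDistribution,
    ValidationError,
    block,
)
from .divergence import di_uniform, divergence_index

__all__ = [
    "HomogeneityResult",
    "ClassThresholds",
    "homogeneity_index",
    "class_thresholds",
    "classify",
    "classify_dataset",
    "DatasetClassification",
]

CLASS_LABELS = ("A", "B", "C", "D")


@dataclass(frozen=True)
class HomogeneityResult:
    """Full homogeneity summary for one distribution.

    ``ci`` in [0, 1]; ``di`` >= 0; ``hi`` in percent [0, 100]; ``s`` the true
    diversity (effective number of categories); ``klass`` one of A-D.
    """

    ci: float
    di: float
    hi: float
    s: float
    klass: str


@dataclass(frozen=True)
class ClassThresholds:
    """Class boundaries for n categories: hi4 (A/B), hi5 (B/C), hi6 (C/D),
    in percent.  Strictly decreasing; hi6 is 0 when n = 6 (the 6-block is
    then the uniform distribution)."""

    n: int
    hi4: float
    hi5: float
    hi6: float

    def __post_init__(self) -> None:
        if not (100.0 > self.hi4 > self.hi5 > self.hi6 >= 0.0):
            raise ValidationError(
                f"thresholds must satisfy 100 > hi4 > hi5 > hi6 >= 0, got "
                f"{self.hi4}, {self.hi5}, {self.hi6}"
            )


def homogeneity_index(d: OrdinalDistribution) -> float:
    """HI of a distribution, in percent (0 = uniform, 100 = singleton)."""
    num = concentration_index(d) + di_uniform(d.n) - divergence_index(d)
    hi = 100.0 * num / (1.0 + di_uniform(d.n))
    return float(np.clip(hi, 0.0, 100.0))


@lru_cache(maxsize=None)
def class_thresholds(n: int) -> ClassThresholds:
    """Thresholds computed from block distributions of 4, 5 and 6 categories."""
    if n < 6:
        raise ValidationError(f"class thresholds need n >= 6, got {n}")
    return ClassThresholds(
        n=n,
        hi4=homogeneity_index(block(4, n)),
        hi5=homogeneity_index(block(5, n)),
        hi6=homogeneity_index(block(6, n)),
    )


def _classify_value(hi: float, th: ClassThresholds) -> str:
    # boundary conventions: A closed on both ends; B, C, D half-open below
    if th.hi4 <= hi <= 100.0:
        return "A"
    if th.hi5 <= hi:
        return "B"
    if th.hi6 <= hi:
        return "C"
    return "D"


def classify(d: OrdinalDistribution) -> str:
    """Concentration class A-D of a distribution."""
    return _classify_value(homogeneity_index(d), class_thresholds(d.n))


def assess(d: OrdinalDistribution) -> HomogeneityResult:
    """All homogeneity quantities for one distribution."""
    hi = homogeneity_index(d)
    return HomogeneityResult(
        ci=concentration_index(d),
        di=divergence_index(d),
        hi=hi,
        s=true_diversity(d),
        klass=_classify_value(hi, class_thresholds(d.n)),
    )


@dataclass(frozen=True)
class DatasetClassification:
    """Per-area results plus the class composition of the dataset.

    ``table`` is indexed by area_id with columns ci, di, hi, s, klass.
    ``class_summary`` has one row per class A-D with count and percent of
    areas (percentages reported to 2 decimals).
    """

    table: pd.DataFrame
    class_summary: pd.DataFrame


def classify_dataset(areas: Sequence[AreaRecord] | Iterable[AreaRecord]) -> DatasetClassification:
    """Classify every area and tabulate the class composition."""
    areas = list(areas)
    if not areas:
        raise ValidationError("need at least one area")
    ids = [a.area_id for a in areas]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValidationError(f"duplicate area_id(s): {dupes}")
    rows = []
    for a in areas:
        r = assess(a.distribution)
        rows.append(
            {"area_id": a.area_id, "ci": r.ci, "di": r.di, "hi": r.hi, "s": r.s, "klass": r.klass}
        )
    table = pd.DataFrame(rows).set_index("area_id")
    counts = table["klass"].value_counts().reindex(CLASS_LABELS, fill_value=0)
    summary = pd.DataFrame(
        {
            "count": counts,
            "percent": (100.0 * counts / len(table)).round(2),
        }
    )
    summary.index.name = "klass"
    return DatasetClassification(table=table, class_summary=summary)
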
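"""Disadvantage banding and peer-group construction for indicator reporting.

Areas are banded by their Location Index with the 40-40-20 split used for
skewed ("clumped") disadvantage-index distributions: on a decile scale the
lowest four deciles are *high* disadvantage, deciles 5-8 *medium*, and the
top two *low* disadvantage.  (Low positions on a relative-disadvantage index
mean high disadvantage; the band naming follows that convention to avoid
sign confusion.)  Peer groups — sets of areas fair to compare on a health
indicator — are the bands restricted to areas whose distribution is
acceptably concentrated (homogeneity classes A, B or C); class-D areas are
heterogeneous and never enter a peer group.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .distributions import ValidationError

__all__ = [
    "PeerGroupAssignment",
    "IndicatorRecord",
    "disadvantage_band",
    "build_peer_groups",
    "report_variation",
]

log = logging.getLogger(__name__)

BANDS = ("high", "medium", "low")


@dataclass(frozen=True)
class PeerGroupAssignment:
    """Band and peer-group membership for one area.

    ``in_peer_group`` is True only for homogeneity classes A-C; the band is a
    function of the Location Index alone.
    """

    area_id: str
    li: int
    band: str
    klass: str
    in_peer_group: bool
    peer_group_id: Optional[str] = None


@dataclass(frozen=True)
class IndicatorRecord:
    """A health-indicator rate for one area (e.g. age-standardised percent
    of very high GP attenders); rates are consumed as given."""

    area_id: str
    rate: float
    rank_group: Optional[int] = None

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise ValidationError(f"rate must be nonnegative, got {self.rate}")


def disadvantage_band(li: int, n: int = 10) -> str:
    """Band of a Location Index: 40% high / 40% medium / 20% low.

    Cut positions generalise the decile rule by the same fractions with
    boundaries rounded down: categories 1..floor(0.4 n) are high and the top
    floor(0.2 n) categories are low.
    """
    if not 1 <= li <= n:
        raise ValidationError(f"li={li} out of range [1, {n}]")
    high_cut = int(np.floor(0.4 * n))       # 4 for deciles
    low_cut = n - int(np.floor(0.2 * n))    # 8 for deciles: low is 9..10
    if li <= high_cut:
        return "high"
    if li > low_cut:
        return "low"
    return "medium"


def build_peer_groups(
    results: Mapping[str, Mapping[str, object]] | pd.DataFrame,
    n: int = 10,
) -> list[PeerGroupAssignment]:
    """Assign every area to a band and, when acceptably homogeneous, to the
    band's peer group.

    ``results`` maps area_id to at least ``{"klass": ..., "li": ...}`` (a
    DataFrame indexed by area_id with those columns works).  Peer-group ids
    are the band names, so membership is stable and deterministic.
    """
    if isinstance(results, pd.DataFrame):
        missing = {"klass", "li"} - set(results.columns)
        if missing:
            raise ValidationError(f"results missing columns: {sorted(missing)}")
        items = [(str(i), row["klass"], row["li"]) for i, row in results.iterrows()]
    else:
        items = []
        for area_id, rec in results.items():
            if "klass" not in rec or "li" not in rec:
                raise ValidationError(f"area {area_id!r} missing class or LI")
            items.append((str(area_id), rec["klass"], rec["li"]))
    out = []
    for area_id, klass, li in sorted(items):
        if klass is None or li is None or (isinstance(li, float) and np.isnan(li)):
            raise ValidationError(f"area {area_id!r} missing class or LI")
        li = int(li)
        band = disadvantage_band(li, n)
        member = str(klass) in {"A", "B", "C"}
        out.append(
            PeerGroupAssignment(
                area_id=area_id,
                li=li,
                band=band,
                klass=str(klass),
                in_peer_group=member,
                peer_group_id=band if member else None,
            )
        )
    return out


def report_variation(
    groups: Sequence[PeerGroupAssignment] | Iterable[PeerGroupAssignment],
    indicators: Sequence[IndicatorRecord] | Iterable[IndicatorRecord],
    k: int = 4,
) -> pd.DataFrame:
    """Per-peer-group indicator summaries plus a k-way rank split.

    Returns one row per peer group (min, max, mean, count of rates) —
    grouped areas without an indicator are excluded with a logged warning.
    The returned frame's ``attrs["rank_groups"]`` maps area_id to its rank
    group 1..k (1 = highest rates) over all grouped areas with a rate.
    """
    indicators = list(indicators)
    if not indicators:
        raise ValidationError("indicator table is empty")
    rates = {r.area_id: r.rate for r in indicators}
    rows = []
    for g in groups:
        if not g.in_peer_group:
            continue
        if g.area_id not in rates:
            log.warning("area %s is grouped but has no indicator rate; excluded", g.area_id)
            continue
        rows.append({"peer_group_id": g.peer_group_id, "area_id": g.area_id, "rate": rates[g.area_id]})
    if not rows:
        raise ValidationError("no grouped area has an indicator rate")
    df = pd.DataFrame(rows)
    summary = (
        df.groupby("peer_group_id")["rate"]
        .agg(rate_min="min", rate_max="max", rate_mean="mean", n_areas="count")
        .reset_index()
    )
    # overall rank split: descending rate into k near-equal groups
    ranked = df.sort_values(["rate", "area_id"], ascending=[False, True]).reset_index(drop=True)
    m = len(ranked)
    sizes = np.full(min(k, m), m // min(k, m))
    sizes[: m % min(k, m)] += 1
    labels = np.repeat(np.arange(1, len(sizes) + 1), sizes)
    summary.attrs["rank_groups"] = dict(zip(ranked["area_id"], labels.tolist()))
    return summary
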
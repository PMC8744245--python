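"""Cost-effectiveness ranking: dominance, ICERs, and WTP verdicts.

Given each strategy's lifetime discounted (cost, QALYs), strategies are
ranked by increasing cost, strongly dominated ones (costlier and less
effective than some alternative) are eliminated, extended dominance is
applied along the remaining frontier, and sequential incremental
cost-effectiveness ratios (ICERs) are computed.  A strategy is judged
cost-effective at a willingness-to-pay (WTP) threshold when its frontier
ICER does not exceed it; the chosen strategy is equivalently the net
monetary benefit (NMB = WTP·QALYs − cost) maximizer, which the test suite
cross-checks by brute force.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import pandas as pd

__all__ = [
    "CEAError",
    "IcerValue",
    "CEARow",
    "CEATable",
    "icer",
    "net_monetary_benefit",
    "dominance_frontier",
    "wtp_verdict",
]

REFERENCE = "reference"
ON_FRONTIER = "on-frontier"
DOMINATED = "dominated"
EXTENDED_DOMINATED = "extended-dominated"


class CEAError(ValueError):
    """Invalid input to the cost-effectiveness ranking."""


@dataclass(frozen=True)
class IcerValue:
    """An ICER with its edge cases made explicit.

    ``value`` is None when the QALY difference is zero (undefined ratio);
    ``dominated_direction`` flags a negative QALY difference, where the
    ratio is not a meaningful willingness-to-pay quantity.
    """

    value: float | None
    dominated_direction: bool = False


def icer(delta_cost: float, delta_qalys: float) -> IcerValue:
    """Incremental cost per incremental QALY."""
    if not (math.isfinite(delta_cost) and math.isfinite(delta_qalys)):
        raise CEAError("ICER inputs must be finite")
    if delta_qalys == 0.0:
        return IcerValue(value=None)
    return IcerValue(value=delta_cost / delta_qalys, dominated_direction=delta_qalys < 0.0)


def net_monetary_benefit(cost: float, qalys: float, wtp: float) -> float:
    return wtp * qalys - cost


@dataclass
class CEARow:
    name: str
    cost: float
    qalys: float
    status: str = ON_FRONTIER
    inc_cost: float | None = None
    inc_qalys: float | None = None
    icer: float | None = None
    cost_effective: bool | None = None

    @property
    def on_frontier(self) -> bool:
        return self.status in (REFERENCE, ON_FRONTIER)


@dataclass
class CEATable:
    """Ranked strategies with dominance flags, incrementals and ICERs."""

    rows: list[CEARow]
    wtp: float | None = None
    chosen: str | None = None

    def __iter__(self):
        return iter(self.rows)

    def row(self, name: str) -> CEARow:
        for r in self.rows:
            if r.name == name:
                return r
        raise KeyError(name)

    @property
    def frontier(self) -> list[CEARow]:
        return [r for r in self.rows if r.on_frontier]

    def to_frame(self, rounded: bool = False) -> pd.DataFrame:
        """Tabular export; ``rounded`` mimics publication formatting
        (whole-dollar costs, 2-decimal QALYs, whole-dollar ICERs)."""
        recs = []
        for r in self.rows:
            icer_repr: object
            if not r.on_frontier:
                icer_repr = r.status.upper()
            elif r.icer is None:
                icer_repr = ""
            else:
                icer_repr = round(r.icer) if rounded else r.icer
            recs.append(
                {
                    "strategy": r.name,
                    "cost": round(r.cost) if rounded else r.cost,
                    "delta_cost": (
                        None if r.inc_cost is None else (round(r.inc_cost) if rounded else r.inc_cost)
                    ),
                    "qalys": round(r.qalys, 2) if rounded else r.qalys,
                    "delta_qalys": (
                        None
                        if r.inc_qalys is None
                        else (round(r.inc_qalys, 2) if rounded else r.inc_qalys)
                    ),
                    "icer": icer_repr,
                    "status": r.status,
                    "cost_effective": r.cost_effective,
                }
            )
        return pd.DataFrame.from_records(recs)


def _normalize(results: Iterable) -> list[CEARow]:
    rows = []
    for item in results:
        if isinstance(item, CEARow):
            rows.append(CEARow(item.name, item.cost, item.qalys))
        elif hasattr(item, "name") and hasattr(item, "cost") and hasattr(item, "qalys"):
            rows.append(CEARow(item.name, float(item.cost), float(item.qalys)))
        else:
            name, cost, qalys = item
            rows.append(CEARow(str(name), float(cost), float(qalys)))
    if not rows:
        raise CEAError("need at least one strategy")
    names = [r.name for r in rows]
    if len(set(names)) != len(names):
        raise CEAError(f"duplicate strategy names: {sorted(names)}")
    for r in rows:
        if not (math.isfinite(r.cost) and math.isfinite(r.qalys)):
            raise CEAError(f"non-finite outcomes for {r.name!r}")
    return rows


def dominance_frontier(results: Iterable) -> CEATable:
    """Rank by cost, eliminate dominated strategies, compute frontier ICERs.

    ``results`` is any iterable of (name, cost, qalys) triples or objects
    with those attributes.  Cost ties are broken by higher QALYs, then by
    name; an exact duplicate of an earlier (cost, QALYs) point is marked
    dominated.
    """
    rows = _normalize(results)
    rows.sort(key=lambda r: (r.cost, -r.qalys, r.name))

    # strong dominance: costlier and strictly less effective than another
    for r in rows:
        for other in rows:
            if other is r:
                continue
            if r.cost >= other.cost and r.qalys < other.qalys:
                r.status = DOMINATED
                break
    # duplicates of an earlier point are redundant
    seen: set[tuple[float, float]] = set()
    for r in rows:
        key = (r.cost, r.qalys)
        if r.status != DOMINATED:
            if key in seen:
                r.status = DOMINATED
            seen.add(key)

    # extended dominance: remove interior points whose ICER is not below the
    # next segment's, until frontier ICERs are strictly increasing
    frontier = [r for r in rows if r.status != DOMINATED]
    while len(frontier) > 2:
        icers = []
        for prev, cur in zip(frontier, frontier[1:]):
            dq = cur.qalys - prev.qalys
            icers.append(math.inf if dq == 0.0 else (cur.cost - prev.cost) / dq)
        victim = None
        for i in range(len(icers) - 1):
            if icers[i] >= icers[i + 1]:
                victim = frontier[i + 1]
                break
        if victim is None:
            break
        victim.status = EXTENDED_DOMINATED
        frontier.remove(victim)
    if len(frontier) == 2:
        # a two-point frontier with zero QALY gain is a weakly dominated tail
        if frontier[1].qalys == frontier[0].qalys:
            frontier[1].status = EXTENDED_DOMINATED
            frontier.pop()

    frontier[0].status = REFERENCE
    for prev, cur in zip(frontier, frontier[1:]):
        cur.status = ON_FRONTIER
        cur.inc_cost = cur.cost - prev.cost
        cur.inc_qalys = cur.qalys - prev.qalys
        cur.icer = icer(cur.inc_cost, cur.inc_qalys).value
    return CEATable(rows=rows)


def wtp_verdict(table: CEATable, wtp: float) -> CEATable:
    """Flag cost-effective frontier rows and pick the chosen strategy.

    The chosen strategy is the most effective frontier row whose sequential
    ICER does not exceed ``wtp`` (the reference row qualifies by
    definition); on the frontier this coincides with NMB maximization.
    """
    if wtp < 0.0:
        raise CEAError("wtp must be >= 0")
    chosen: CEARow | None = None
    for r in table.rows:
        if not r.on_frontier:
            r.cost_effective = False
            continue
        r.cost_effective = r.icer is None or r.icer <= wtp
        if r.cost_effective:
            chosen = r  # frontier rows are in increasing-QALY order
    table.wtp = wtp
    table.chosen = chosen.name if chosen is not None else None
    return table
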
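"""Usage, outcome, toolbox, and group reports.

Counts are taken over retained (non-excluded) observations only, and
percentages are reported to one decimal with half-up rounding, as clinicians
read them.  The outcome report's zone-day counts partition the enrollment
period exactly: in + below + above + no-data = days enrolled.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .activity import StepRecord, collapse_step_records
from .adherence import AdherenceZone
from .intervention import ToolboxEpisode
from .units import kg_to_lb
from .weight_stream import WeightSeries

__all__ = [
    "UsageReport",
    "OutcomeReport",
    "ToolboxReport",
    "ViewEvent",
    "usage_report",
    "outcome_report",
    "toolbox_report",
    "group_report",
    "round_pct",
    "write_report_json",
    "write_report_csv",
]


def round_pct(x: float, ndigits: int = 1) -> float:
    """Half-up rounding (Python's round() is banker's rounding)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ViewEvent:
    """A graph or tip view emitted by the (out-of-scope) UI layer."""

    day: int
    kind: str                 # weight_graph | step_graph | tip
    tip_id: str | None = None


@dataclass
class UsageReport:
    client_id: str
    days_enrolled: int
    days_with_weight: int
    days_with_steps: int
    pct_days_with_weight: float
    pct_days_with_steps: float
    weight_graph_views: int
    step_graph_views: int
    tips_viewed: dict = field(default_factory=dict)   # tip id -> view count

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class OutcomeReport:
    client_id: str
    days_enrolled: int
    first_weight_lb: float
    last_weight_lb: float
    change_lb: float
    change_pct: float
    target_weight_lb: float          # predicted weight at the end of the period
    target_lower_lb: float
    target_upper_lb: float
    days_in_zone: int
    days_below_zone: int
    days_above_zone: int
    days_no_data: int
    pct_in_zone: float
    pct_below_zone: float
    pct_above_zone: float

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class ToolboxReport:
    client_id: str
    strategy_counts: dict                 # strategy id -> deployments
    episodes: list = field(default_factory=list)
    # per episode: strategy, start/end day, status, weight change lb, mean steps

    def to_dict(self) -> dict:
        return {"client_id": self.client_id,
                "strategy_counts": self.strategy_counts,
                "episodes": self.episodes}


# ---------------------------------------------------------------------------

def _period_days(period: tuple[int, int]) -> list[int]:
    """Inclusive day range; enrollment day counts."""
    a, b = period
    if b < a:
        return []
    return list(range(a, b + 1))


def usage_report(series: WeightSeries,
                 steps: Iterable[StepRecord],
                 view_events: Iterable[ViewEvent],
                 period: tuple[int, int],
                 client_id: str | None = None) -> UsageReport:
    """Telemetry usage over ``period`` (inclusive day offsets)."""
    days = _period_days(period)
    n = len(days)
    dayset = set(days)
    weight_days = {o.day for o in series.retained() if o.day in dayset}
    step_by_date = collapse_step_records(steps)
    base = series.baseline_date
    step_days = set()
    for d in step_by_date:
        off = (d - base).days if base is not None else None
        if off in dayset:
            step_days.add(off)
    views = [v for v in view_events if v.day in dayset]
    tips: dict[str, int] = {}
    for v in views:
        if v.kind == "tip" and v.tip_id is not None:
            tips[v.tip_id] = tips.get(v.tip_id, 0) + 1
    return UsageReport(
        client_id=client_id or series.client_id,
        days_enrolled=n,
        days_with_weight=len(weight_days),
        days_with_steps=len(step_days),
        pct_days_with_weight=round_pct(100.0 * len(weight_days) / n) if n else 0.0,
        pct_days_with_steps=round_pct(100.0 * len(step_days) / n) if n else 0.0,
        weight_graph_views=sum(v.kind == "weight_graph" for v in views),
        step_graph_views=sum(v.kind == "step_graph" for v in views),
        tips_viewed=tips)


def outcome_report(series: WeightSeries,
                   zone: AdherenceZone,
                   period: tuple[int, int],
                   client_id: str | None = None) -> OutcomeReport:
    """Weight change and zone-day partition over ``period``."""
    days = _period_days(period)
    if not days:
        raise ValueError("empty period")
    kept = [o for o in series.retained() if period[0] <= o.day <= period[1]]
    if not kept:
        raise ValueError("no retained weights in period")
    first, last = kept[0], kept[-1]
    in_z = below = above = no_data = 0
    for d in days:
        w = series.weight_on(d)
        if w is None or d >= len(zone):
            no_data += 1
        elif w > zone.upper_kg[d]:
            above += 1
        elif w < zone.lower_kg[d]:
            below += 1
        else:
            in_z += 1
    n = len(days)
    end = min(period[1], len(zone) - 1)
    change_lb = last.weight_lb - first.weight_lb
    return OutcomeReport(
        client_id=client_id or series.client_id,
        days_enrolled=n,
        first_weight_lb=round(first.weight_lb, 1),
        last_weight_lb=round(last.weight_lb, 1),
        change_lb=round(change_lb, 1),
        change_pct=round_pct(100.0 * change_lb / first.weight_lb),
        target_weight_lb=round(kg_to_lb(float(zone.predicted_kg[end])), 1),
        target_lower_lb=round(kg_to_lb(float(zone.lower_kg[end])), 1),
        target_upper_lb=round(kg_to_lb(float(zone.upper_kg[end])), 1),
        days_in_zone=in_z, days_below_zone=below, days_above_zone=above,
        days_no_data=no_data,
        pct_in_zone=round_pct(100.0 * in_z / n),
        pct_below_zone=round_pct(100.0 * below / n),
        pct_above_zone=round_pct(100.0 * above / n))


def toolbox_report(episodes: Sequence[ToolboxEpisode],
                   series: WeightSeries,
                   steps: Iterable[StepRecord],
                   client_id: str | None = None) -> ToolboxReport:
    """Per-strategy usage with weight change and mean daily steps per episode."""
    counts: dict[str, int] = {}
    step_by_date = collapse_step_records(steps)
    base = series.baseline_date
    step_by_day = {(d - base).days: s for d, s in step_by_date.items()} \
        if base is not None else {}
    rows = []
    for ep in episodes:
        counts[ep.strategy_id] = counts.get(ep.strategy_id, 0) + 1
        end = ep.end_day if ep.end_day is not None else ep.start_day + ep.window_days
        kept = [o for o in series.retained() if ep.start_day <= o.day <= end]
        change = round(kept[-1].weight_lb - kept[0].weight_lb, 1) if len(kept) >= 2 else None
        ep_steps = [step_by_day[d] for d in range(ep.start_day, end + 1)
                    if d in step_by_day]
        rows.append({
            "strategy": ep.strategy_id, "start_day": ep.start_day, "end_day": end,
            "status": ep.status, "weight_change_lb": change,
            "mean_daily_steps": round(float(np.mean(ep_steps)), 1) if ep_steps else None,
        })
    return ToolboxReport(client_id=client_id or series.client_id,
                         strategy_counts=counts, episodes=rows)


def group_report(outcomes: Sequence[OutcomeReport]) -> pd.DataFrame:
    """Per-client rows plus mean/median aggregate rows over the numeric columns."""
    if not outcomes:
        raise ValueError("need at least one client")
    df = pd.DataFrame([o.to_dict() for o in outcomes])
    numeric = df.select_dtypes("number").columns
    agg = pd.DataFrame([
        {"client_id": "MEAN", **{c: round(float(df[c].mean()), 2) for c in numeric}},
        {"client_id": "MEDIAN", **{c: round(float(df[c].median()), 2) for c in numeric}},
    ])
    return pd.concat([df, agg], ignore_index=True)


def write_report_json(report, path) -> None:
    with open(path, "w") as fh:
        json.dump(report.to_dict(), fh, indent=2)


def write_report_csv(report, path) -> None:
    if isinstance(report, pd.DataFrame):
        report.to_csv(path, index=False)
    else:
        pd.json_normalize(report.to_dict()).to_csv(path, index=False)
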
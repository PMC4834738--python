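"""Step goals and daily step adherence.

The activity goal currency is steps/day, never kcal: consumer activity
monitors estimate caloric expenditure poorly but count steps well.  The goal
is baseline steps plus a 3000-4000 step/day increment (so a typical 4000
step/day baseline becomes 7000-8000), consistent with 150 min/week of
moderate activity.

Step devices sync cumulative daily totals more than once a day, so same-day
records collapse to the maximum (the latest total supersedes), unlike
weights where the first of the day is kept.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from datetime import date as Date, timedelta
from typing import Iterable

import pandas as pd

__all__ = [
    "StepRecord",
    "ActivityGoal",
    "StepAdherence",
    "compute_goal",
    "collapse_step_records",
    "step_adherence",
    "read_steps_csv",
    "plot_steps",
]

DEFAULT_INCREMENT_RANGE = (3000, 4000)   # steps/day above baseline


@dataclass(frozen=True)
class StepRecord:
    date: Date
    steps: int
    source: str = "device"     # "device" | "manual"

    def __post_init__(self) -> None:
        if self.steps < 0:
            raise ValueError("steps must be >= 0")
        if self.source not in ("device", "manual"):
            raise ValueError(f"unknown source {self.source!r}")


@dataclass(frozen=True)
class ActivityGoal:
    baseline_steps: int
    increment: int
    goal: int

    def __post_init__(self) -> None:
        assert self.goal == self.baseline_steps + self.increment


def compute_goal(baseline_steps: int, increment: int = 3500) -> ActivityGoal:
    """Daily step goal = baseline + increment (default mid-range 3500)."""
    if baseline_steps < 0 or increment < 0:
        raise ValueError("baseline and increment must be >= 0")
    return ActivityGoal(baseline_steps=int(baseline_steps), increment=int(increment),
                        goal=int(baseline_steps) + int(increment))


class StepStatus(enum.Enum):
    MET = "met"
    NOT_MET = "not_met"
    MISSING = "missing"


@dataclass(frozen=True)
class StepAdherence:
    date: Date
    steps: int | None
    goal: int
    status: StepStatus


def collapse_step_records(records: Iterable[StepRecord]) -> dict[Date, int]:
    """One retained count per date: the max over same-day syncs."""
    by_date: dict[Date, int] = {}
    for r in records:
        if r.date not in by_date or r.steps > by_date[r.date]:
            by_date[r.date] = r.steps
    return by_date


def step_adherence(records: Iterable[StepRecord],
                   goal: ActivityGoal,
                   dates: Iterable[Date] | None = None) -> list[StepAdherence]:
    """Per-day goal adherence: met iff retained steps >= goal.

    ``dates`` selects the evaluation period (default: the span of the
    records); days without a record are flagged missing.
    """
    by_date = collapse_step_records(records)
    if dates is None:
        if not by_date:
            return []
        lo, hi = min(by_date), max(by_date)
        dates = [lo + timedelta(days=i) for i in range((hi - lo).days + 1)]
    out = []
    for d in dates:
        steps = by_date.get(d)
        if steps is None:
            status = StepStatus.MISSING
        elif steps >= goal.goal:
            status = StepStatus.MET
        else:
            status = StepStatus.NOT_MET
        out.append(StepAdherence(date=d, steps=steps, goal=goal.goal, status=status))
    return out


def read_steps_csv(path) -> list[StepRecord]:
    """CSV columns: date, steps, source."""
    df = pd.read_csv(path, dtype=str)
    records = []
    for _, row in df.iterrows():
        records.append(StepRecord(date=Date.fromisoformat(str(row["date"])),
                                  steps=int(float(row["steps"])),
                                  source=str(row.get("source", "device"))))
    return records


def plot_steps(adherence: list[StepAdherence], path,
               title: str = "Daily steps vs. goal") -> None:
    """Bar plot of daily steps with the goal line, saved to PNG/SVG."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 3.5))
    days = range(len(adherence))
    steps = [a.steps or 0 for a in adherence]
    colors = ["seagreen" if a.status is StepStatus.MET else "lightgray"
              for a in adherence]
    ax.bar(days, steps, color=colors)
    if adherence:
        ax.axhline(adherence[0].goal, color="black", lw=1, label="goal")
        ax.legend()
    ax.set_xlabel("day")
    ax.set_ylabel("steps")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
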
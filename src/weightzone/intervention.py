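"""Escalating intervention toolbox, tip scheduling, and automated feedback.

When a client's weight is repeatedly out of the zone, strategies are drawn
from a clinic-configured toolbox, least intense (and usually least costly)
first.  Each deployment is an *episode* evaluated after a fixed window
(default 14 days): success means the client's weight is back inside the zone
on the last episode day, or is falling at least as fast as the prediction
over the episode.  On failure the next-ranked strategy is deployed; after a
success the escalation resets, so a later lapse starts again from the
cheapest remedy.  An exhausted catalogue signals a clinician referral.

Health-education tips follow a per-phase cadence (typically weekly at
program onset, tapering to biweekly and then monthly), with view and
acknowledgment timestamps tracked per tip.

Automated feedback is template-driven and fully deterministic: a GREEN day
earns a congratulatory message plus a tip, a fired k-of-n trigger earns a
toolbox recommendation, and a streak of missing weigh-ins (default 3 days)
earns a reminder.  Every event records the trigger that produced it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Iterable, Sequence

import numpy as np
import yaml

from .adherence import AdherenceZone, Flag, trailing_slope
from .weight_stream import WeightSeries

__all__ = [
    "ToolboxStrategy",
    "ToolboxEpisode",
    "TipPhase",
    "TipSchedule",
    "FeedbackEvent",
    "EscalationExhausted",
    "DEFAULT_CATALOGUE",
    "next_strategy",
    "evaluate_episode",
    "schedule_tips",
    "generate_feedback",
    "load_catalogue",
    "write_events_jsonl",
    "read_events_jsonl",
]


class EscalationExhausted(Exception):
    """Every catalogue strategy failed in the current escalation run."""


@dataclass(frozen=True)
class ToolboxStrategy:
    id: str
    label: str
    intensity_rank: int     # 1 = least intense
    cost_tier: str = "low"

    def __post_init__(self) -> None:
        if self.intensity_rank < 1:
            raise ValueError("intensity_rank must be >= 1")


#: Example clinic catalogue, least-to-most intense.
DEFAULT_CATALOGUE: tuple[ToolboxStrategy, ...] = (
    ToolboxStrategy("self_monitoring", "Self-monitor food intake", 1, "low"),
    ToolboxStrategy("increase_activity", "Increase activity or exercise", 2, "low"),
    ToolboxStrategy("portion_controlled", "Use portion-controlled foods", 3, "medium"),
    ToolboxStrategy("contact_frequency", "Increase contact with clinician", 4, "high"),
)


@dataclass
class ToolboxEpisode:
    """One strategy deployment with its evaluation outcome."""

    strategy_id: str
    start_day: int
    window_days: int = 14
    status: str = "active"          # active | success | failure
    end_day: int | None = None
    slope_kg_d: float | None = None
    extended: bool = False

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ToolboxEpisode":
        return cls(**d)


def _validate_catalogue(catalogue: Sequence[ToolboxStrategy]) -> list[ToolboxStrategy]:
    ranks = [s.intensity_rank for s in catalogue]
    if len(set(ranks)) != len(ranks):
        raise ValueError("intensity_rank must be unique within a catalogue")
    return sorted(catalogue, key=lambda s: s.intensity_rank)


def next_strategy(catalogue: Sequence[ToolboxStrategy],
                  history: Sequence[ToolboxEpisode]) -> ToolboxStrategy:
    """Lowest-rank strategy not already attempted-and-failed in the current
    escalation run (the run restarts after the most recent success)."""
    ordered = _validate_catalogue(catalogue)
    run: list[ToolboxEpisode] = []
    for ep in history:
        if ep.status == "success":
            run = []
        elif ep.status == "failure":
            run.append(ep)
    failed_ids = {ep.strategy_id for ep in run}
    for s in ordered:
        if s.id not in failed_ids:
            return s
    raise EscalationExhausted(
        "all strategies failed this run; refer the client to a clinician")


def evaluate_episode(episode: ToolboxEpisode,
                     series: WeightSeries,
                     zone: AdherenceZone,
                     min_points: int = 3) -> ToolboxEpisode:
    """Evaluate an active episode once its window has elapsed.

    Success iff the retained weight on the last episode day is back inside
    the zone, or the least-squares slope over the episode is at most the mean
    predicted slope over the same days.  With fewer than ``min_points``
    retained weights the evaluation is deferred and the window extended.
    """
    if episode.status != "active":
        return episode
    end = episode.start_day + episode.window_days
    days, weights = series.days_weights()
    days_a = np.asarray(days)
    mask = (days_a >= episode.start_day) & (days_a <= end)
    n = int(mask.sum())
    if n < min_points:
        episode.extended = True
        episode.window_days += 7
        return episode

    slope, _, _ = trailing_slope(days, weights, end, window=episode.window_days + 1)
    episode.slope_kg_d = slope
    pred_slope = (zone.predicted_kg[min(end, len(zone) - 1)]
                  - zone.predicted_kg[episode.start_day]) / episode.window_days

    w_end = series.weight_on(end)
    back_in_zone = (w_end is not None and end < len(zone)
                    and zone.contains(end, w_end))
    episode.status = "success" if (back_in_zone or slope <= pred_slope) else "failure"
    episode.end_day = end
    return episode


# ---------------------------------------------------------------------------
# Tip scheduling
# ---------------------------------------------------------------------------

CADENCE_DAYS = {"weekly": 7, "biweekly": 14, "monthly": 28}


@dataclass(frozen=True)
class TipPhase:
    length_days: int
    cadence: str          # weekly | biweekly | monthly

    def __post_init__(self) -> None:
        if self.length_days < 0:
            raise ValueError("phase length must be >= 0")
        if self.cadence not in CADENCE_DAYS:
            raise ValueError(f"unknown cadence {self.cadence!r}")


DEFAULT_TIP_PHASES: tuple[TipPhase, ...] = (
    TipPhase(8 * 7, "weekly"),
    TipPhase(8 * 7, "biweekly"),
    TipPhase(8 * 7, "monthly"),
)


@dataclass
class TipSchedule:
    program_days: int
    phases: tuple[TipPhase, ...]
    delivery_days: list[int] = field(default_factory=list)
    viewed: dict[int, int] = field(default_factory=dict)        # day -> view day
    acknowledged: dict[int, int] = field(default_factory=dict)

    def mark_viewed(self, delivery_day: int, on_day: int) -> None:
        if delivery_day not in self.delivery_days:
            raise KeyError(f"no tip delivered on day {delivery_day}")
        self.viewed[delivery_day] = on_day

    def mark_acknowledged(self, delivery_day: int, on_day: int) -> None:
        if delivery_day not in self.delivery_days:
            raise KeyError(f"no tip delivered on day {delivery_day}")
        self.acknowledged[delivery_day] = on_day


def schedule_tips(program_days: int,
                  phases: Sequence[TipPhase] = DEFAULT_TIP_PHASES) -> TipSchedule:
    """Delivery days per phase cadence; deliveries start on each phase's first
    day and repeat at the cadence interval while inside both the phase and
    the program."""
    if program_days < 0:
        raise ValueError("program length must be >= 0")
    freq = [CADENCE_DAYS[p.cadence] for p in phases]
    if any(b < a for a, b in zip(freq, freq[1:])):
        raise ValueError("cadence must not speed up in later phases")
    days: list[int] = []
    start = 0
    for phase in phases:
        interval = CADENCE_DAYS[phase.cadence]
        end = min(start + phase.length_days, program_days)
        d = start
        while d < end:
            days.append(d)
            d += interval
        start += phase.length_days
        if start >= program_days:
            break
    return TipSchedule(program_days=program_days, phases=tuple(phases),
                       delivery_days=days)


# ---------------------------------------------------------------------------
# Feedback events
# ---------------------------------------------------------------------------

DEFAULT_TEMPLATES: dict[str, tuple[str, ...]] = {
    "congratulatory": (
        "Great work - your weight is right on track today.",
        "You're inside your zone. Keep doing what you're doing!",
        "Another on-track day. Consistency is what gets results.",
    ),
    "tip": (
        "Tip: plan tomorrow's meals tonight to stay ahead of hunger.",
        "Tip: a short walk after meals adds up over the week.",
        "Tip: pre-portioned snacks make sticking to your target easier.",
    ),
    "toolbox_recommendation": (
        "Your weight has been above the zone for several days. "
        "Let's pick a strategy from your toolbox: {strategy}.",
    ),
    "reminder": (
        "We haven't received a weight in {days} days - please step on the scale.",
    ),
    "clinician_referral": (
        "All toolbox strategies have been tried this round. "
        "Please schedule a visit with your clinician.",
    ),
}


@dataclass(frozen=True)
class FeedbackEvent:
    day: int
    kind: str        # congratulatory | tip | toolbox_recommendation | reminder | clinician_custom
    payload: str
    trigger: str     # provenance: the flag, schedule, or rule that produced it

    def to_dict(self) -> dict:
        return asdict(self)


def _pick(templates: Sequence[str], day: int) -> str:
    return templates[day % len(templates)]


def generate_feedback(flag: Flag,
                      day: int,
                      trigger_fired: bool = False,
                      no_data_streak: int = 0,
                      reminder_after: int = 3,
                      strategy: ToolboxStrategy | None = None,
                      templates: dict[str, tuple[str, ...]] | None = None
                      ) -> list[FeedbackEvent]:
    """Deterministic, template-driven events for one client-day.

    Priority: a fired out-of-zone trigger recommends a toolbox strategy; a
    missing-weight streak of ``reminder_after`` or more days sends a
    reminder; a GREEN day sends a congratulatory message plus a tip.  Other
    flags produce no automated event (the graph itself is the feedback).
    """
    templates = templates or DEFAULT_TEMPLATES
    events: list[FeedbackEvent] = []
    if trigger_fired:
        label = strategy.label if strategy is not None else "a toolbox strategy"
        events.append(FeedbackEvent(
            day=day, kind="toolbox_recommendation",
            payload=_pick(templates["toolbox_recommendation"], day).format(strategy=label),
            trigger="k_of_n_out_of_zone"))
        return events
    if no_data_streak >= reminder_after:
        events.append(FeedbackEvent(
            day=day, kind="reminder",
            payload=_pick(templates["reminder"], day).format(days=no_data_streak),
            trigger=f"no_data_streak:{no_data_streak}"))
        return events
    if flag is Flag.GREEN:
        events.append(FeedbackEvent(day=day, kind="congratulatory",
                                    payload=_pick(templates["congratulatory"], day),
                                    trigger="flag:green"))
        events.append(FeedbackEvent(day=day, kind="tip",
                                    payload=_pick(templates["tip"], day),
                                    trigger="flag:green"))
    return events


# ---------------------------------------------------------------------------
# Config and audit log I/O
# ---------------------------------------------------------------------------

def load_catalogue(path) -> list[ToolboxStrategy]:
    """Load a toolbox catalogue from YAML: a list of {id, label,
    intensity_rank, cost_tier} mappings."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return _validate_catalogue([ToolboxStrategy(**item) for item in raw])


def write_events_jsonl(events: Iterable[FeedbackEvent], path) -> None:
    with open(path, "w") as fh:
        for e in events:
            fh.write(json.dumps(e.to_dict()) + "\n")


def read_events_jsonl(path) -> list[FeedbackEvent]:
    events = []
    with open(path) as fh:
        for line in fh:
            if line.strip():
                events.append(FeedbackEvent(**json.loads(line)))
    return events
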
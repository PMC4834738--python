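"""End-to-end daily update loop: the "virtual clinic".

Replays a client's telemetry day by day exactly as the live system would see
it: clean the weight stream, build the zone once from the prescription, then
for each enrolled day classify the flag, evaluate the k-of-n trigger, manage
toolbox episodes (open on trigger, evaluate after the episode window), and
emit deterministic feedback events.  The same history always produces the
same event stream.
"""

from __future__ import annotations

from dataclasses import dataclass

from .activity import StepRecord
from .adherence import (AdherenceZone, Flag, FlagState, build_zone,
                        classify_flag, trigger_check)
from .config import ProgramConfig
from .energy_model import ClientProfile, EnergyPrescription, predict_trajectory
from .intervention import (EscalationExhausted, FeedbackEvent, ToolboxEpisode,
                           evaluate_episode, generate_feedback, next_strategy,
                           schedule_tips)
from .reports import (OutcomeReport, UsageReport, ToolboxReport, ViewEvent,
                      outcome_report, toolbox_report, usage_report)
from .weight_stream import WeightSeries

__all__ = ["RunResult", "run_daily_loop"]


@dataclass
class RunResult:
    zone: AdherenceZone
    flags: list[FlagState]
    events: list[FeedbackEvent]
    episodes: list[ToolboxEpisode]
    usage: UsageReport
    outcome: OutcomeReport
    toolbox: ToolboxReport


def run_daily_loop(profile: ClientProfile,
                   rx: EnergyPrescription,
                   series: WeightSeries,
                   steps: list[StepRecord] | None = None,
                   view_events: list[ViewEvent] | None = None,
                   config: ProgramConfig | None = None) -> RunResult:
    """Replay the program over days 0..horizon and return every artifact."""
    config = config or ProgramConfig()
    steps = steps or []
    view_events = view_events or []
    params = config.params()
    zone = build_zone(predict_trajectory(profile, rx, params), config.band_spec())
    catalogue = config.catalogue()
    tip_days = set(schedule_tips(rx.horizon_days, config.phases()).delivery_days)

    trigger_flags = frozenset({Flag.RED, Flag.RED_GREEN}) \
        if config.trigger.include_red_green else frozenset({Flag.RED})

    flags: list[FlagState] = []
    events: list[FeedbackEvent] = []
    episodes: list[ToolboxEpisode] = []
    no_data_streak = 0
    fc = config.flags

    for day in range(rx.horizon_days + 1):
        flag = classify_flag(series, zone, day,
                             slope_window=fc.slope_window,
                             min_slope_points=fc.min_slope_points,
                             plateau_z=fc.plateau_z,
                             upper_edge_fraction=fc.upper_edge_fraction)
        flags.append(flag)
        no_data_streak = no_data_streak + 1 if flag.flag is Flag.NO_DATA else 0

        # evaluate any active episode whose window has elapsed
        for ep in episodes:
            if ep.status == "active" and day >= ep.start_day + ep.window_days:
                evaluate_episode(ep, series, zone)

        fired = trigger_check(flags, k=config.trigger.k, n=config.trigger.n,
                              trigger_flags=trigger_flags,
                              no_data_counts_in_n=config.trigger.no_data_counts_in_n,
                              days_since_enrollment=day + 1)
        active = any(ep.status == "active" for ep in episodes)
        strategy = None
        opened = False
        if fired and not active:
            try:
                strategy = next_strategy(catalogue, episodes)
                episodes.append(ToolboxEpisode(
                    strategy_id=strategy.id, start_day=day,
                    window_days=config.episode_window_days))
                opened = True
            except EscalationExhausted:
                events.append(FeedbackEvent(
                    day=day, kind="clinician_custom",
                    payload="All toolbox strategies exhausted; clinician referral.",
                    trigger="escalation_exhausted"))

        day_events = generate_feedback(
            flag.flag, day, trigger_fired=opened,
            no_data_streak=no_data_streak,
            reminder_after=config.reminder_after_missing_days,
            strategy=strategy)
        # only GREEN days on the tip schedule actually carry the tip payload
        day_events = [e for e in day_events if e.kind != "tip" or day in tip_days]
        events.extend(day_events)

    period = (0, rx.horizon_days)
    usage = usage_report(series, steps, view_events, period)
    outcome = outcome_report(series, zone, period)
    toolbox = toolbox_report(episodes, series, steps)
    return RunResult(zone=zone, flags=flags, events=events, episodes=episodes,
                     usage=usage, outcome=outcome, toolbox=toolbox)
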
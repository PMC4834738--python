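"""Synthetic client telemetry generator.

Emulates the daily data stream of a weight-management client so every other
module can be exercised with no external data.  The client's *true* weight
follows the energy-balance model under an effective intake of
``maintenance + adherence x delta`` (plus any configured lapse excess);
what the scale reports adds Gaussian day-to-day noise (hydration, clothing;
default sd 0.3 kg).  Days go missing at a configured probability, and
occasionally a *foreign* weight — someone else stepping on the scale — is
emitted instead, offset by at least 6 % from the true weight so the ±5 %
cleaning filter has unambiguous ground truth to catch.

Everything is driven by one integer seed and is byte-level reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date as Date, datetime, time, timedelta

import numpy as np

from .activity import StepRecord
from .energy_model import (ClientProfile, EnergyPrescription, ModelParams,
                           WeightTrajectory, simulate_weights)
from .reports import ViewEvent
from .weight_stream import RawWeightRecord

__all__ = ["LapseEpisode", "BehaviorProfile", "SimulatedClient", "simulate_client"]


@dataclass(frozen=True)
class LapseEpisode:
    """A stretch of days where the client eats above the effective intake."""

    start_day: int
    length_days: int
    intake_excess_kcal: float     # added to the daily effective intake


@dataclass(frozen=True)
class BehaviorProfile:
    """How faithfully (and how noisily) a synthetic client behaves.

    ``adherence`` is the fraction of the prescribed intake change actually
    achieved: 1.0 = perfectly adherent, 0.0 = stays at maintenance.
    """

    adherence: float = 1.0
    weight_noise_sd: float = 0.3          # kg
    missing_prob: float = 0.1
    foreign_prob: float = 0.02
    foreign_min_offset: float = 0.06      # fraction of true weight; >= the 5% filter
    foreign_max_offset: float = 0.12
    duplicate_prob: float = 0.05          # chance of a second same-day weigh-in
    step_sd: float = 1500.0
    step_increment: float = 3500.0        # goal increment the client works toward
    lapses: tuple[LapseEpisode, ...] = ()

    def __post_init__(self) -> None:
        for name in ("adherence", "missing_prob", "foreign_prob", "duplicate_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.weight_noise_sd < 0 or self.step_sd < 0:
            raise ValueError("noise sd must be >= 0")
        if not 0.05 < self.foreign_min_offset <= self.foreign_max_offset:
            raise ValueError("foreign offsets must exceed the 5% filter and be ordered")


@dataclass
class SimulatedClient:
    profile: ClientProfile
    prescription: EnergyPrescription
    behavior: BehaviorProfile
    seed: int
    start_date: Date
    true_trajectory: WeightTrajectory
    weight_records: list[RawWeightRecord] = field(default_factory=list)
    step_records: list[StepRecord] = field(default_factory=list)
    view_events: list[ViewEvent] = field(default_factory=list)
    foreign_days: list[int] = field(default_factory=list)
    missing_days: list[int] = field(default_factory=list)


def effective_intake_schedule(rx: EnergyPrescription,
                              behavior: BehaviorProfile) -> np.ndarray:
    """Per-day intake actually consumed: maintenance + adherence x delta,
    plus lapse excess on lapse days."""
    intake = np.full(rx.horizon_days,
                     rx.maintenance_intake + behavior.adherence * rx.delta_intake)
    for lapse in behavior.lapses:
        a = max(0, lapse.start_day)
        b = min(rx.horizon_days, lapse.start_day + lapse.length_days)
        intake[a:b] += lapse.intake_excess_kcal
    return intake


def simulate_client(profile: ClientProfile,
                    rx: EnergyPrescription,
                    behavior: BehaviorProfile | None = None,
                    seed: int = 0,
                    start_date: Date = Date(2024, 1, 1),
                    params: ModelParams | None = None) -> SimulatedClient:
    """Generate raw weight records, step records, and view events for one
    client over the prescription horizon (days 0..horizon inclusive)."""
    behavior = behavior or BehaviorProfile()
    params = params or ModelParams()
    rng = np.random.default_rng(seed)

    days = rx.horizon_days
    true = simulate_weights(profile, effective_intake_schedule(rx, behavior),
                            days, params) if days > 0 else \
        simulate_weights(profile, rx.maintenance_intake, 0, params)

    client = SimulatedClient(profile=profile, prescription=rx, behavior=behavior,
                             seed=seed, start_date=start_date, true_trajectory=true)

    baseline_steps = profile.baseline_steps if profile.baseline_steps is not None else 4000
    step_target = baseline_steps + behavior.adherence * behavior.step_increment

    for d in range(days + 1):
        date_d = start_date + timedelta(days=d)
        # ---- weight record(s) ----
        if d == 0 or rng.random() >= behavior.missing_prob:
            minute = int(rng.integers(0, 60))
            ts = datetime.combine(date_d, time(7, minute))
            w_true = float(true.weight_kg[d])
            if d > 0 and rng.random() < behavior.foreign_prob:
                mag = rng.uniform(behavior.foreign_min_offset, behavior.foreign_max_offset)
                sign = 1.0 if rng.random() < 0.5 else -1.0
                w_obs = w_true * (1.0 + sign * mag)
                client.foreign_days.append(d)
            else:
                w_obs = w_true + rng.normal(0.0, behavior.weight_noise_sd)
            client.weight_records.append(RawWeightRecord(ts, max(w_obs, 1.0), "device"))
            if rng.random() < behavior.duplicate_prob:
                ts2 = datetime.combine(date_d, time(20, int(rng.integers(0, 60))))
                w2 = w_true + rng.normal(0.0, behavior.weight_noise_sd) + 0.4
                client.weight_records.append(RawWeightRecord(ts2, max(w2, 1.0), "device"))
        else:
            client.missing_days.append(d)

        # ---- step records: midday partial sync then end-of-day total ----
        total = max(0, int(round(rng.normal(step_target, behavior.step_sd))))
        partial = int(total * rng.uniform(0.3, 0.7))
        client.step_records.append(StepRecord(date_d, partial, "device"))
        client.step_records.append(StepRecord(date_d, total, "device"))

        # ---- app usage ----
        if rng.random() < 0.5:
            client.view_events.append(ViewEvent(day=d, kind="weight_graph"))
        if rng.random() < 0.3:
            client.view_events.append(ViewEvent(day=d, kind="step_graph"))
        if d % 7 == 0 and rng.random() < 0.8:
            client.view_events.append(ViewEvent(day=d, kind="tip", tip_id=f"tip_{d // 7}"))

    return client
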
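"""Weight telemetry ingestion and cleaning.

Raw records arrive timestamped from a connected bathroom scale, from the
client by hand, or from a clinician.  Two rules turn them into the
one-observation-per-day series that everything downstream consumes:

* **first-of-day** — if a client weighs several times on one date, only the
  earliest record is analysed; the rest are kept but marked excluded.
* **±5 % filter** — scanning retained observations in date order, a weight
  deviating by strictly more than 5 % from the last *retained* weight is
  assumed not to come from the client (someone else on the scale) and is
  excluded.  An excluded weight never becomes the reference, so a run of
  foreign weights cannot poison later comparisons.  A deviation of exactly
  5 % is retained.

Excluded records are never dropped — they carry their exclusion reason so
the cleaning is fully auditable.  Both rules apply identically to device and
manual entries; first-of-day collapsing can be disabled for programs that
want to study intraday fluctuation.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, replace
from datetime import date, datetime, timedelta, timezone
from typing import Iterable

import pandas as pd

from .units import lb_to_kg, kg_to_lb

__all__ = [
    "RawWeightRecord",
    "WeightObservation",
    "WeightSeries",
    "ingest",
    "filter_outliers",
    "clean",
    "read_weight_csv",
    "read_scale_json",
    "write_series_csv",
    "read_series_csv",
]

log = logging.getLogger(__name__)

SOURCES = ("device", "client_manual", "clinician_manual")

DUPLICATE_SAME_DAY = "duplicate_same_day"
OUTLIER_GT_5PCT = "outlier_gt_5pct"


@dataclass(frozen=True)
class RawWeightRecord:
    timestamp: datetime
    weight_kg: float
    source: str = "device"

    def __post_init__(self) -> None:
        if not self.weight_kg > 0:
            raise ValueError("weight must be positive")
        if self.source not in SOURCES:
            raise ValueError(f"unknown source {self.source!r}")


@dataclass(frozen=True)
class WeightObservation:
    day: int                    # offset from the series baseline date
    date: date
    timestamp: datetime
    weight_kg: float
    source: str
    excluded: str | None = None   # None, "duplicate_same_day", "outlier_gt_5pct"

    @property
    def weight_lb(self) -> float:
        return kg_to_lb(self.weight_kg)

    @property
    def retained(self) -> bool:
        return self.excluded is None


@dataclass
class WeightSeries:
    """Cleaned per-day weight observations for one client."""

    observations: list[WeightObservation]
    client_id: str = "client"
    baseline_date: date | None = None

    def __post_init__(self) -> None:
        # strictly increasing timestamps; dates strictly increase too unless
        # first-of-day collapsing was disabled (several retained per date)
        kept = [o for o in self.observations if o.retained]
        if any(b.timestamp <= a.timestamp for a, b in zip(kept, kept[1:])):
            raise ValueError("retained observations must be strictly ordered in time")

    def retained(self) -> list[WeightObservation]:
        return [o for o in self.observations if o.retained]

    def excluded(self) -> list[WeightObservation]:
        return [o for o in self.observations if not o.retained]

    def days_weights(self) -> tuple[list[int], list[float]]:
        """(day offsets, weights in kg) of retained observations."""
        kept = self.retained()
        return [o.day for o in kept], [o.weight_kg for o in kept]

    def weight_on(self, day: int) -> float | None:
        for o in self.observations:
            if o.retained and o.day == day:
                return o.weight_kg
        return None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "day": o.day, "date": o.date.isoformat(),
            "timestamp": o.timestamp.isoformat(),
            "weight_kg": round(o.weight_kg, 4),
            "weight_lb": round(o.weight_lb, 4),
            "source": o.source,
            "excluded": o.excluded or "",
        } for o in self.observations])

    def __len__(self) -> int:
        return len(self.observations)


# ---------------------------------------------------------------------------
# Cleaning rules
# ---------------------------------------------------------------------------

def ingest(records: Iterable[RawWeightRecord],
           client_id: str = "client",
           baseline_date: date | None = None,
           collapse_first_of_day: bool = True) -> WeightSeries:
    """Apply the first-of-day rule and assemble a dated series.

    Per calendar date the earliest-timestamp record is retained; later
    same-day records are marked ``duplicate_same_day``.  The baseline date
    defaults to the earliest record's date (that day is day 0).
    """
    recs = sorted(records, key=lambda r: r.timestamp)
    if not recs:
        return WeightSeries([], client_id=client_id, baseline_date=baseline_date)
    if baseline_date is None:
        baseline_date = recs[0].timestamp.date()

    observations: list[WeightObservation] = []
    seen: set[date] = set()
    for r in recs:
        d = r.timestamp.date()
        dup = collapse_first_of_day and d in seen
        seen.add(d)
        observations.append(WeightObservation(
            day=(d - baseline_date).days, date=d, timestamp=r.timestamp,
            weight_kg=r.weight_kg, source=r.source,
            excluded=DUPLICATE_SAME_DAY if dup else None))
    return WeightSeries(observations, client_id=client_id, baseline_date=baseline_date)


def filter_outliers(series: WeightSeries, threshold: float = 0.05) -> WeightSeries:
    """Exclude weights deviating by more than ``threshold`` from the last
    retained weight.

    Sequential in date order; the first retained observation is always kept
    and an excluded observation never updates the reference, so the filter is
    idempotent.  The comparison is strict (> threshold); exactly 5 % passes.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    out: list[WeightObservation] = []
    reference: float | None = None
    for o in series.observations:
        if not o.retained:           # already excluded upstream (duplicates)
            out.append(o)
            continue
        if reference is None:
            reference = o.weight_kg
            out.append(o)
            continue
        # epsilon guard keeps a deviation of exactly `threshold` retained even
        # after unit conversion rounding
        if abs(o.weight_kg - reference) / reference > threshold + 1e-12:
            out.append(replace(o, excluded=OUTLIER_GT_5PCT))
        else:
            reference = o.weight_kg
            out.append(o)
    return WeightSeries(out, client_id=series.client_id,
                        baseline_date=series.baseline_date)


def clean(records: Iterable[RawWeightRecord],
          client_id: str = "client",
          baseline_date: date | None = None,
          threshold: float = 0.05,
          collapse_first_of_day: bool = True) -> WeightSeries:
    """ingest + filter_outliers in one step."""
    return filter_outliers(
        ingest(records, client_id=client_id, baseline_date=baseline_date,
               collapse_first_of_day=collapse_first_of_day),
        threshold=threshold)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_weight_csv(path) -> list[RawWeightRecord]:
    """Read raw records from CSV with columns timestamp, weight, unit, source.

    Unparseable rows are logged and skipped; processing continues.
    """
    df = pd.read_csv(path, dtype=str)
    records: list[RawWeightRecord] = []
    for i, row in df.iterrows():
        try:
            ts = datetime.fromisoformat(str(row["timestamp"]))
            w = float(row["weight"])
            unit = str(row.get("unit", "kg")).strip().lower()
            if unit in ("lb", "lbs", "pound", "pounds"):
                w = lb_to_kg(w)
            elif unit not in ("kg", "kgs", "kilogram", "kilograms"):
                raise ValueError(f"unknown unit {unit!r}")
            source = str(row.get("source", "device")).strip()
            records.append(RawWeightRecord(ts, w, source))
        except Exception as exc:  # noqa: BLE001 - bad telemetry must not abort the run
            log.warning("rejected weight record %d in %s: %s", i, path, exc)
    return records


def read_scale_json(path) -> list[RawWeightRecord]:
    """Read a network-scale push payload: a JSON list of
    ``{"deviceId": ..., "timestamp": epoch_ms, "weight": grams}`` objects.
    """
    with open(path) as fh:
        payload = json.load(fh)
    records: list[RawWeightRecord] = []
    for i, item in enumerate(payload):
        try:
            ts = datetime.fromtimestamp(int(item["timestamp"]) / 1000.0, tz=timezone.utc)
            records.append(RawWeightRecord(ts.replace(tzinfo=None),
                                           float(item["weight"]) / 1000.0, "device"))
        except Exception as exc:  # noqa: BLE001
            log.warning("rejected scale payload item %d in %s: %s", i, path, exc)
    return records


def write_series_csv(series: WeightSeries, path) -> None:
    series.to_frame().to_csv(path, index=False)


def read_series_csv(path, client_id: str = "client") -> WeightSeries:
    df = pd.read_csv(path, dtype={"excluded": str}, keep_default_na=False)
    observations = [WeightObservation(
        day=int(r["day"]), date=date.fromisoformat(r["date"]),
        timestamp=datetime.fromisoformat(r["timestamp"]),
        weight_kg=float(r["weight_kg"]), source=str(r["source"]),
        excluded=(str(r["excluded"]) or None)) for _, r in df.iterrows()]
    baseline = None
    if observations:
        first = observations[0]
        baseline = first.date - timedelta(days=first.day)
    return WeightSeries(observations, client_id=client_id, baseline_date=baseline)
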
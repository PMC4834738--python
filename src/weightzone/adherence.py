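"""Zone of adherence, daily color-coded flags, and out-of-zone triggers.

The zone is a band around the model-predicted trajectory; a client whose
daily weight stays inside it is, by construction, adhering to the energy
prescription.  Each dated weight maps to exactly one flag:

* ``GREEN`` — inside the zone, on track.
* ``GREEN_YELLOW`` — inside the zone but plateauing while the prediction
  slopes down, or drifting into the top of the band: an early warning.
* ``RED`` — outside the zone (above it without an adherent rate of loss, or
  below it, i.e. losing faster than prescribed).
* ``RED_GREEN`` — above the zone but falling at least as fast as the
  prediction, so continued behavior returns the client to the zone.
* ``NO_DATA`` — no retained weight that day.

Plateau detection compares the trailing 7-day least-squares slope with zero.
Daily weights carry ~0.3 kg of hydration/clothing noise, which makes a raw
7-day slope estimate noisier (SE ~0.06 kg/day) than the predicted loss rate
itself; the plateau condition therefore requires the slope to be
non-negative with one-sided confidence (slope - z * SE >= 0, z = 1.645 by
default).  Set ``plateau_z = 0`` for the raw rule.

``trigger_check`` implements the k-of-n rule (default 3 of the last 5 days
out of zone) that escalates a client into the intervention toolbox.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .energy_model import WeightTrajectory
from .units import lb_to_kg, kg_to_lb
from .weight_stream import WeightSeries

__all__ = [
    "Flag",
    "FlagState",
    "BandSpec",
    "AdherenceZone",
    "build_zone",
    "classify_flag",
    "classify_series",
    "trigger_check",
    "trailing_slope",
    "plot_smartgraph",
]


class Flag(enum.Enum):
    GREEN = "green"
    GREEN_YELLOW = "green_yellow"
    RED = "red"
    RED_GREEN = "red_green"
    NO_DATA = "no_data"


#: flag values meaning the weight was inside the zone
IN_ZONE_FLAGS = frozenset({Flag.GREEN, Flag.GREEN_YELLOW})
#: default set of flags counting toward the toolbox trigger; RED_GREEN is
#: excluded because it signals recovering adherence
DEFAULT_TRIGGER_FLAGS = frozenset({Flag.RED})


@dataclass(frozen=True)
class BandSpec:
    """Width of the zone around the predicted trajectory.

    ``mode='percent_baseline'`` (default): half-width = pct/100 x baseline
    weight, constant over time.  ``mode='absolute'``: half-widths in kg.
    Asymmetric bands set ``upper`` and ``lower`` separately.
    """

    mode: str = "percent_baseline"
    pct: float = 2.0
    upper_kg: float | None = None
    lower_kg: float | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("percent_baseline", "absolute"):
            raise ValueError(f"unknown band mode {self.mode!r}")
        if self.mode == "percent_baseline" and self.pct < 0:
            raise ValueError("band percent must be >= 0")
        if self.mode == "absolute":
            if self.upper_kg is None or self.lower_kg is None:
                raise ValueError("absolute band needs upper_kg and lower_kg")
            if self.upper_kg < 0 or self.lower_kg < 0:
                raise ValueError("band widths must be >= 0")

    def half_widths(self, baseline_kg: float) -> tuple[float, float]:
        """(upper, lower) half-widths in kg."""
        if self.mode == "percent_baseline":
            hw = self.pct / 100.0 * baseline_kg
            return hw, hw
        return float(self.upper_kg), float(self.lower_kg)

    @classmethod
    def absolute_lb(cls, upper_lb: float, lower_lb: float | None = None) -> "BandSpec":
        if lower_lb is None:
            lower_lb = upper_lb
        return cls(mode="absolute", upper_kg=lb_to_kg(upper_lb),
                   lower_kg=lb_to_kg(lower_lb))


@dataclass
class AdherenceZone:
    """Predicted trajectory with upper/lower bounds on the integer-day grid."""

    days: np.ndarray
    predicted_kg: np.ndarray
    lower_kg: np.ndarray
    upper_kg: np.ndarray

    def __post_init__(self) -> None:
        if not (np.all(self.lower_kg <= self.predicted_kg + 1e-12)
                and np.all(self.predicted_kg <= self.upper_kg + 1e-12)):
            raise ValueError("zone must contain the predicted trajectory")

    def __len__(self) -> int:
        return len(self.days)

    def predicted_slope(self, day: int) -> float:
        """One-day backward difference of the prediction (kg/day)."""
        i = int(day)
        if i <= 0:
            i = 1
        i = min(i, len(self.days) - 1)
        return float(self.predicted_kg[i] - self.predicted_kg[i - 1])

    def contains(self, day: int, weight_kg: float) -> bool:
        return bool(self.lower_kg[day] <= weight_kg <= self.upper_kg[day])

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({
            "day": self.days,
            "predicted_lb": np.round(kg_to_lb(self.predicted_kg), 4),
            "lower_lb": np.round(kg_to_lb(self.lower_kg), 4),
            "upper_lb": np.round(kg_to_lb(self.upper_kg), 4),
            "predicted_kg": np.round(self.predicted_kg, 4),
            "lower_kg": np.round(self.lower_kg, 4),
            "upper_kg": np.round(self.upper_kg, 4),
        })


def build_zone(trajectory: WeightTrajectory, band: BandSpec | None = None) -> AdherenceZone:
    """Attach upper/lower adherence bounds to a predicted trajectory."""
    band = band or BandSpec()
    up, lo = band.half_widths(float(trajectory.weight_kg[0]))
    pred = np.asarray(trajectory.weight_kg, dtype=float)
    return AdherenceZone(days=np.asarray(trajectory.days),
                         predicted_kg=pred, lower_kg=pred - lo, upper_kg=pred + up)


# ---------------------------------------------------------------------------
# Trailing slope and flag classification
# ---------------------------------------------------------------------------

def trailing_slope(days: Sequence[int], weights: Sequence[float], day: int,
                   window: int = 7) -> tuple[float, float, int]:
    """Least-squares slope (kg/day), its standard error, and n over the
    retained observations in the trailing window ``[day - window + 1, day]``.

    Returns (nan, nan, n) when fewer than two points fall in the window; SE
    is 0 for an exact two-point or collinear fit.
    """
    days = np.asarray(days)
    weights = np.asarray(weights, dtype=float)
    mask = (days >= day - window + 1) & (days <= day)
    x, y = days[mask].astype(float), weights[mask]
    n = len(x)
    if n < 2:
        return float("nan"), float("nan"), n
    xm = x - x.mean()
    sxx = float(xm @ xm)
    slope = float(xm @ y) / sxx
    resid = y - y.mean() - slope * xm
    if n > 2:
        se = float(np.sqrt(max(resid @ resid, 0.0) / (n - 2) / sxx))
    else:
        se = 0.0
    return slope, se, n


@dataclass(frozen=True)
class FlagState:
    """One client-day adherence flag with its supporting evidence."""

    day: int
    flag: Flag
    weight_kg: float | None = None
    lower_kg: float | None = None
    upper_kg: float | None = None
    trailing_slope_kg_d: float | None = None
    slope_se_kg_d: float | None = None
    predicted_slope_kg_d: float | None = None
    n_slope_points: int = 0


def _classify_day(day: int,
                  weight: float | None,
                  obs_days: np.ndarray,
                  obs_weights: np.ndarray,
                  zone: AdherenceZone,
                  slope_window: int,
                  min_slope_points: int,
                  plateau_z: float,
                  upper_edge_fraction: float) -> FlagState:
    if weight is None:
        return FlagState(day=day, flag=Flag.NO_DATA)
    d = int(day)
    w = float(weight)
    lower, upper = float(zone.lower_kg[d]), float(zone.upper_kg[d])
    slope, se, n = trailing_slope(obs_days, obs_weights, d, window=slope_window)
    pred_slope = zone.predicted_slope(d)
    have_slope = n >= min_slope_points

    def state(flag: Flag) -> FlagState:
        return FlagState(day=d, flag=flag, weight_kg=w, lower_kg=lower,
                         upper_kg=upper,
                         trailing_slope_kg_d=slope if n >= 2 else None,
                         slope_se_kg_d=se if n >= 2 else None,
                         predicted_slope_kg_d=pred_slope, n_slope_points=n)

    if lower <= w <= upper:
        near_upper = w >= upper - upper_edge_fraction * (upper - lower)
        # -1e-9 kg/day guard: an exactly flat fit must count as a plateau
        plateau = (have_slope and pred_slope < 0
                   and slope - plateau_z * se >= -1e-9)
        return state(Flag.GREEN_YELLOW if (near_upper or plateau) else Flag.GREEN)
    if w > upper:
        if have_slope and slope <= pred_slope:
            return state(Flag.RED_GREEN)
        return state(Flag.RED)
    return state(Flag.RED)          # below the zone: losing faster than prescribed


def classify_flag(series: WeightSeries,
                  zone: AdherenceZone,
                  day: int,
                  slope_window: int = 7,
                  min_slope_points: int = 3,
                  plateau_z: float = 1.645,
                  upper_edge_fraction: float = 0.2) -> FlagState:
    """Classify one client-day against the zone.

    Slope conditions (plateau, adherent-rate) need at least
    ``min_slope_points`` retained weights in the trailing window; with fewer,
    only the in/out position is evaluated, except that the positional
    top-of-band early warning never needs history.
    """
    obs_days, obs_weights = series.days_weights()
    return _classify_day(int(day), series.weight_on(day),
                         np.asarray(obs_days), np.asarray(obs_weights, dtype=float),
                         zone, slope_window, min_slope_points, plateau_z,
                         upper_edge_fraction)


def classify_series(series: WeightSeries,
                    zone: AdherenceZone,
                    days: Sequence[int] | None = None,
                    slope_window: int = 7,
                    min_slope_points: int = 3,
                    plateau_z: float = 1.645,
                    upper_edge_fraction: float = 0.2) -> list[FlagState]:
    """Flags for every day in ``days`` (default: the zone's full day grid)."""
    if days is None:
        days = [int(d) for d in zone.days]
    obs_days, obs_weights = series.days_weights()
    obs_days = np.asarray(obs_days)
    obs_weights = np.asarray(obs_weights, dtype=float)
    by_day = {int(d): float(w) for d, w in zip(obs_days, obs_weights)}
    return [_classify_day(int(d), by_day.get(int(d)), obs_days, obs_weights,
                          zone, slope_window, min_slope_points, plateau_z,
                          upper_edge_fraction) for d in days]


# ---------------------------------------------------------------------------
# k-of-n trigger
# ---------------------------------------------------------------------------

def trigger_check(flags: Sequence[FlagState | Flag],
                  k: int = 3,
                  n: int = 5,
                  trigger_flags: frozenset = DEFAULT_TRIGGER_FLAGS,
                  no_data_counts_in_n: bool = True,
                  days_since_enrollment: int | None = None) -> bool:
    """True iff at least ``k`` of the most recent ``n`` daily flags call for
    intervention (default: RED only; RED_GREEN signals recovery).

    ``NO_DATA`` days never count toward ``k``; by default they occupy slots
    in the ``n``-day lookback (set ``no_data_counts_in_n=False`` to look back
    over the last ``n`` days *with data*).  With fewer than ``n`` flags the
    check evaluates over the available history only when at least ``n`` days
    have elapsed since enrollment; earlier it is always False.
    """
    if not (n >= k >= 1):
        raise ValueError("need n >= k >= 1")
    seq = [f.flag if isinstance(f, FlagState) else f for f in flags]
    if not no_data_counts_in_n:
        seq = [f for f in seq if f is not Flag.NO_DATA]
    if len(seq) < n:
        enrolled = days_since_enrollment if days_since_enrollment is not None else len(seq)
        if enrolled < n:
            return False
        recent = seq
    else:
        recent = seq[-n:]
    return sum(f in trigger_flags for f in recent) >= k


# ---------------------------------------------------------------------------
# SmartGraph rendering
# ---------------------------------------------------------------------------

def plot_smartgraph(zone: AdherenceZone, series: WeightSeries, path,
                    title: str = "Weight vs. zone of adherence") -> None:
    """Render predicted line, dashed bounds, and observed weights to PNG/SVG."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 4.5))
    ax.plot(zone.days, kg_to_lb(zone.predicted_kg), color="goldenrod",
            label="predicted")
    ax.plot(zone.days, kg_to_lb(zone.upper_kg), "--", color="steelblue",
            label="zone bounds")
    ax.plot(zone.days, kg_to_lb(zone.lower_kg), "--", color="steelblue")
    kept = series.retained()
    if kept:
        ax.plot([o.day for o in kept], [o.weight_lb for o in kept],
                ".-", color="purple", label="observed")
    for o in series.excluded():
        ax.plot(o.day, o.weight_lb, "x", color="gray")
    ax.set_xlabel("day")
    ax.set_ylabel("weight (lb)")
    ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
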
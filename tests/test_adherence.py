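"""Zone construction, flag classification, and the k-of-n trigger."""

import itertools

import numpy as np
import pytest

from weightzone import (BandSpec, Flag, WeightTrajectory, build_zone,
                        classify_flag, classify_series, trigger_check)
from weightzone.adherence import trailing_slope
from weightzone.units import lb_to_kg, kg_to_lb

from conftest import series_from_arrays
from oracles import oracle_flag, ols_slope_se


def flat_trajectory(weight_lb, days=30):
    w = np.full(days + 1, lb_to_kg(weight_lb))
    return WeightTrajectory(days=np.arange(days + 1), weight_kg=w,
                            fat_kg=0.3 * w, ffm_kg=0.7 * w)


# ---------------------------------------------------------------------------
# zone construction
# ---------------------------------------------------------------------------

def test_zero_band_degenerates_to_prediction(ref_trajectory):
    zone = build_zone(ref_trajectory, BandSpec(pct=0.0))
    np.testing.assert_array_equal(zone.upper_kg, zone.predicted_kg)
    np.testing.assert_array_equal(zone.lower_kg, zone.predicted_kg)


def test_absolute_band_arithmetic():
    zone = build_zone(flat_trajectory(195.0), BandSpec.absolute_lb(2.0))
    assert kg_to_lb(zone.lower_kg[0]) == pytest.approx(193.0)
    assert kg_to_lb(zone.upper_kg[0]) == pytest.approx(197.0)


@pytest.mark.parametrize("band", [BandSpec(pct=2.0), BandSpec(pct=0.5),
                                  BandSpec.absolute_lb(3.0, 1.0)])
def test_zone_contains_prediction(ref_trajectory, band):
    zone = build_zone(ref_trajectory, band)
    assert np.all(zone.lower_kg <= zone.predicted_kg)
    assert np.all(zone.predicted_kg <= zone.upper_kg)


def test_negative_band_rejected():
    with pytest.raises(ValueError):
        BandSpec(pct=-1.0)
    with pytest.raises(ValueError):
        BandSpec(mode="absolute", upper_kg=-0.5, lower_kg=0.5)


# ---------------------------------------------------------------------------
# flag classification
# ---------------------------------------------------------------------------

def test_green_defining_case(ref_trajectory, make_series):
    zone = build_zone(ref_trajectory)
    # track the predicted center exactly: inside, descending, far from the edge
    days = np.arange(20)
    series = make_series(days, zone.predicted_kg[days])
    state = classify_flag(series, zone, 10)
    assert state.flag is Flag.GREEN
    assert state.trailing_slope_kg_d < 0


def test_red_defining_case(ref_trajectory, make_series):
    zone = build_zone(ref_trajectory)
    days = np.arange(15)
    series = make_series(days, zone.upper_kg[days] + 0.5 + 0.01 * days)  # rising, above
    state = classify_flag(series, zone, 14)
    assert state.flag is Flag.RED


def test_red_green_when_descending_faster_than_prediction(ref_trajectory, make_series):
    zone = build_zone(ref_trajectory)
    days = np.arange(10, 20)
    # 1 lb above the upper bound but descending at 3x the predicted rate
    pred_slope = zone.predicted_kg[19] - zone.predicted_kg[18]
    weights = zone.upper_kg[19] + lb_to_kg(1.0) + 3 * pred_slope * (days - 19)
    series = make_series(days, weights)
    state = classify_flag(series, zone, 19)
    # cross-check the slope with an independent least-squares fit
    slope, _ = ols_slope_se(days[-7:], weights[-7:])
    assert slope <= pred_slope
    assert state.flag is Flag.RED_GREEN


def test_green_yellow_near_upper_edge(ref_trajectory, make_series):
    zone = build_zone(ref_trajectory)
    d = 15
    w = zone.upper_kg[d] - 0.05 * (zone.upper_kg[d] - zone.lower_kg[d])  # top 20%
    series = make_series([d], [w])
    assert classify_flag(series, zone, d).flag is Flag.GREEN_YELLOW


def test_green_yellow_on_confident_plateau(ref_trajectory, make_series):
    zone = build_zone(ref_trajectory)
    days = np.arange(20, 30)
    series = make_series(days, np.full(10, zone.predicted_kg[25]))  # dead flat
    state = classify_flag(series, zone, 29)
    assert state.flag is Flag.GREEN_YELLOW
    assert state.predicted_slope_kg_d < 0


def test_insufficient_history_only_position_evaluated(ref_trajectory, make_series):
    zone = build_zone(ref_trajectory)
    # two points descending steeply from above the zone: would be RED_GREEN
    # with enough history, but with n < 3 only in/out applies -> RED
    series = make_series([8, 9], [zone.upper_kg[9] + 2.0, zone.upper_kg[9] + 0.5])
    state = classify_flag(series, zone, 9)
    assert state.flag is Flag.RED
    assert state.n_slope_points == 2


def test_no_data_day(ref_trajectory, make_series):
    zone = build_zone(ref_trajectory)
    series = make_series([0, 1], [zone.predicted_kg[0], zone.predicted_kg[1]])
    assert classify_flag(series, zone, 5).flag is Flag.NO_DATA


def test_every_day_gets_exactly_one_flag(ref_trajectory, make_series):
    zone = build_zone(ref_trajectory)
    days = np.arange(0, 40, 3)
    series = make_series(days, zone.predicted_kg[days])
    states = classify_series(series, zone, days=range(40))
    assert len(states) == 40
    assert [s.day for s in states] == list(range(40))
    assert all(isinstance(s.flag, Flag) for s in states)


def test_widening_band_never_turns_green_red(ref_trajectory, make_series):
    rng = np.random.default_rng(7)
    narrow = build_zone(ref_trajectory, BandSpec(pct=1.0))
    wide = build_zone(ref_trajectory, BandSpec(pct=3.0))
    days = np.arange(60)
    for _ in range(50):
        weights = ref_trajectory.weight_kg[days] + rng.normal(0, 1.0, 60)
        series = make_series(days, weights)
        f_narrow = [s.flag for s in classify_series(series, narrow, days=days)]
        f_wide = [s.flag for s in classify_series(series, wide, days=days)]
        for fn, fw in zip(f_narrow, f_wide):
            if fn is Flag.GREEN:
                assert fw is not Flag.RED


def test_classifier_matches_independent_oracle(ref_trajectory, make_series):
    """Interval tests + independently coded least-squares slope agree with the
    classifier on randomized series (larger sample in the acceptance suite)."""
    zone = build_zone(ref_trajectory)
    rng = np.random.default_rng(11)
    horizon = 60
    for _ in range(200):
        present = rng.random(horizon + 1) > 0.2
        present[0] = True
        days = np.flatnonzero(present)
        drift = rng.normal(0, 0.08) * days
        weights = (ref_trajectory.weight_kg[days] + drift
                   + rng.normal(0, rng.uniform(0.1, 1.5), len(days)))
        series = make_series(days, weights)
        by_day = dict(zip(days.tolist(), weights.tolist()))
        states = classify_series(series, zone, days=range(horizon + 1))
        for s in states:
            expect = oracle_flag(by_day, s.day, zone.predicted_kg,
                                 zone.lower_kg, zone.upper_kg)
            assert s.flag is expect, f"day {s.day}: {s.flag} != {expect}"


def test_trailing_slope_matches_closed_form():
    days = [3, 5, 6, 8, 9]
    w = [90.0, 89.5, 89.6, 89.1, 89.0]
    slope, se, n = trailing_slope(days, w, day=9, window=7)
    exp_slope, exp_se = ols_slope_se(days, w)
    assert n == 5
    assert slope == pytest.approx(exp_slope)
    assert se == pytest.approx(exp_se)


# ---------------------------------------------------------------------------
# k-of-n trigger
# ---------------------------------------------------------------------------

def test_trigger_truth_table_exhaustive():
    """All 2^5 RED/GREEN patterns: fires iff >= 3 of the last 5 are RED."""
    for bits in itertools.product([0, 1], repeat=5):
        flags = [Flag.RED if b else Flag.GREEN for b in bits]
        assert trigger_check(flags, k=3, n=5) is (sum(bits) >= 3)


def test_trigger_example_patterns():
    seq = [Flag.RED, Flag.GREEN, Flag.RED, Flag.GREEN, Flag.RED]
    assert trigger_check(seq) is True
    assert trigger_check([Flag.GREEN] * 5) is False
    assert trigger_check([Flag.RED, Flag.RED, Flag.GREEN, Flag.GREEN, Flag.GREEN]) is False


def test_red_green_not_counted_by_default_but_configurable():
    seq = [Flag.RED_GREEN, Flag.RED_GREEN, Flag.RED, Flag.RED, Flag.GREEN]
    assert trigger_check(seq) is False
    assert trigger_check(seq, trigger_flags=frozenset({Flag.RED, Flag.RED_GREEN})) is True


def test_no_data_occupies_lookback_slots():
    seq = [Flag.RED, Flag.RED, Flag.RED, Flag.NO_DATA, Flag.NO_DATA]
    assert trigger_check(seq) is True          # 3 RED within the last 5 slots
    seq = [Flag.RED, Flag.RED, Flag.NO_DATA, Flag.NO_DATA, Flag.NO_DATA]
    assert trigger_check(seq) is False
    # skipping NO_DATA looks further back at days with data
    longer = [Flag.RED, Flag.RED, Flag.RED, Flag.GREEN, Flag.GREEN,
              Flag.NO_DATA, Flag.NO_DATA]
    assert trigger_check(longer, no_data_counts_in_n=False) is True


def test_short_history_needs_enrollment_time():
    seq = [Flag.RED, Flag.RED, Flag.RED]
    assert trigger_check(seq) is False                              # 3 days enrolled
    assert trigger_check(seq, days_since_enrollment=6) is True      # sparse history
    with pytest.raises(ValueError):
        trigger_check(seq, k=4, n=3)
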
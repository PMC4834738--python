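"""Energy-balance model: maintenance energy, forward prediction, inversion."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from weightzone import (ClientProfile, EnergyPrescription,
                        InvalidPrescriptionError, InvalidProfileError,
                        estimate_intake, maintenance_energy, predict_trajectory,
                        simulate_weights)
from weightzone.energy_model import (initial_composition, tissue_energy,
                                     resting_metabolic_rate)
from weightzone.units import kg_to_lb, lb_to_kg, inches_to_cm, cm_to_inches


# ---------------------------------------------------------------------------
# units and profile validation
# ---------------------------------------------------------------------------

@settings(max_examples=100, deadline=None, derandomize=True)
@given(st.floats(min_value=50, max_value=500))
def test_unit_round_trip_lossless(lb):
    assert kg_to_lb(lb_to_kg(lb)) == pytest.approx(lb, abs=0.01)
    assert cm_to_inches(inches_to_cm(lb)) == pytest.approx(lb, abs=0.01)


@pytest.mark.parametrize("kwargs", [
    {"sex": "female", "age": 50, "height_cm": 0, "weight_kg": 90},
    {"sex": "female", "age": 50, "height_cm": 165, "weight_kg": -5},
    {"sex": "female", "age": 0, "height_cm": 165, "weight_kg": 90},
    {"sex": "other", "age": 50, "height_cm": 165, "weight_kg": 90},
])
def test_invalid_profile_rejected(kwargs):
    with pytest.raises(InvalidProfileError):
        ClientProfile(**kwargs)


def test_negative_prescribed_intake_rejected():
    with pytest.raises(InvalidPrescriptionError):
        EnergyPrescription(maintenance_intake=2000, delta_intake=-2500)


# ---------------------------------------------------------------------------
# maintenance energy
# ---------------------------------------------------------------------------

def test_maintenance_increases_with_weight(params):
    heavier = ClientProfile.from_us("female", 50, 65, 200)
    lighter = ClientProfile.from_us("female", 50, 65, 150)
    assert maintenance_energy(heavier, params) > maintenance_energy(lighter, params)


def test_maintenance_frozen_regression_value(ref_profile, params):
    # hand evaluation of activity_factor * MSJ / (1 - tef) for the worked example:
    # RMR = 10 * 90.718474 + 6.25 * 165.1 - 5 * 50 - 161 = 1528.05974 kcal/d
    # maintenance = 1.5 * RMR / 0.9 = 2546.76623 kcal/d
    assert maintenance_energy(ref_profile, params) == pytest.approx(2546.766, abs=0.01)


def test_maintenance_intake_holds_weight(ref_profile, params):
    maint = maintenance_energy(ref_profile, params)
    traj = simulate_weights(ref_profile, maint, 90, params)
    assert np.max(np.abs(traj.weight_kg - traj.weight_kg[0])) < 0.25


# ---------------------------------------------------------------------------
# forward prediction
# ---------------------------------------------------------------------------

def test_worked_example_one_year_loss(ref_trajectory):
    loss_lb = ref_trajectory.weight_lb[0] - ref_trajectory.weight_lb[-1]
    assert loss_lb == pytest.approx(17.4, abs=0.5)
    assert 100 * loss_lb / ref_trajectory.weight_lb[0] == pytest.approx(8.7, abs=0.25)


def test_zero_horizon_returns_baseline(ref_profile, params):
    rx = EnergyPrescription(maintenance_energy(ref_profile, params), -500, 0)
    traj = predict_trajectory(ref_profile, rx, params)
    assert len(traj) == 1
    assert traj.weight_kg[0] == pytest.approx(ref_profile.weight_kg)


def test_trajectory_structure(ref_trajectory, ref_profile, ref_rx):
    assert len(ref_trajectory) == ref_rx.horizon_days + 1
    assert ref_trajectory.weight_kg[0] == pytest.approx(ref_profile.weight_kg)
    np.testing.assert_allclose(ref_trajectory.weight_kg,
                               ref_trajectory.fat_kg + ref_trajectory.ffm_kg)


def test_restriction_monotone_and_decelerating(ref_trajectory, ref_profile, params):
    w = ref_trajectory.weight_kg
    assert np.all(np.diff(w) <= 1e-9)                      # non-increasing
    assert abs(w[365] - w[364]) < abs(w[30] - w[29])       # plateau

    milder = EnergyPrescription(maintenance_energy(ref_profile, params), -250, 365)
    w_mild = predict_trajectory(ref_profile, milder, params).weight_kg
    assert np.all(w[1:] < w_mild[1:])                      # deeper deficit lies lower


def _euler_trajectory(profile, intake, days, params, step=0.01):
    """Brute-force fixed-step Euler integration of the same ODE."""
    pal_rmr0 = params.activity_factor * resting_metabolic_rate(profile, params)
    f, l = initial_composition(profile, params)
    w0 = profile.weight_kg
    n_steps = int(round(days / step))
    per_day = int(round(1.0 / step))
    out = [f + l]
    for i in range(n_steps):
        w = f + l
        expenditure = (pal_rmr0 + params.tef_fraction * intake
                       + params.expenditure_slope * (w - w0))
        alpha = params.forbes_c / (params.forbes_c + f)
        rho = alpha * params.rho_ffm + (1 - alpha) * params.rho_fat
        dw = (intake - expenditure) / rho
        f += (1 - alpha) * dw * step
        l += alpha * dw * step
        if (i + 1) % per_day == 0:
            out.append(f + l)
    return np.array(out)


def test_adaptive_integrator_matches_euler_oracle(ref_profile, ref_rx, params,
                                                  ref_trajectory):
    euler = _euler_trajectory(ref_profile, ref_rx.prescribed_intake, 365, params)
    assert np.max(np.abs(ref_trajectory.weight_kg - euler)) < 0.01


def test_energy_bookkeeping_closes(ref_profile, ref_rx, params, ref_trajectory):
    """Cumulative (intake - expenditure) equals the change in tissue energy."""
    intake = ref_rx.prescribed_intake
    pal_rmr0 = params.activity_factor * resting_metabolic_rate(ref_profile, params)
    w = ref_trajectory.weight_kg
    imbalance = (intake - (pal_rmr0 + params.tef_fraction * intake
                           + params.expenditure_slope * (w - w[0])))
    stored = (tissue_energy(ref_trajectory.fat_kg[-1], ref_trajectory.ffm_kg[-1], params)
              - tissue_energy(ref_trajectory.fat_kg[0], ref_trajectory.ffm_kg[0], params))
    assert stored == pytest.approx(np.trapezoid(imbalance), rel=1e-3)


def test_piecewise_intake_schedule_matches_segments(ref_profile, params):
    """A two-level schedule equals constant runs chained by hand."""
    maint = maintenance_energy(ref_profile, params)
    schedule = np.concatenate([np.full(10, maint - 500), np.full(10, maint)])
    traj = simulate_weights(ref_profile, schedule, 20, params)
    first = simulate_weights(ref_profile, maint - 500, 10, params)
    second = simulate_weights(ref_profile, maint, 10, params,
                              y0=(first.fat_kg[-1], first.ffm_kg[-1]))
    np.testing.assert_allclose(traj.weight_kg[:11], first.weight_kg, atol=1e-8)
    np.testing.assert_allclose(traj.weight_kg[10:], second.weight_kg, atol=1e-8)


# ---------------------------------------------------------------------------
# inverse problem
# ---------------------------------------------------------------------------

def test_flat_weights_recover_maintenance(ref_profile, params):
    maint = maintenance_energy(ref_profile, params)
    days = np.arange(29)
    weights = np.full(29, ref_profile.weight_kg)
    ests = estimate_intake(ref_profile, days, weights, params, window=14)
    assert len(ests) == 2
    for e in ests:
        assert not e.skipped
        assert e.intake_kcal == pytest.approx(maint, abs=10)


def test_noise_free_recovery_within_5_kcal(ref_profile, params):
    maint = maintenance_energy(ref_profile, params)
    rx = EnergyPrescription(maint, -500, 28)
    traj = predict_trajectory(ref_profile, rx, params)
    ests = estimate_intake(ref_profile, traj.days, traj.weight_kg, params, window=14)
    for e in ests:
        assert e.delta_kcal == pytest.approx(-500, abs=5)


def test_estimate_matches_grid_search_oracle(ref_profile, params):
    """Bounded minimization lands on the brute-force 1-kcal-grid argmin."""
    maint = maintenance_energy(ref_profile, params)
    rx = EnergyPrescription(maint, -400, 14)
    traj = predict_trajectory(ref_profile, rx, params)
    rng = np.random.default_rng(42)
    weights = traj.weight_kg + rng.normal(0, 0.2, len(traj))
    weights[0] = traj.weight_kg[0]

    est = estimate_intake(ref_profile, traj.days, weights, params, window=14)[0]

    grid = np.arange(maint - 800, maint + 801, 1.0)
    days = np.arange(1, 15)
    sses = []
    for intake in grid:
        t = simulate_weights(ref_profile, float(intake), 14, params)
        sses.append(np.sum((t.weight_kg[days] - weights[days]) ** 2))
    best = grid[int(np.argmin(sses))]
    assert est.intake_kcal == pytest.approx(best, abs=1.0)


def test_sparse_window_skipped_and_flagged(ref_profile, params):
    days = np.array([0, 2, 5, 9, 20])        # second window has a single point
    weights = np.full(len(days), ref_profile.weight_kg)
    ests = estimate_intake(ref_profile, days, weights, params, window=14)
    assert [e.skipped for e in ests] == [False, True]
    assert ests[1].intake_kcal is None and ests[1].n_obs == 1
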
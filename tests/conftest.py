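from datetime import date, datetime, time, timedelta

import pytest

from weightzone import (ClientProfile, EnergyPrescription, ModelParams,
                        WeightSeries, maintenance_energy, predict_trajectory)
from weightzone.weight_stream import WeightObservation

BASE_DATE = date(2024, 1, 1)


@pytest.fixture(scope="session")
def params():
    return ModelParams()


@pytest.fixture(scope="session")
def ref_profile():
    """The canonical worked example: 50-year-old female, 65 in, 200 lb."""
    return ClientProfile.from_us("female", 50, 65, 200, baseline_steps=4000)


@pytest.fixture(scope="session")
def ref_rx(ref_profile, params):
    return EnergyPrescription(maintenance_energy(ref_profile, params), -500.0, 365)


@pytest.fixture(scope="session")
def ref_trajectory(ref_profile, ref_rx, params):
    return predict_trajectory(ref_profile, ref_rx, params)


def series_from_arrays(days, weights_kg, client_id="test", baseline=BASE_DATE):
    """Build a cleaned WeightSeries directly from day offsets and kg weights."""
    obs = [WeightObservation(day=int(d), date=baseline + timedelta(days=int(d)),
                             timestamp=datetime.combine(baseline + timedelta(days=int(d)),
                                                        time(7, 0)),
                             weight_kg=float(w), source="device")
           for d, w in zip(days, weights_kg)]
    return WeightSeries(obs, client_id=client_id, baseline_date=baseline)


@pytest.fixture
def make_series():
    return series_from_arrays
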
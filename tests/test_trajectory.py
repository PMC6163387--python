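import math
from datetime import date

import numpy as np
import pytest

import mothtraj as mt
from mothtraj.exceptions import ValidationError
from mothtraj.trajectory import M_PER_DEG
from mothtraj.windfield import Extent

from conftest import NIGHT, RELEASE

EQ_EXTENT = Extent(
    lon=(-3.0, 3.0), lat=(-1.0, 8.0), heights=(400.0, 500.0, 600.0, 700.0, 800.0),
    start="2000-03-01T18:00", hours=14.0, n_lon=7, n_lat=10,
)


def _run(field, behavior, mode, **kw):
    return mt.run_trajectory(field, RELEASE, NIGHT, 600.0, behavior, mode=mode, **kw)


def test_uniform_wind_passive_advection(uniform_field):
    traj = _run(uniform_field, mt.FlightBehavior(), "passive")
    assert traj.termination == "completed"
    assert len(traj.waypoints) == 13
    # 10 m/s northward for 1 h moves 36 km = 0.32376 degrees of latitude
    assert traj.waypoints[1].lat == pytest.approx(36000.0 / M_PER_DEG, abs=1e-9)
    assert traj.waypoints[1].lon == pytest.approx(0.0, abs=1e-12)
    end = (traj.endpoint.lon, traj.endpoint.lat)
    assert mt.haversine_km(RELEASE, end) == pytest.approx(432.0, abs=0.01)
    assert mt.path_length_km(traj) == pytest.approx(432.0, abs=0.01)


def test_uniform_wind_behavioral_endpoints(uniform_field):
    crab0 = _run(uniform_field, mt.FlightBehavior(crab_angle=0.0), "behavioral")
    end = (crab0.endpoint.lon, crab0.endpoint.lat)
    assert mt.haversine_km(RELEASE, end) == pytest.approx(626.4, abs=0.01)
    assert end[0] == pytest.approx(0.0, abs=1e-9)  # due north

    crab30 = _run(uniform_field, mt.FlightBehavior(), "behavioral")
    end30 = (crab30.endpoint.lon, crab30.endpoint.lat)
    assert mt.haversine_km(RELEASE, end30) == pytest.approx(608.2, abs=0.2)
    assert mt.bearing_deg(RELEASE, end30) == pytest.approx(9.195, abs=0.02)


def test_heun_equals_euler_for_constant_wind(uniform_field):
    heun = _run(uniform_field, mt.FlightBehavior(), "behavioral", scheme="heun")
    euler = _run(uniform_field, mt.FlightBehavior(), "behavioral", scheme="euler")
    for a, b in zip(heun.waypoints, euler.waypoints):
        # predictor and corrector velocities coincide; only float rounding
        # in the interpolation weights separates the two schemes
        assert a.lon == pytest.approx(b.lon, abs=1e-12)
        assert a.lat == pytest.approx(b.lat, abs=1e-12)


def test_calm_air_without_heading_keeps_position():
    calm = mt.make_uniform_field(0.0, 0.0, EQ_EXTENT)
    traj = _run(calm, mt.FlightBehavior(), "behavioral")
    assert traj.termination == "completed"
    for wp in traj.waypoints:
        assert (wp.lon, wp.lat) == RELEASE


def test_calm_air_carries_last_defined_heading():
    """When the wind dies mid-flight the moth keeps its last heading."""
    lons, lats, heights, times = EQ_EXTENT.axes()
    shape = (times.size, heights.size, lats.size, lons.size)
    V = np.zeros(shape)
    V[:3] = 10.0  # northward wind for the first two hours, then calm
    field = mt.GridWindField(lons, lats, heights, times, np.zeros(shape), V)
    traj = _run(field, mt.FlightBehavior(), "behavioral")
    assert traj.termination == "completed"
    lats_series = [w.lat for w in traj.waypoints]
    # still progressing northward during the calm tail (airspeed contribution)
    assert lats_series[-1] > lats_series[4] > lats_series[2]
    hourly_late = (lats_series[-1] - lats_series[-2]) * M_PER_DEG / 3600.0
    assert hourly_late == pytest.approx(4.5 * math.cos(math.radians(30.0)), rel=1e-3)


def test_cold_stop_at_first_check():
    cold = mt.make_uniform_field(0.0, 10.0, EQ_EXTENT, temp=5.0)
    traj = _run(cold, mt.FlightBehavior(), "behavioral")
    assert traj.termination == "cold_stop"
    assert len(traj.waypoints) == 1  # release point only
    assert traj.termination_time == traj.release.time


def test_rain_stop():
    wet = mt.make_uniform_field(0.0, 10.0, EQ_EXTENT, precip=0.5)
    traj = _run(wet, mt.FlightBehavior(), "passive")
    assert traj.termination == "rain_stop"
    assert len(traj.waypoints) == 1


def test_absent_variables_disable_stop_rules():
    lons, lats, heights, times = EQ_EXTENT.axes()
    shape = (times.size, heights.size, lats.size, lons.size)
    bare = mt.GridWindField(lons, lats, heights, times, np.zeros(shape),
                            np.full(shape, 10.0))
    traj = _run(bare, mt.FlightBehavior(temp_min=30.0), "passive")
    assert traj.termination == "completed"


def test_domain_exit_keeps_only_in_domain_waypoints():
    tight = Extent(lon=(-1.0, 1.0), lat=(-0.5, 1.0), heights=(500.0, 700.0),
                   start="2000-03-01T18:00", hours=14.0, n_lon=3, n_lat=3)
    field = mt.make_uniform_field(0.0, 25.0, tight)
    traj = _run(field, mt.FlightBehavior(), "passive")
    assert traj.termination == "domain_exit"
    assert len(traj.waypoints) < 13
    for wp in traj.waypoints:
        assert -0.5 <= wp.lat <= 1.0


def test_release_outside_domain_is_an_error(uniform_field):
    with pytest.raises(ValidationError):
        mt.run_trajectory(uniform_field, (50.0, 0.0), NIGHT, 600.0,
                          mt.FlightBehavior(), mode="passive")


def test_rotating_wind_closed_form_oracle():
    """Half a rotation of a 10 m/s wind displaces 2S/omega east of release."""
    field, cfg = mt.load_preset("rotating_test")
    omega = 2.0 * math.pi / (12 * 3600.0)
    traj = mt.run_trajectory(field, RELEASE, date(2000, 1, 1), 600.0,
                             mt.FlightBehavior(max_duration=6.0), mode="passive", dt=60.0)
    assert traj.termination == "completed"
    end = (traj.endpoint.lon, traj.endpoint.lat)
    closed_km = 2.0 * 10.0 / omega / 1000.0  # 137.51
    dist = mt.haversine_km(RELEASE, end)
    assert abs(dist - closed_km) / closed_km < 0.002
    assert mt.bearing_deg(RELEASE, end) == pytest.approx(90.0, abs=0.1)
    # hourly-chord path length: 6 chords of a 30-degree arc each
    chord_km = 6.0 * 2.0 * (10.0 / omega) * math.sin(omega * 3600.0 / 2.0) / 1000.0
    assert mt.path_length_km(traj) == pytest.approx(chord_km, rel=0.002)


def test_waypoints_are_hourly_at_constant_altitude(study_runs):
    for traj in study_runs["behavioral"][:10]:
        times = [w.time for w in traj.waypoints]
        for a, b in zip(times, times[1:]):
            assert b - a == np.timedelta64(3600, "s")
        assert all(w.alt == traj.start_height for w in traj.waypoints)


def test_airspeed_zero_behavioral_equals_passive_bitwise(study):
    field, _ = study
    still = mt.FlightBehavior(airspeed=0.0)
    kw = dict(night=date(1995, 3, 19), start_height=600.0, dt=60.0)
    passive = mt.run_trajectory(field, (-97.78, 26.18), behavior=still,
                                mode="passive", **kw)
    behavioral = mt.run_trajectory(field, (-97.78, 26.18), behavior=still,
                                   mode="behavioral", **kw)
    assert passive.termination == behavioral.termination
    for a, b in zip(passive.waypoints, behavioral.waypoints):
        assert (a.lon, a.lat) == (b.lon, b.lat)


def test_ensemble_order_and_failure_isolation(uniform_field):
    cfg = mt.EnsembleConfig(
        sources=[("A", 0.0, 0.0), ("B", 50.0, 0.0), ("C", 1.0, 0.5)],
        nights=[date(2000, 3, 1)],
        heights=[600.0, 500.0],
        mode="passive",
        behavior=mt.FlightBehavior(),
        field=uniform_field,
        dt=3600.0,
    )
    trajs = mt.run_ensemble(cfg)
    assert len(trajs) == cfg.size == 6
    assert [t.source_id for t in trajs] == ["A", "A", "B", "B", "C", "C"]
    assert [t.start_height for t in trajs[:2]] == [500.0, 600.0]  # ascending
    failed = [t for t in trajs if t.termination == "failed"]
    assert len(failed) == 2 and all(t.source_id == "B" for t in failed)
    assert all(t.termination == "completed" for t in trajs if t.source_id != "B")


def test_single_cell_ensemble(uniform_field):
    cfg = mt.EnsembleConfig(
        sources=[("SRC", 0.0, 0.0)], nights=[NIGHT], heights=[600.0],
        mode="behavioral", behavior=mt.FlightBehavior(), field=uniform_field,
    )
    assert len(mt.run_ensemble(cfg)) == 1


def test_dt_must_divide_the_hour(uniform_field):
    with pytest.raises(ValidationError):
        mt.run_trajectory(uniform_field, RELEASE, NIGHT, 600.0,
                          mt.FlightBehavior(), mode="passive", dt=7.0)
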
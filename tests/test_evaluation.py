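import math
from datetime import date, timedelta

import numpy as np
import pytest

import mothtraj as mt
from mothtraj.evaluation import KM_PER_DEG
from mothtraj.exceptions import (
    CalmWindError,
    MetricUndefinedError,
    ValidationError,
)
from mothtraj.trajectory import Trajectory, Waypoint


def _traj(points, night=date(1995, 3, 19), mode="passive", source="S",
          termination="completed", t0="1995-03-19T19:00"):
    """Synthetic trajectory from (lon, lat) pairs at hourly spacing."""
    start = np.datetime64(t0)
    wps = [
        Waypoint(lon, lat, 600.0, start + np.timedelta64(i * 3600, "s"))
        for i, (lon, lat) in enumerate(points)
    ]
    return Trajectory(source, night, 600.0, mode, wps, termination, wps[-1].time)


# -- geodesy ---------------------------------------------------------------


def test_haversine_basics():
    assert mt.haversine_km((0.0, 0.0), (0.0, 0.0)) == 0.0
    assert mt.haversine_km((10.0, 20.0), (10.0, 21.0)) == pytest.approx(111.19, abs=0.01)


def test_haversine_symmetry_and_triangle_inequality():
    rng = np.random.default_rng(3)
    for _ in range(200):
        pts = [(rng.uniform(-100, -90), rng.uniform(20, 35)) for _ in range(3)]
        a, b, c = pts
        assert mt.haversine_km(a, b) == pytest.approx(mt.haversine_km(b, a), rel=1e-12)
        assert mt.haversine_km(a, c) <= mt.haversine_km(a, b) + mt.haversine_km(b, c) + 1e-9


def test_source_centroid_and_printed_distances():
    c = mt.centroid([(s.lon, s.lat) for s in mt.SOURCE_SITES])
    assert c == pytest.approx((-97.966, 26.244), abs=1e-9)
    # independent spherical-law-of-cosines check of the trap distance
    falfurrias = (-98.15, 27.17)
    lon1, lat1, lon2, lat2 = map(math.radians, (*c, *falfurrias))
    loc = 6371.0 * math.acos(
        math.sin(lat1) * math.sin(lat2)
        + math.cos(lat1) * math.cos(lat2) * math.cos(lon2 - lon1)
    )
    assert mt.haversine_km(c, falfurrias) == pytest.approx(loc, abs=1e-6)
    assert mt.haversine_km(c, falfurrias) == pytest.approx(104.6, abs=0.1)


def test_centroid_edge_cases():
    assert mt.centroid([(3.0, 4.0)]) == (3.0, 4.0)
    assert mt.centroid([(-1.0, -2.0), (1.0, 2.0)]) == (0.0, 0.0)
    with pytest.raises(ValidationError):
        mt.centroid([])


def test_bearing_conventions():
    assert mt.bearing_deg((0.0, 0.0), (0.0, 1.0)) == pytest.approx(0.0)
    assert mt.bearing_deg((0.0, 0.0), (1.0, 0.0)) == pytest.approx(90.0)
    fwd = mt.bearing_deg((-98.0, 26.0), (-98.0, 27.0))
    back = mt.bearing_deg((-98.0, 27.0), (-98.0, 26.0))
    assert abs((back - fwd) % 360.0 - 180.0) < 1e-6
    with pytest.raises(CalmWindError):
        mt.bearing_deg((1.0, 1.0), (1.0, 1.0))


# -- path metrics ----------------------------------------------------------


def test_path_length_degenerate_and_additive():
    single = _traj([(0.0, 0.0)])
    assert mt.path_length_km(single) == 0.0
    pts = [(0.0, 0.0), (0.0, 0.5), (0.2, 0.9), (0.5, 1.0)]
    whole = mt.path_length_km(_traj(pts))
    first = mt.path_length_km(_traj(pts[:2]))
    rest = mt.path_length_km(_traj(pts[1:]))
    assert whole == pytest.approx(first + rest, rel=1e-12)
    # invariant under time relabeling
    relabeled = mt.path_length_km(_traj(pts, t0="2001-07-01T19:00"))
    assert relabeled == whole


def test_sdp_point_on_path_and_perpendicular_offset():
    traj = _traj([(0.0, 0.0), (0.0, 1.0)])
    assert mt.sdp_km((0.0, 0.5), traj) == pytest.approx(0.0, abs=1e-9)
    # trap offset 0.1 deg east of the midpoint of a meridional segment
    d = mt.sdp_km((0.1, 0.5), traj)
    assert d == pytest.approx(0.1 * KM_PER_DEG * math.cos(math.radians(0.5)), rel=1e-3)


def test_sdp_clamps_to_segment_end():
    traj = _traj([(0.0, 0.0), (0.0, 1.0)])
    trap = (0.0, 1.5)  # beyond the northern end
    assert mt.sdp_km(trap, traj) == pytest.approx(mt.ptop_km(trap, traj), rel=1e-4)


def test_ptop_picks_nearest_waypoint():
    traj = _traj([(0.0, 0.0), (0.0, 1.0)])
    assert mt.ptop_km((0.05, 0.95), traj) < mt.ptop_km((0.05, 0.95), _traj([(0.0, 0.0)]))
    assert mt.ptop_km((0.0, 1.0), traj) == 0.0


def test_sdp_never_exceeds_ptop_randomized():
    rng = np.random.default_rng(11)
    for _ in range(500):
        n = rng.integers(1, 13)
        lon0, lat0 = rng.uniform(-100, -95), rng.uniform(25, 30)
        steps = rng.normal(0, 0.3, size=(n, 2))
        pts = np.cumsum(np.vstack([[lon0, lat0], steps]), axis=0)[: n + 1]
        traj = _traj([tuple(p) for p in pts])
        trap = (rng.uniform(-101, -94), rng.uniform(24, 31))
        assert mt.sdp_km(trap, traj) <= mt.ptop_km(trap, traj) + 1e-9


def test_single_waypoint_sdp_equals_point_distance():
    traj = _traj([(-98.0, 27.0)])
    trap = (-98.2, 27.3)
    assert mt.sdp_km(trap, traj) == pytest.approx(mt.haversine_km(trap, (-98.0, 27.0)), rel=1e-4)


# -- drift angles ----------------------------------------------------------


def test_drift_angle_identity_mirror_and_antisymmetry():
    ref = _traj([(0.0, 0.1 * i) for i in range(13)])
    assert mt.drift_angle_deg(ref, ref, 12) == 0.0
    east = _traj([(0.02 * i, 0.1 * i) for i in range(13)])
    west = _traj([(-0.02 * i, 0.1 * i) for i in range(13)])
    for dur in (4, 8, 12):
        de = mt.drift_angle_deg(ref, east, dur)
        dw = mt.drift_angle_deg(ref, west, dur)
        assert de > 0 > dw
        assert de == pytest.approx(-dw, abs=1e-9)
        assert mt.drift_angle_deg(east, ref, dur) == pytest.approx(-de, abs=1e-9)


def test_drift_angle_uniform_wind_crab(uniform_field):
    from conftest import NIGHT, RELEASE

    passive = mt.run_trajectory(uniform_field, RELEASE, NIGHT, 600.0,
                                mt.FlightBehavior(), mode="passive")
    behavioral = mt.run_trajectory(uniform_field, RELEASE, NIGHT, 600.0,
                                   mt.FlightBehavior(), mode="behavioral")
    for dur in (4, 8, 12):
        assert mt.drift_angle_deg(passive, behavioral, dur) == pytest.approx(9.195, abs=0.02)
    mirrored = mt.run_trajectory(uniform_field, RELEASE, NIGHT, 600.0,
                                 mt.FlightBehavior(crab_angle=-30.0), mode="behavioral")
    assert mt.drift_angle_deg(passive, mirrored, 8) == pytest.approx(-9.195, abs=0.02)


def test_drift_angle_undefined_pairs_are_excluded():
    ref = _traj([(0.0, 0.1 * i) for i in range(13)])
    short = _traj([(0.01 * i, 0.1 * i) for i in range(5)], termination="domain_exit")
    with pytest.raises(MetricUndefinedError):
        mt.drift_angle_deg(ref, short, 12)
    with pytest.raises(MetricUndefinedError):
        mt.drift_angle_deg(_traj([(1.0, 1.0), (1.0, 2.0)]), ref, 1)  # release mismatch
    values, excluded = mt.drift_angles([ref, ref], [short, ref], durations=(4, 8, 12))
    assert excluded == 2  # the short pair is undefined at 8 and 12 h
    assert len(values) == 4


# -- scheme evaluation and comparison --------------------------------------


def _trap(name, lon, lat, d=date(1995, 3, 20)):
    return mt.TrapRecord(d, name, lon, lat, 5, 3, 1)


def test_evaluate_scheme_direct_hit_and_matching():
    traj = _traj([(0.0, 0.1 * i) for i in range(13)], night=date(1995, 3, 19))
    trap = _trap("hit", 0.0, 0.6)
    ev = mt.evaluate_scheme([traj], [trap], scheme="test")
    assert len(ev.table) == 1
    assert ev.table.loc[0, "sdp_km"] == pytest.approx(0.0, abs=1e-9)
    assert ev.table.loc[0, "ptop_km"] == pytest.approx(0.0, abs=1e-9)
    summ = ev.summary()
    assert set(summ["metric"]) == {"sdp", "ptop"}
    assert (summ["mean_km"] < 1e-9).all()


def test_evaluate_scheme_excludes_unmatched_dates():
    traj = _traj([(0.0, 0.1 * i) for i in range(13)], night=date(1995, 3, 19))
    orphan = _trap("orphan", 0.0, 0.5, d=date(1995, 3, 25))
    with pytest.warns(UserWarning, match="orphan"):
        ev = mt.evaluate_scheme([traj], [_trap("ok", 0.0, 0.5), orphan])
    assert len(ev.table) == 1
    assert ev.n_traps_excluded == 1


def test_evaluate_scheme_sdp_bounded_by_ptop_per_trap(study_runs):
    traps = mt.packaged_trap_table()
    ev = mt.evaluate_scheme(study_runs["behavioral"], traps, scheme="behavioral")
    assert len(ev.table) == 14
    assert (ev.table["sdp_km"] <= ev.table["ptop_km"] + 1e-9).all()


def test_compare_paired_all_positive_differences():
    """A scheme uniformly closer to the traps gives the one-sided minimum p."""
    a = [1.0, 2.0, 3.0, 4.0, 5.0]
    b = [2.0, 3.0, 4.0, 5.0, 7.0]
    comp = mt.compare_paired(a, b, metric="sdp", alternative="less")
    assert comp.n == 5
    assert comp.p_value == pytest.approx(1.0 / 2**5)
    assert comp.mean_a == pytest.approx(3.0)


def test_compare_identical_schemes_reports_no_difference():
    vals = [1.0, 2.0, 3.0]
    comp = mt.compare_paired(vals, vals, metric="ptop")
    assert comp.note is not None and "no difference" in comp.note
    assert comp.p_value == 1.0


def test_compare_schemes_pairs_on_traps():
    traj_near = _traj([(0.0, 0.1 * i) for i in range(13)], night=date(1995, 3, 19))
    traj_far = _traj([(0.5, 0.1 * i) for i in range(13)], night=date(1995, 3, 19))
    traps = [_trap(f"t{i}", 0.0, 0.2 + 0.1 * i) for i in range(6)]
    ev_a = mt.evaluate_scheme([traj_near], traps, scheme="near")
    ev_b = mt.evaluate_scheme([traj_far], traps, scheme="far")
    comp = mt.compare_schemes(ev_a, ev_b, metric="sdp", alternative="less")
    assert comp.n == 6
    assert comp.p_value == pytest.approx(1.0 / 2**6)
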
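"""Forward trajectory integration at fixed flight altitude, with termination
rules and the multi-night / multi-height ensemble design.

A trajectory starts at a release site at the configured take-off time and is
integrated forward with a Heun (predictor-corrector) scheme, sampling the
gridded wind each sub-step and recording a waypoint every full hour.  Flight
stops early when the moth leaves the wind-field domain, the air is colder
than the behavioral minimum, or precipitation exceeds the allowed rate.

Altitude is held constant (metres AGL): migrant moths are released at fixed
flight levels and no vertical motion is modelled.  Positions advance on a
sphere of radius 6371 km, so one degree of latitude is 111,194.9 m.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import date as Date
from typing import Literal, NamedTuple, Optional, Sequence

import numpy as np

from .behavior import FlightBehavior, Mode, ground_velocity
from .exceptions import OutOfDomainError, ValidationError
from .windfield import GridWindField

__all__ = [
    "M_PER_DEG",
    "Waypoint",
    "Trajectory",
    "EnsembleConfig",
    "step",
    "run_trajectory",
    "run_ensemble",
]

EARTH_RADIUS_M = 6_371_000.0
M_PER_DEG = EARTH_RADIUS_M * math.pi / 180.0  # 111,194.9 m per degree

Termination = Literal["completed", "domain_exit", "cold_stop", "rain_stop", "failed"]
Scheme = Literal["heun", "euler"]


class Waypoint(NamedTuple):
    lon: float
    lat: float
    alt: float
    time: np.datetime64


@dataclass
class Trajectory:
    """An hourly-resolved forward flight path with start metadata."""

    source_id: str
    night: Date
    start_height: float
    mode: Mode
    waypoints: list[Waypoint]
    termination: Termination
    termination_time: np.datetime64

    @property
    def release(self) -> Waypoint:
        return self.waypoints[0]

    @property
    def endpoint(self) -> Waypoint:
        return self.waypoints[-1]

    @property
    def duration_h(self) -> float:
        """Hours from release to the last recorded waypoint."""
        delta = self.endpoint.time - self.release.time
        return float(delta / np.timedelta64(1, "h"))


@dataclass
class EnsembleConfig:
    """The full simulation design: sources x nights x release heights.

    The reference study releases from 5 source sites on each of 3 nights at
    5 heights (500-700 m AGL), one take-off time per night, giving 75
    trajectories per modelling scheme.
    """

    sources: Sequence[tuple[str, float, float]]  # (id, lon, lat)
    nights: Sequence[Date]
    heights: Sequence[float]
    mode: Mode
    behavior: FlightBehavior
    field: GridWindField
    dt: float = 60.0  # s
    takeoff_local_time: Optional[str] = None  # defaults to behavior's
    scheme: Scheme = "heun"

    def __post_init__(self) -> None:
        if not (self.sources and self.nights and self.heights):
            raise ValidationError("sources, nights and heights must be non-empty")
        _check_dt(self.dt)

    @property
    def size(self) -> int:
        return len(self.sources) * len(self.nights) * len(self.heights)


def _check_dt(dt: float) -> None:
    if dt <= 0 or abs(3600.0 / dt - round(3600.0 / dt)) > 1e-9:
        raise ValidationError("dt must be positive and divide 3600 s")


def takeoff_time(night: Date, local_time: str) -> np.datetime64:
    """Timestamp of take-off on the evening of ``night`` (naive local clock)."""
    return np.datetime64(f"{night.isoformat()}T{local_time}").astype("datetime64[ns]")


def _advance(lon: float, lat: float, u: float, v: float, dt: float) -> tuple[float, float]:
    """Move (lon, lat) by a velocity (m/s) over dt seconds on the sphere."""
    new_lat = lat + (v * dt) / M_PER_DEG
    new_lon = lon + (u * dt) / (M_PER_DEG * math.cos(math.radians(lat)))
    return new_lon, new_lat


def step(
    lon: float,
    lat: float,
    alt: float,
    t,
    dt: float,
    field: GridWindField,
    behavior: FlightBehavior,
    mode: Mode = "passive",
    carried_heading: Optional[float] = None,
    scheme: Scheme = "heun",
) -> tuple[float, float, Optional[float]]:
    """One integration step; returns (lon', lat', carried_heading').

    Heun predictor-corrector: the velocity at the current point predicts a
    trial position, the velocity there corrects it, and the position advances
    with the mean of the two.  For a spatially and temporally constant wind
    predictor and corrector coincide, so Heun equals explicit Euler exactly.
    Raises :class:`OutOfDomainError` when a required wind sample falls outside
    the field; the caller terminates the flight at the last in-domain position.
    """
    t0 = np.datetime64(t)
    s1 = field.interpolate(lon, lat, alt, t0)
    u1, v1, heading = ground_velocity(s1, behavior, mode, carried_heading)
    if heading is not None:
        carried_heading = heading
    if scheme == "euler":
        new_lon, new_lat = _advance(lon, lat, u1, v1, dt)
        return new_lon, new_lat, carried_heading
    trial_lon, trial_lat = _advance(lon, lat, u1, v1, dt)
    t1 = t0 + np.timedelta64(int(dt), "s")
    s2 = field.interpolate(trial_lon, trial_lat, alt, t1)
    u2, v2, heading2 = ground_velocity(s2, behavior, mode, carried_heading)
    if heading2 is not None:
        carried_heading = heading2
    new_lon, new_lat = _advance(lon, lat, 0.5 * (u1 + u2), 0.5 * (v1 + v2), dt)
    return new_lon, new_lat, carried_heading


def run_trajectory(
    field: GridWindField,
    release: tuple[float, float],
    night: Date,
    start_height: float,
    behavior: FlightBehavior,
    mode: Mode = "behavioral",
    dt: float = 60.0,
    source_id: str = "SRC",
    takeoff_local_time: Optional[str] = None,
    scheme: Scheme = "heun",
) -> Trajectory:
    """Integrate one flight from take-off for up to ``behavior.max_duration`` h.

    Waypoints are the integrator states at exact whole hours (plus the
    release point).  Temperature and precipitation thresholds are checked at
    every sub-step from the interpolated field; a variable absent from the
    field disables the corresponding rule.  Early terminations record the
    reason and time; no waypoint is recorded after a stop condition is met.
    """
    _check_dt(dt)
    lon, lat = float(release[0]), float(release[1])
    alt = float(start_height)
    t0 = takeoff_time(night, takeoff_local_time or behavior.takeoff_local_time)
    if not field.contains(lon, lat, alt, t0):
        raise ValidationError(
            f"release point ({lon}, {lat}, {alt} m) at {t0} is outside the wind field"
        )
    waypoints = [Waypoint(lon, lat, alt, t0)]
    heading: Optional[float] = None
    steps_per_hour = int(round(3600.0 / dt))
    n_steps = int(round(behavior.max_duration * steps_per_hour))
    termination: Termination = "completed"
    termination_time = t0
    for k in range(n_steps):
        t = t0 + np.timedelta64(int(round(k * dt)), "s")
        try:
            sample = field.interpolate(lon, lat, alt, t)
        except OutOfDomainError:
            termination, termination_time = "domain_exit", t
            break
        if sample.temp is not None and sample.temp < behavior.temp_min:
            termination, termination_time = "cold_stop", t
            break
        if sample.precip is not None and sample.precip > behavior.precip_max:
            termination, termination_time = "rain_stop", t
            break
        try:
            lon, lat, heading = step(
                lon, lat, alt, t, dt, field, behavior, mode, heading, scheme
            )
        except OutOfDomainError:
            termination, termination_time = "domain_exit", t
            break
        if (k + 1) % steps_per_hour == 0:
            t_next = t0 + np.timedelta64(int(round((k + 1) * dt)), "s")
            waypoints.append(Waypoint(lon, lat, alt, t_next))
            termination_time = t_next
    return Trajectory(
        source_id=source_id,
        night=night,
        start_height=alt,
        mode=mode,
        waypoints=waypoints,
        termination=termination,
        termination_time=termination_time,
    )


def run_ensemble(config: EnsembleConfig) -> list[Trajectory]:
    """Run the full design: one trajectory per (source, night, height).

    Order is deterministic: sources in the given order, nights ascending,
    heights ascending.  A release outside the field domain yields a
    trajectory marked ``failed`` (release waypoint only); the rest of the
    ensemble is unaffected.
    """
    out: list[Trajectory] = []
    for source_id, lon, lat in config.sources:
        for night in sorted(config.nights):
            for height in sorted(config.heights):
                try:
                    traj = run_trajectory(
                        config.field,
                        (lon, lat),
                        night,
                        height,
                        config.behavior,
                        mode=config.mode,
                        dt=config.dt,
                        source_id=source_id,
                        takeoff_local_time=config.takeoff_local_time,
                        scheme=config.scheme,
                    )
                except ValidationError:
                    t0 = takeoff_time(
                        night,
                        config.takeoff_local_time
                        or config.behavior.takeoff_local_time,
                    )
                    traj = Trajectory(
                        source_id=source_id,
                        night=night,
                        start_height=float(height),
                        mode=config.mode,
                        waypoints=[Waypoint(float(lon), float(lat), float(height), t0)],
                        termination="failed",
                        termination_time=t0,
                    )
                out.append(traj)
    return out
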
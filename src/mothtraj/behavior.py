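"""Self-powered flight behavior of a nocturnal migrant moth.

High-flying noctuid moths are not inert particles: radar studies show they
add an airspeed of roughly 4-5 m/s to the wind and hold a common orientation
offset a fixed *crab angle* to the right of the downwind direction.  This
module parameterizes that behavior and converts a wind sample into the
moth's ground velocity.

Bearing convention: compass degrees, 0 = north, 90 = east.  A positive crab
angle rotates the flight heading clockwise (to the right of downwind) in the
map sense of the northern hemisphere.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Optional

from .exceptions import CalmWindError, ValidationError
from .windfield import WindSample

__all__ = [
    "FlightBehavior",
    "downwind_bearing",
    "flight_vector",
    "ground_velocity",
]

Mode = Literal["passive", "behavioral"]


@dataclass(frozen=True)
class FlightBehavior:
    """Constant-parameter flight model of a migrating moth.

    Defaults are the corn earworm (*Helicoverpa zea*) values: 4.5 m/s
    airspeed, 30 degrees crab to the right of downwind, take-off around
    19:00 local time (about 30 min after sunset in late March), flights of
    up to 12 h at 500-700 m AGL, no flight below 10 degC or in rain.
    """

    airspeed: float = 4.5  # m/s
    crab_angle: float = 30.0  # deg, positive = right of downwind
    takeoff_local_time: str = "19:00"
    max_duration: float = 12.0  # h
    flight_heights: tuple[float, ...] = (500.0, 550.0, 600.0, 650.0, 700.0)  # m AGL
    temp_min: float = 10.0  # degC; flight stops below this
    precip_max: float = 0.0  # mm/h; flight stops above this (any rain)

    def __post_init__(self) -> None:
        object.__setattr__(self, "flight_heights", tuple(self.flight_heights))
        if self.airspeed < 0:
            raise ValidationError("airspeed must be >= 0")
        if not (-180.0 < self.crab_angle <= 180.0):
            raise ValidationError("crab_angle must lie in (-180, 180]")
        if self.max_duration <= 0:
            raise ValidationError("max_duration must be positive")
        if not self.flight_heights or any(h <= 0 for h in self.flight_heights):
            raise ValidationError("flight_heights must be non-empty and positive")


def downwind_bearing(u: float, v: float) -> float:
    """Compass bearing toward which the air moves, in [0, 360).

    (0, 10) is a due-north flow (bearing 0); (10, 0) blows east (bearing 90).
    Calm air has no downwind direction and raises :class:`CalmWindError`;
    the trajectory integrator handles that by carrying the last defined
    heading forward.
    """
    if u == 0.0 and v == 0.0:
        raise CalmWindError("downwind bearing undefined for calm wind")
    return math.degrees(math.atan2(u, v)) % 360.0


def flight_vector(
    u: float,
    v: float,
    behavior: FlightBehavior,
    fallback_heading: Optional[float] = None,
) -> tuple[float, float, Optional[float]]:
    """The moth's self-powered velocity contribution for the current wind.

    Heading is the instantaneous downwind bearing plus the crab angle,
    recomputed every call as the wind turns.  In calm air the caller-held
    ``fallback_heading`` (the most recent defined heading) is used; if none
    exists yet the contribution is suppressed.

    Returns ``(uf, vf, heading)`` where ``heading`` is the flight heading
    actually used, or ``None`` if no heading is defined yet.
    """
    try:
        heading = downwind_bearing(u, v) + behavior.crab_angle
    except CalmWindError:
        if fallback_heading is None:
            return 0.0, 0.0, None
        heading = fallback_heading
    rad = math.radians(heading)
    return (
        behavior.airspeed * math.sin(rad),
        behavior.airspeed * math.cos(rad),
        heading,
    )


def ground_velocity(
    sample: WindSample,
    behavior: FlightBehavior,
    mode: Mode = "behavioral",
    fallback_heading: Optional[float] = None,
) -> tuple[float, float, Optional[float]]:
    """Ground velocity (m/s east, m/s north) of the migrant, plus heading.

    ``passive`` mode treats the moth as an inert particle: ground velocity
    equals the wind.  ``behavioral`` mode adds the crab-angle flight vector
    to the local airflow.  The third return value is the flight heading used
    (carried by the integrator across calm patches); in passive mode it is
    always ``None``.
    """
    if mode == "passive":
        return sample.u, sample.v, None
    if mode != "behavioral":
        raise ValidationError(f"unknown mode {mode!r}")
    uf, vf, heading = flight_vector(sample.u, sample.v, behavior, fallback_heading)
    return sample.u + uf, sample.v + vf, heading
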
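"""Gridded wind fields: data model, interpolation, synthetic generators, NetCDF I/O.

The atmospheric state is a 4-D grid (time, height AGL, latitude, longitude)
of eastward/northward wind components, optionally with air temperature and
precipitation rate.  Real studies obtain such fields from mesoscale weather
models; here they can also be generated synthetically to emulate the synoptic
situations that drive nocturnal insect transport -- most importantly the
southerly nocturnal low-level jet (LLJ), a wind-speed maximum a few hundred
metres above ground that acts as a conveyor belt for high-flying migrants.

Conventions
-----------
* u is the eastward wind component (m/s), v the northward component.
  Wind *direction* is always derived from (u, v), never stored.
* Heights are metres above ground level (AGL), not pressure levels.
* Longitudes are signed degrees east; latitudes degrees north.
* The native time axis is uniform; interpolation supplies sub-step values.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import NamedTuple, Optional

import numpy as np
import xarray as xr

from .exceptions import FieldFormatError, OutOfDomainError, ValidationError

__all__ = [
    "Extent",
    "GridWindField",
    "WindSample",
    "interpolate",
    "make_uniform_field",
    "make_llj_field",
    "make_shear_field",
    "make_rotating_field",
    "read_field",
    "write_field",
]


class WindSample(NamedTuple):
    """Point sample of the gridded atmospheric state."""

    u: float
    v: float
    temp: Optional[float] = None
    precip: Optional[float] = None


@dataclass(frozen=True)
class Extent:
    """Axis specification for synthetic field generators.

    Parameters
    ----------
    lon, lat : (min, max) in degrees; each range must be nonzero.
    heights : metres AGL, strictly increasing, at least two levels.
    start : first timestamp of the field (anything ``np.datetime64`` accepts).
    hours : temporal span of the field in hours.
    n_lon, n_lat : number of horizontal grid nodes per axis.
    time_step_s : native time step in seconds (default hourly, the typical
        output cadence of mesoscale weather models).
    """

    lon: tuple[float, float] = (-104.0, -94.0)
    lat: tuple[float, float] = (25.0, 33.5)
    heights: tuple[float, ...] = (100.0, 300.0, 500.0, 600.0, 700.0, 900.0, 1200.0)
    start: str = "1995-03-19T18:00"
    hours: float = 14.0
    n_lon: int = 21
    n_lat: int = 18
    time_step_s: int = 3600

    def axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        if self.lon[1] <= self.lon[0] or self.lat[1] <= self.lat[0]:
            raise ValidationError("extent must span a nonzero lon/lat range")
        if len(self.heights) < 2:
            raise ValidationError("extent needs at least two height levels")
        lons = np.linspace(self.lon[0], self.lon[1], self.n_lon)
        lats = np.linspace(self.lat[0], self.lat[1], self.n_lat)
        heights = np.asarray(self.heights, dtype=float)
        n_t = int(round(self.hours * 3600 / self.time_step_s)) + 1
        t0 = np.datetime64(self.start)
        times = t0 + np.arange(n_t) * np.timedelta64(int(self.time_step_s), "s")
        return lons, lats, heights, times.astype("datetime64[ns]")


@dataclass
class GridWindField:
    """A 4-D gridded wind field on strictly increasing axes.

    Arrays are indexed ``(time, height, lat, lon)``.  ``temp`` (degC) and
    ``precip`` (mm/h) are optional; when absent the corresponding flight
    termination rules are disabled downstream.
    """

    lons: np.ndarray
    lats: np.ndarray
    heights: np.ndarray
    times: np.ndarray  # datetime64
    u: np.ndarray
    v: np.ndarray
    temp: Optional[np.ndarray] = None
    precip: Optional[np.ndarray] = None

    # lazily built interpolation cache (stacked variables + float time axis)
    _stacked: Optional[np.ndarray] = dc_field(default=None, repr=False, compare=False)
    _times_s: Optional[np.ndarray] = dc_field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.lons = np.asarray(self.lons, dtype=float)
        self.lats = np.asarray(self.lats, dtype=float)
        self.heights = np.asarray(self.heights, dtype=float)
        self.times = np.asarray(self.times).astype("datetime64[ns]")
        self.u = np.asarray(self.u, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if self.temp is not None:
            self.temp = np.asarray(self.temp, dtype=float)
        if self.precip is not None:
            self.precip = np.asarray(self.precip, dtype=float)
        self._validate()

    def _validate(self) -> None:
        for name, ax in (
            ("lon", self.lons),
            ("lat", self.lats),
            ("height", self.heights),
        ):
            if ax.ndim != 1 or ax.size < 2:
                raise ValidationError(f"axis {name!r} must be 1-D with >= 2 nodes")
            if not np.all(np.isfinite(ax)):
                raise ValidationError(f"axis {name!r} contains non-finite values")
            if not np.all(np.diff(ax) > 0):
                raise ValidationError(f"axis {name!r} must be strictly increasing")
        if self.times.ndim != 1 or self.times.size < 2:
            raise ValidationError("time axis must be 1-D with >= 2 nodes")
        steps = np.diff(self.times)
        if not np.all(steps > np.timedelta64(0, "s")):
            raise ValidationError("time axis must be strictly increasing")
        if not np.all(steps == steps[0]):
            raise ValidationError("time axis must have a uniform step")
        shape = (self.times.size, self.heights.size, self.lats.size, self.lons.size)
        for name, arr in self._variables():
            if arr.shape != shape:
                raise ValidationError(
                    f"variable {name!r} has shape {arr.shape}, expected {shape}"
                )
            if not np.all(np.isfinite(arr)):
                raise FieldFormatError(
                    f"variable {name!r} contains missing/non-finite values "
                    "inside the declared domain"
                )

    def _variables(self) -> list[tuple[str, np.ndarray]]:
        out = [("u", self.u), ("v", self.v)]
        if self.temp is not None:
            out.append(("temp", self.temp))
        if self.precip is not None:
            out.append(("precip", self.precip))
        return out

    # -- interpolation -----------------------------------------------------

    def _cache(self) -> tuple[np.ndarray, np.ndarray]:
        if self._stacked is None:
            self._stacked = np.stack([a for _, a in self._variables()], axis=-1)
            self._times_s = self.times.astype("datetime64[s]").astype(float)
        return self._stacked, self._times_s  # type: ignore[return-value]

    def interpolate(self, lon: float, lat: float, z: float, t) -> WindSample:
        """Quadrilinear sample of the field at (lon, lat, z, t).

        Linear in each of the four axes; exact at grid nodes.  Raises
        :class:`OutOfDomainError` outside the axis bounding box -- the signal
        the trajectory integrator turns into a ``domain_exit`` termination.
        """
        stacked, times_s = self._cache()
        ts = np.datetime64(t).astype("datetime64[s]").astype(float)
        i_t, f_t = _locate(times_s, ts, "time")
        i_z, f_z = _locate(self.heights, z, "height")
        i_y, f_y = _locate(self.lats, lat, "lat")
        i_x, f_x = _locate(self.lons, lon, "lon")
        c = stacked[i_t : i_t + 2, i_z : i_z + 2, i_y : i_y + 2, i_x : i_x + 2]
        c = c[0] * (1.0 - f_t) + c[1] * f_t
        c = c[0] * (1.0 - f_z) + c[1] * f_z
        c = c[0] * (1.0 - f_y) + c[1] * f_y
        c = c[0] * (1.0 - f_x) + c[1] * f_x
        vals = iter(c)
        u = float(next(vals))
        v = float(next(vals))
        temp = float(next(vals)) if self.temp is not None else None
        precip = float(next(vals)) if self.precip is not None else None
        return WindSample(u, v, temp, precip)

    def contains(self, lon: float, lat: float, z: float, t) -> bool:
        ts = np.datetime64(t).astype("datetime64[s]").astype(float)
        _, times_s = self._cache()
        return bool(
            self.lons[0] <= lon <= self.lons[-1]
            and self.lats[0] <= lat <= self.lats[-1]
            and self.heights[0] <= z <= self.heights[-1]
            and times_s[0] <= ts <= times_s[-1]
        )

    def equals(self, other: "GridWindField") -> bool:
        """Bitwise equality of axes and data arrays (determinism checks)."""
        if not (
            np.array_equal(self.lons, other.lons)
            and np.array_equal(self.lats, other.lats)
            and np.array_equal(self.heights, other.heights)
            and np.array_equal(self.times, other.times)
        ):
            return False
        mine, theirs = dict(self._variables()), dict(other._variables())
        if mine.keys() != theirs.keys():
            return False
        return all(np.array_equal(mine[k], theirs[k]) for k in mine)


def _locate(axis: np.ndarray, x: float, name: str) -> tuple[int, float]:
    """Bracketing index and fractional offset of ``x`` along an axis."""
    if not (axis[0] <= x <= axis[-1]):
        raise OutOfDomainError(
            f"query {x!r} outside {name} axis [{axis[0]!r}, {axis[-1]!r}]", axis=name
        )
    i = int(np.searchsorted(axis, x, side="right")) - 1
    i = min(max(i, 0), axis.size - 2)
    f = (x - axis[i]) / (axis[i + 1] - axis[i])
    return i, float(f)


def interpolate(field: GridWindField, lon: float, lat: float, z: float, t) -> WindSample:
    """Module-level alias for :meth:`GridWindField.interpolate`."""
    return field.interpolate(lon, lat, z, t)


# -- synthetic generators --------------------------------------------------


def _blank(extent: Extent) -> tuple[np.ndarray, ...]:
    lons, lats, heights, times = extent.axes()
    shape = (times.size, heights.size, lats.size, lons.size)
    return lons, lats, heights, times, np.zeros(shape), np.zeros(shape)


def make_uniform_field(
    u: float,
    v: float,
    extent: Extent = Extent(),
    temp: float = 20.0,
    precip: float = 0.0,
) -> GridWindField:
    """Spatially and temporally constant wind; the simplest test atmosphere."""
    lons, lats, heights, times, U, V = _blank(extent)
    U += u
    V += v
    T = np.full_like(U, temp)
    P = np.full_like(U, precip)
    return GridWindField(lons, lats, heights, times, U, V, temp=T, precip=P)


def make_llj_field(
    base_speed: float,
    jet_max: float,
    jet_height: float,
    jet_sigma: float,
    night_window: tuple,
    extent: Extent = Extent(),
    temp: float = 20.0,
) -> GridWindField:
    """Southerly flow with a Gaussian nocturnal low-level jet.

    Wind is due north (u = 0) with speed

        ``base_speed + (jet_max - base_speed) * exp(-(z - jet_height)^2 /
        (2 jet_sigma^2)) * ramp(t)``

    where ``ramp`` is 1 inside ``night_window = (t_on, t_off)``, 0 outside,
    with 1-hour linear shoulders.  Emulates the 18-24 m/s nocturnal jets near
    925-950 hPa that carry moths several hundred kilometres in a night.
    """
    if jet_sigma <= 0:
        raise ValidationError("jet_sigma must be positive")
    if not (jet_max >= base_speed >= 0):
        raise ValidationError("require jet_max >= base_speed >= 0")
    lons, lats, heights, times, U, V = _blank(extent)
    t_on = np.datetime64(night_window[0]).astype("datetime64[s]").astype(float)
    t_off = np.datetime64(night_window[1]).astype("datetime64[s]").astype(float)
    ts = times.astype("datetime64[s]").astype(float)
    ramp = np.clip(np.minimum((ts - (t_on - 3600)) / 3600.0, ((t_off + 3600) - ts) / 3600.0), 0.0, 1.0)
    gauss = np.exp(-((heights - jet_height) ** 2) / (2.0 * jet_sigma**2))
    speed = base_speed + (jet_max - base_speed) * gauss[None, :] * ramp[:, None]
    V += speed[:, :, None, None]
    T = np.full_like(U, temp)
    P = np.zeros_like(U)
    return GridWindField(lons, lats, heights, times, U, V, temp=T, precip=P)


def make_shear_field(
    lon0: float,
    west_wind: tuple[float, float],
    east_wind: tuple[float, float],
    blend_width: float,
    extent: Extent = Extent(),
    temp: float = 20.0,
) -> GridWindField:
    """Two wind regimes separated by a north-south shear line at ``lon0``.

    West of ``lon0 - blend_width/2`` the field is ``west_wind``; east of
    ``lon0 + blend_width/2`` it is ``east_wind``; in between the components
    blend linearly.  Emulates a westerly/southerly shear line such as the one
    observed along 102 degrees W during the studied migration nights.
    """
    if blend_width <= 0:
        raise ValidationError("blend_width must be positive")
    lons, lats, heights, times, U, V = _blank(extent)
    w = np.clip((lons - (lon0 - blend_width / 2.0)) / blend_width, 0.0, 1.0)
    U += (1 - w) * west_wind[0] + w * east_wind[0]
    V += (1 - w) * west_wind[1] + w * east_wind[1]
    T = np.full_like(U, temp)
    P = np.zeros_like(U)
    return GridWindField(lons, lats, heights, times, U, V, temp=T, precip=P)


def make_rotating_field(
    speed: float,
    omega: float,
    extent: Extent = Extent(
        lon=(-2.0, 2.0), lat=(-2.0, 2.0), heights=(400.0, 600.0, 800.0),
        start="2000-01-01T19:00", hours=8.0, n_lon=3, n_lat=3, time_step_s=60,
    ),
    temp: float = 20.0,
) -> GridWindField:
    """Spatially uniform wind whose direction rotates at ``omega`` rad/s.

    ``u(t) = speed * sin(omega (t - t0))``, ``v(t) = speed * cos(omega (t - t0))``
    with ``t0`` the first time node.  The passive trajectory has the closed
    form ``(x, y) = (S/omega (1 - cos omega T), S/omega sin omega T)`` in local
    metres, which makes this field the integrator-accuracy oracle.  The native
    time step defaults to 60 s so the gridded field tracks the sinusoid
    closely enough for that closed form to apply.
    """
    if speed < 0:
        raise ValidationError("speed must be >= 0")
    lons, lats, heights, times, U, V = _blank(extent)
    ts = times.astype("datetime64[s]").astype(float)
    phase = omega * (ts - ts[0])
    U += (speed * np.sin(phase))[:, None, None, None]
    V += (speed * np.cos(phase))[:, None, None, None]
    T = np.full_like(U, temp)
    P = np.zeros_like(U)
    return GridWindField(lons, lats, heights, times, U, V, temp=T, precip=P)


# -- NetCDF I/O ------------------------------------------------------------

_UNITS = {"u": "m s-1", "v": "m s-1", "temp": "degC", "precip": "mm h-1"}


def write_field(field: GridWindField, path) -> None:
    """Write a field as CF-style NetCDF (classic format, via scipy)."""
    data = {}
    for name, arr in field._variables():
        data[name] = xr.DataArray(
            arr,
            dims=("time", "height", "lat", "lon"),
            attrs={"units": _UNITS[name]},
        )
    ds = xr.Dataset(
        data,
        coords={
            "time": field.times,
            "height": ("height", field.heights, {"units": "m", "positive": "up"}),
            "lat": ("lat", field.lats, {"units": "degrees_north"}),
            "lon": ("lon", field.lons, {"units": "degrees_east"}),
        },
    )
    ref = np.datetime_as_string(field.times[0].astype("datetime64[s]"))
    encoding = {"time": {"units": f"seconds since {ref}", "dtype": "int32"}}
    ds.to_netcdf(path, engine="scipy", encoding=encoding)


def read_field(path) -> GridWindField:
    """Read a CF-style NetCDF wind field; validates axes and completeness."""
    with xr.open_dataset(path, engine="scipy") as ds:
        for dim in ("time", "height", "lat", "lon"):
            if dim not in ds.dims:
                raise FieldFormatError(f"missing required dimension {dim!r}")
        for var in ("u", "v"):
            if var not in ds.data_vars:
                raise FieldFormatError(f"missing required variable {var!r}")
        kwargs = {}
        for var in ("temp", "precip"):
            if var in ds.data_vars:
                kwargs[var] = ds[var].transpose("time", "height", "lat", "lon").values
        return GridWindField(
            lons=ds["lon"].values,
            lats=ds["lat"].values,
            heights=ds["height"].values,
            times=ds["time"].values,
            u=ds["u"].transpose("time", "height", "lat", "lon").values,
            v=ds["v"].transpose("time", "height", "lat", "lon").values,
            **kwargs,
        )
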
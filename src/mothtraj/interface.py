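"""Configuration, packaged fixtures, presets, and report/trajectory writers.

Fixtures shipped with the package:

* the five source sites spanning the citrus belt of the Lower Rio Grande
  Valley (LRGV), the confirmed origin of the pollen-marked moths;
* the trap-catch table of pollen-marked males for 20-22 March 1995.

The ``study_nights`` preset generates a deterministic synthetic wind field
emulating the synoptic situation of those nights: a southerly nocturnal
low-level jet east of a north-south shear line near 102 degrees W on the
first night, weak variable flow on the second, and a stronger southerly jet
on the third.  It stands in for mesoscale-model output, which is not
shipped, so absolute evaluation numbers from it characterize the synthetic
atmosphere -- not the historical one.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field as dc_field
from datetime import date as Date, datetime
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .behavior import FlightBehavior
from .evaluation import ComparisonResult, SchemeEvaluation, TrapRecord
from .exceptions import ValidationError
from .trajectory import EnsembleConfig, Trajectory, Waypoint, run_ensemble
from .windfield import Extent, GridWindField, make_rotating_field, make_uniform_field, read_field

__all__ = [
    "SourceSite",
    "SOURCE_SITES",
    "RunConfig",
    "read_trap_table",
    "packaged_trap_table",
    "load_preset",
    "PRESETS",
    "run_from_config",
    "write_waypoints_csv",
    "read_waypoints_csv",
    "write_trajectories_geojson",
    "write_report",
]


@dataclass(frozen=True)
class SourceSite:
    id: str
    lon: float
    lat: float


#: Pheromone-trap / release sites in the LRGV citrus region.
SOURCE_SITES: tuple[SourceSite, ...] = (
    SourceSite("AG", -97.78, 26.18),  # Adams Garden
    SourceSite("BV", -97.40, 26.14),  # Bay View
    SourceSite("CC", -98.39, 26.33),  # Citrus City
    SourceSite("DN", -98.03, 26.21),  # Donna
    SourceSite("HV", -98.23, 26.36),  # Heald Valley
)


# -- trap table ------------------------------------------------------------


def read_trap_table(path=None) -> list[TrapRecord]:
    """Read a trap-occurrence CSV into validated :class:`TrapRecord` rows.

    Columns: date, name, lon, lat, n_trapped, n_examined, n_pollen.  Lines
    beginning with ``#`` are comments.  With no path, the packaged 1995
    table is loaded.  Rows violating count ordering or with malformed dates
    raise :class:`ValidationError` naming the offending row.
    """
    if path is None:
        ref = resources.files("mothtraj.data") / "trap_catches_1995.csv"
        with resources.as_file(ref) as p:
            return read_trap_table(p)
    df = pd.read_csv(path, comment="#")
    required = {"date", "name", "lon", "lat", "n_trapped", "n_examined", "n_pollen"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"trap table missing columns: {sorted(missing)}")
    records = []
    for i, row in df.iterrows():
        try:
            d = datetime.strptime(str(row["date"]), "%Y-%m-%d").date()
        except ValueError as exc:
            raise ValidationError(
                f"trap table row {i + 1} ({row['name']!r}): malformed date "
                f"{row['date']!r}"
            ) from exc
        try:
            records.append(
                TrapRecord(
                    date=d,
                    name=str(row["name"]),
                    lon=float(row["lon"]),
                    lat=float(row["lat"]),
                    n_trapped=int(row["n_trapped"]),
                    n_examined=int(row["n_examined"]),
                    n_pollen=int(row["n_pollen"]),
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"trap table row {i + 1}: {exc}") from exc
    return records


def packaged_trap_table() -> list[TrapRecord]:
    """The packaged 1995 pollen-marked trap-catch table (14 records)."""
    return read_trap_table(None)


# -- run configuration -----------------------------------------------------


@dataclass
class RunConfig:
    """Everything needed to reproduce a simulation run."""

    field: Mapping  # {"preset": name} | {"path": file} | {"kind": "uniform", ...}
    sources: Sequence[SourceSite]
    nights: Sequence[Date]
    heights: Sequence[float]
    modes: Sequence[str] = ("passive", "behavioral")
    behavior: FlightBehavior = dc_field(default_factory=FlightBehavior)
    takeoff_local_time: str = "19:00"
    dt: float = 60.0
    output: Optional[str] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.modes:
            raise ValidationError("modes must be non-empty")
        for m in self.modes:
            if m not in ("passive", "behavioral"):
                raise ValidationError(f"unknown mode {m!r}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        behavior = FlightBehavior(**raw.get("behavior", {}))
        sources = [SourceSite(**s) if isinstance(s, dict) else SourceSite(*s) for s in raw["sources"]]
        nights = [n if isinstance(n, Date) else datetime.strptime(str(n), "%Y-%m-%d").date() for n in raw["nights"]]
        return cls(
            field=raw["field"],
            sources=sources,
            nights=nights,
            heights=[float(h) for h in raw["heights"]],
            modes=tuple(raw.get("modes", ("passive", "behavioral"))),
            behavior=behavior,
            takeoff_local_time=str(raw.get("takeoff_local_time", "19:00")),
            dt=float(raw.get("dt", 60.0)),
            output=raw.get("output"),
            seed=int(raw.get("seed", 0)),
        )

    def to_yaml(self, path) -> None:
        raw = {
            "field": dict(self.field),
            "sources": [{"id": s.id, "lon": s.lon, "lat": s.lat} for s in self.sources],
            "nights": [n.isoformat() for n in self.nights],
            "heights": list(self.heights),
            "modes": list(self.modes),
            "behavior": {
                "airspeed": self.behavior.airspeed,
                "crab_angle": self.behavior.crab_angle,
                "takeoff_local_time": self.behavior.takeoff_local_time,
                "max_duration": self.behavior.max_duration,
                "flight_heights": list(self.behavior.flight_heights),
                "temp_min": self.behavior.temp_min,
                "precip_max": self.behavior.precip_max,
            },
            "takeoff_local_time": self.takeoff_local_time,
            "dt": self.dt,
            "output": self.output,
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)

    def resolve_field(self) -> GridWindField:
        spec = dict(self.field)
        if "preset" in spec:
            field, _ = load_preset(spec["preset"])
            return field
        if "path" in spec:
            return read_field(spec["path"])
        if spec.get("kind") == "uniform":
            return make_uniform_field(
                float(spec.get("u", 0.0)),
                float(spec.get("v", 10.0)),
                temp=float(spec.get("temp", 20.0)),
            )
        raise ValidationError(f"cannot resolve field spec {spec!r}")


# -- presets ---------------------------------------------------------------

STUDY_NIGHTS: tuple[Date, ...] = (Date(1995, 3, 19), Date(1995, 3, 20), Date(1995, 3, 21))

# per-night (base southerly speed m/s, jet maximum m/s); the middle night is
# weak and variable, the outer nights carry nocturnal jets (observed maxima
# were 18-24 m/s near 925-950 hPa, i.e. roughly 500-700 m AGL here)
_NIGHT_JETS = {0: (6.0, 18.0), 1: (3.0, 3.0), 2: (7.0, 22.0)}
_JET_HEIGHT_M = 600.0
_JET_SIGMA_M = 150.0
_SHEAR_LON = -102.0
_SHEAR_BLEND_DEG = 2.0


def _study_nights_field(resolution: str = "fine") -> GridWindField:
    """Deterministic three-night synthetic atmosphere over Texas.

    ``fine`` approximates mesoscale-model output (0.5 degrees, hourly);
    ``coarse`` approximates a reanalysis archive (about 1 degree, 3-hourly),
    providing the degraded-wind passive scheme of the three-way comparison.
    """
    if resolution == "fine":
        extent = Extent(
            lon=(-104.0, -94.0), lat=(25.0, 33.5),
            heights=(100.0, 300.0, 500.0, 600.0, 700.0, 900.0, 1200.0),
            start="1995-03-19T18:00", hours=62.0, n_lon=21, n_lat=18,
            time_step_s=3600,
        )
    elif resolution == "coarse":
        extent = Extent(
            lon=(-104.0, -94.0), lat=(25.0, 33.5),
            heights=(100.0, 400.0, 700.0, 1200.0),
            start="1995-03-19T18:00", hours=63.0, n_lon=11, n_lat=9,
            time_step_s=3 * 3600,
        )
    else:
        raise ValidationError(f"unknown resolution {resolution!r}")
    lons, lats, heights, times = extent.axes()
    ts = times.astype("datetime64[s]").astype(float)

    gauss = np.exp(-((heights - _JET_HEIGHT_M) ** 2) / (2.0 * _JET_SIGMA_M**2))
    ramps = np.zeros((len(STUDY_NIGHTS), ts.size))
    for n, night in enumerate(STUDY_NIGHTS):
        t_on = np.datetime64(f"{night.isoformat()}T19:00").astype("datetime64[s]").astype(float)
        t_off = t_on + 12 * 3600.0  # 07:00 next morning
        ramps[n] = np.clip(
            np.minimum((ts - (t_on - 3600)) / 3600.0, ((t_off + 3600) - ts) / 3600.0),
            0.0,
            1.0,
        )
    night_sum = ramps.sum(axis=0)

    # east-of-shear (transport) regime
    v_e = np.full((ts.size, heights.size), 2.0) * (1.0 - night_sum)[:, None]
    for n, (base, jet_max) in _NIGHT_JETS.items():
        profile = base + (jet_max - base) * gauss  # (nz,)
        v_e += ramps[n][:, None] * profile[None, :]
    t1_on = np.datetime64(f"{STUDY_NIGHTS[1].isoformat()}T19:00").astype("datetime64[s]").astype(float)
    u_e = 1.0 + ramps[1] * 2.5 * np.sin(2.0 * math.pi * (ts - t1_on) / (8 * 3600.0))  # (nt,)

    # west-of-shear regime: weak westerly flow
    u_w, v_w = 7.0, 0.5
    w = np.clip((lons - (_SHEAR_LON - _SHEAR_BLEND_DEG / 2.0)) / _SHEAR_BLEND_DEG, 0.0, 1.0)

    shape = (ts.size, heights.size, lats.size, lons.size)
    U = u_e[:, None, None, None] * w[None, None, None, :] + u_w * (1.0 - w)[None, None, None, :]
    V = v_e[:, :, None, None] * w[None, None, None, :] + v_w * (1.0 - w)[None, None, None, :]
    U = np.broadcast_to(U, shape).copy()
    V = np.broadcast_to(V, shape).copy()
    TEMP = np.broadcast_to((20.0 - 0.006 * heights)[None, :, None, None], shape).copy()
    PRECIP = np.zeros(shape)
    return GridWindField(lons, lats, heights, times, U, V, temp=TEMP, precip=PRECIP)


def _study_config(field_spec: Mapping) -> RunConfig:
    return RunConfig(
        field=field_spec,
        sources=SOURCE_SITES,
        nights=STUDY_NIGHTS,
        heights=(500.0, 550.0, 600.0, 650.0, 700.0),
        modes=("passive", "behavioral"),
        behavior=FlightBehavior(),
        takeoff_local_time="19:00",
        dt=60.0,
    )


def _uniform_test() -> tuple[GridWindField, RunConfig]:
    # equatorial domain: the flat-metric closed forms for uniform wind hold
    # essentially exactly there, making this the analytic oracle fixture
    extent = Extent(
        lon=(-3.0, 3.0), lat=(-1.0, 8.0),
        heights=(400.0, 500.0, 600.0, 700.0, 800.0),
        start="2000-03-01T18:00", hours=14.0, n_lon=7, n_lat=10,
    )
    field = make_uniform_field(0.0, 10.0, extent, temp=20.0)
    cfg = RunConfig(
        field={"preset": "uniform_test"},
        sources=(SourceSite("SRC", 0.0, 0.0),),
        nights=(Date(2000, 3, 1),),
        heights=(500.0, 550.0, 600.0, 650.0, 700.0),
    )
    return field, cfg


def _rotating_test() -> tuple[GridWindField, RunConfig]:
    omega = 2.0 * math.pi / (12 * 3600.0)  # one rotation per 12 h
    field = make_rotating_field(10.0, omega)
    cfg = RunConfig(
        field={"preset": "rotating_test"},
        sources=(SourceSite("SRC", 0.0, 0.0),),
        nights=(Date(2000, 1, 1),),
        heights=(600.0,),
        modes=("passive",),
        behavior=FlightBehavior(max_duration=6.0),
    )
    return field, cfg


def _study_nights() -> tuple[GridWindField, RunConfig]:
    return _study_nights_field("fine"), _study_config({"preset": "study_nights"})


def _study_nights_coarse() -> tuple[GridWindField, RunConfig]:
    return _study_nights_field("coarse"), _study_config({"preset": "study_nights_coarse"})


PRESETS = {
    "study_nights": _study_nights,
    "study_nights_coarse": _study_nights_coarse,
    "uniform_test": _uniform_test,
    "rotating_test": _rotating_test,
}


def load_preset(name: str) -> tuple[GridWindField, RunConfig]:
    """Deterministic (field, config) pairs for the packaged scenarios."""
    try:
        factory = PRESETS[name]
    except KeyError:
        raise ValidationError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}"
        ) from None
    return factory()


def run_from_config(
    config: RunConfig, field: Optional[GridWindField] = None
) -> dict[str, list[Trajectory]]:
    """Run the configured ensemble for every requested mode."""
    if field is None:
        field = config.resolve_field()
    out = {}
    for mode in config.modes:
        ens = EnsembleConfig(
            sources=[(s.id, s.lon, s.lat) for s in config.sources],
            nights=list(config.nights),
            heights=list(config.heights),
            mode=mode,  # type: ignore[arg-type]
            behavior=config.behavior,
            field=field,
            dt=config.dt,
            takeoff_local_time=config.takeoff_local_time,
        )
        out[mode] = run_ensemble(ens)
    return out


# -- writers ---------------------------------------------------------------

_WP_COLUMNS = [
    "traj_id", "source_id", "night", "height", "mode", "hour",
    "time", "lon", "lat", "alt", "termination",
]


def write_waypoints_csv(trajectories: Sequence[Trajectory], path) -> None:
    """One row per hourly waypoint; deterministic column order and precision."""
    rows = []
    for tid, traj in enumerate(trajectories):
        for hour, wp in enumerate(traj.waypoints):
            rows.append(
                {
                    "traj_id": tid,
                    "source_id": traj.source_id,
                    "night": traj.night.isoformat(),
                    "height": f"{traj.start_height:.1f}",
                    "mode": traj.mode,
                    "hour": hour,
                    "time": np.datetime_as_string(wp.time.astype("datetime64[s]")),
                    "lon": f"{wp.lon:.10f}",
                    "lat": f"{wp.lat:.10f}",
                    "alt": f"{wp.alt:.1f}",
                    "termination": traj.termination,
                }
            )
    pd.DataFrame(rows, columns=_WP_COLUMNS).to_csv(path, index=False)


def read_waypoints_csv(path) -> list[Trajectory]:
    """Rebuild trajectories from a waypoint CSV (inverse of the writer)."""
    df = pd.read_csv(path)
    missing = set(_WP_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"waypoint CSV missing columns: {sorted(missing)}")
    out = []
    for tid, grp in df.groupby("traj_id", sort=True):
        grp = grp.sort_values("hour")
        waypoints = [
            Waypoint(
                float(r["lon"]), float(r["lat"]), float(r["alt"]),
                np.datetime64(r["time"]).astype("datetime64[ns]"),
            )
            for _, r in grp.iterrows()
        ]
        first = grp.iloc[0]
        out.append(
            Trajectory(
                source_id=str(first["source_id"]),
                night=datetime.strptime(str(first["night"]), "%Y-%m-%d").date(),
                start_height=float(first["height"]),
                mode=str(first["mode"]),  # type: ignore[arg-type]
                waypoints=waypoints,
                termination=str(first["termination"]),  # type: ignore[arg-type]
                termination_time=waypoints[-1].time,
            )
        )
    return out


def write_trajectories_geojson(trajectories: Sequence[Trajectory], path) -> None:
    """FeatureCollection of LineStrings, one feature per trajectory.

    A trajectory with a single waypoint (e.g. an immediate stop) is written
    as a degenerate two-point LineString so the collection stays homogeneous.
    """
    features = []
    for tid, traj in enumerate(trajectories):
        coords = [[round(w.lon, 6), round(w.lat, 6)] for w in traj.waypoints]
        if len(coords) == 1:
            coords = coords * 2
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "LineString", "coordinates": coords},
                "properties": {
                    "traj_id": tid,
                    "source_id": traj.source_id,
                    "night": traj.night.isoformat(),
                    "height_m": traj.start_height,
                    "mode": traj.mode,
                    "termination": traj.termination,
                    "n_waypoints": len(traj.waypoints),
                },
            }
        )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh, indent=1)


def write_report(
    outdir,
    evaluations: Iterable[SchemeEvaluation] = (),
    comparisons: Iterable[tuple[str, ComparisonResult]] = (),
    trajectories: Optional[Mapping[str, Sequence[Trajectory]]] = None,
) -> dict[str, Path]:
    """Write per-trap, summary, and trajectory files under ``outdir``.

    Distances are reported to 3 decimals (km) and angles to 2 (degrees);
    empty inputs yield headers-only CSVs.  Returns the paths written.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    per_trap_rows = []
    for ev in evaluations:
        for _, row in ev.table.iterrows():
            per_trap_rows.append(
                {
                    "scheme": ev.scheme,
                    "date": row["date"],
                    "name": row["name"],
                    "lon": row["lon"],
                    "lat": row["lat"],
                    "sdp_km": f"{row['sdp_km']:.3f}",
                    "sdp_traj": row["sdp_traj"],
                    "ptop_km": f"{row['ptop_km']:.3f}",
                    "ptop_traj": row["ptop_traj"],
                }
            )
    per_trap = outdir / "per_trap.csv"
    pd.DataFrame(
        per_trap_rows,
        columns=["scheme", "date", "name", "lon", "lat", "sdp_km", "sdp_traj", "ptop_km", "ptop_traj"],
    ).to_csv(per_trap, index=False)
    paths["per_trap"] = per_trap

    summary_rows = []
    for ev in evaluations:
        for _, row in ev.summary().iterrows():
            summary_rows.append(
                {
                    "kind": "scheme",
                    "label": f"{ev.scheme}:{row['metric']}",
                    "mean": f"{row['mean_km']:.3f}",
                    "sd": f"{row['sd_km']:.3f}",
                    "n": row["n"],
                    "W": "",
                    "p_value": "",
                    "alternative": "",
                }
            )
    for label, comp in comparisons:
        summary_rows.append(
            {
                "kind": "comparison",
                "label": label,
                "mean": f"{comp.mean_a:.3f} vs {comp.mean_b:.3f}",
                "sd": f"{comp.sd_a:.3f} vs {comp.sd_b:.3f}",
                "n": comp.n,
                "W": f"{comp.wilcoxon_W:.1f}",
                "p_value": f"{comp.p_value:.4g}",
                "alternative": comp.alternative,
            }
        )
    summary = outdir / "summary.csv"
    pd.DataFrame(
        summary_rows,
        columns=["kind", "label", "mean", "sd", "n", "W", "p_value", "alternative"],
    ).to_csv(summary, index=False)
    paths["summary"] = summary

    if trajectories:
        for scheme, trajs in trajectories.items():
            gj = outdir / f"trajectories_{scheme}.geojson"
            write_trajectories_geojson(trajs, gj)
            paths[f"geojson_{scheme}"] = gj
            wp = outdir / f"waypoints_{scheme}.csv"
            write_waypoints_csv(trajs, wp)
            paths[f"waypoints_{scheme}"] = wp
    return paths
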
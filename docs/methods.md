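# Methods

## Model and assumptions

`mothtraj` integrates forward flight trajectories of nocturnal insect
migrants over a gridded atmosphere.  Two schemes share one integrator:

* **passive** — the migrant is an inert particle; ground velocity equals
  the interpolated wind.
* **behavioral** — a constant airspeed `a` is added to the wind along a
  heading offset a fixed crab angle `δ` from the instantaneous downwind
  bearing (positive = clockwise, i.e. to the right of downwind in the
  northern-hemisphere map sense).  The heading is recomputed every
  integration step as the wind turns; the model deliberately has no
  temperature- or wind-dependent airspeed, no altitude selection, and no
  take-off/landing flight phases.

Flight is at a fixed altitude AGL: migrants are released at discrete
flight levels and vertical air motion is ignored.  This is an explicit
divergence from 3-D particle models (e.g. HYSPLIT-style vertical motion and
mixing), which are out of scope here; the passive scheme is a fixed-level
advection emulation, not a re-implementation of any particular program.

In calm air the downwind direction is undefined.  The integrator carries
the last defined heading forward; if the very first sample is already calm
the behavioral contribution is suppressed until wind appears.  This avoids
inventing an absolute heading the biology does not license.

## Parameters

| parameter | default | units | meaning |
|---|---|---|---|
| `airspeed` | 4.5 | m/s | self-powered airspeed of the moth |
| `crab_angle` | +30 | deg | heading offset right of downwind |
| `takeoff_local_time` | 19:00 | clock | release time (≈30 min after sunset in late March) |
| `max_duration` | 12 | h | maximum single-night flight |
| `flight_heights` | 500–700 (step 50) | m AGL | release levels |
| `temp_min` | 10 | °C | no flight below this temperature |
| `precip_max` | 0 | mm/h | any rain stops flight |
| `dt` | 60 | s | integration step (must divide 3600) |

The defaults are the corn-earworm values used throughout; all are plain
dataclass fields and YAML/CLI-overridable.

## Numerics

* **Integration** is Heun predictor–corrector.  The rotating-wind oracle
  (closed form `(x, y) = (S/ω·(1−cos ωT), S/ω·sin ωT)`) bounds the error:
  at `dt = 60 s` the 6-h endpoint is within 0.005 % of the analytic value,
  and halving `dt` moves 12-h endpoints on the three-night preset by
  < 0.001 % of displacement (second-order convergence).  An explicit Euler
  scheme is available for comparison.
* **Metric**: local spherical metric with R = 6371 km (111 194.9 m per
  degree; longitude scaled by cos φ).  Adequate below ~35° latitude over
  the ≤ 700 km nightly ranges simulated here.
* **Interpolation** is quadrilinear (linear in lon, lat, height, time),
  exact at grid nodes and for multilinear fields; tested against scipy's
  regular-grid interpolator.  Out-of-domain queries raise a dedicated
  signal which the integrator converts into a `domain_exit` termination at
  the last in-domain position.
* **Termination checks** (temperature, precipitation, domain) run at every
  integration sub-step, not only hourly — stricter and monotone in `dt`.
  Variables absent from a field disable the corresponding rule.  Waypoints
  are integrator states at exact whole hours; nothing is recorded after a
  stop condition is first met, so early-terminated flights simply end at
  their last completed hour.
* **Time** is a naive local clock with a uniform step per field; no DST or
  timezone database is involved.

## Evaluation metrics

* `sdp_km` — trap-to-polyline distance.  Waypoint (vertex) distances are
  great-circle; segment interiors are resolved in a local equirectangular
  projection centred at the trap (< 0.1 % planar error at sub-50 km
  offsets), and the minimum of the two is taken so that SDP ≤ PtoP holds
  identically.  Exact geodesic cross-track formulas could be swapped in.
* `ptop_km` — minimum great-circle distance to the hourly waypoints.
* `drift_angle_deg` — difference of initial great-circle bearings from the
  shared release to each trajectory's waypoint at the stated duration,
  normalized to (−180, 180].  "Direction of migration" is read as the
  *net-displacement* direction, not the instantaneous heading; the angle is
  signed (positive = right of the reference).  Pairs in which either
  trajectory ended before the duration are excluded and counted.
* `path_length_km` — summed great-circle chords between consecutive hourly
  waypoints.  Note this is a chord sum: on the rotating-wind oracle the 6-h
  path is 6 chords of 30° arcs (213.5 km), slightly below the true 216 km
  arc length — an inherent property of hourly sampling, not an integrator
  error.
* Trap matching: a record dated D (morning of collection) is scored against
  trajectories released at take-off on the evening of D − 1.
* "Distance from the source areas" uses the arithmetic-mean centroid of the
  five release sites.  This reproduces the printed rounded distances for
  Falfurrias (105 km) and Rockdale (507 km); the northernmost trap
  (Richland) computes ≈ 647 km against a printed 637 km — the original
  reference convention for that one value is unknown and the discrepancy is
  documented rather than reconciled.

## Wilcoxon signed-rank test

Differences `d = a − b`; zeros dropped (count reported; Pratt's variant is
available), average ranks for tied |d|, `W` = rank sum of positive
differences.  For n ≤ 20 the p-value is exact, from the subset-sum count
recursion over all 2ⁿ sign assignments on doubled (hence integral) ranks;
tests verify it against literal 2ⁿ enumeration and against scipy on
tie-free samples.  For n > 20 a normal approximation is used with the
average-rank tie correction `Σ(t³−t)/48` subtracted from the variance and
a 0.5 continuity correction; at n = 20 it sits within 0.01 of the exact
p-value.  Comparing identical schemes yields all-zero differences; the
scheme-comparison wrapper reports this as "no difference" (p = 1) rather
than an error.

## Synthetic atmospheres

Generators return fully populated 4-D grids (no missing values inside the
domain) with strictly monotone axes and a uniform time step, stored as
(u, v) components — direction and speed are always derived, never stored.
Fields round-trip through CF-style NetCDF (classic format via scipy;
time encoded as integer seconds since the first node).

* `make_uniform_field` — constant wind; the flat-geometry analytic cases.
* `make_llj_field` — southerly flow with a Gaussian jet in height
  (`base + (max − base)·exp(−(z−z₀)²/2σ²)`) gated by a night window with
  1-h linear shoulders; speed is bounded by construction in [base, max].
* `make_shear_field` — two regimes blended linearly across a meridional
  shear line.
* `make_rotating_field` — spatially uniform wind rotating at ω; its native
  time step defaults to 60 s because a 1-h sampling of the sinusoid would
  bias the trapezoidal time interpolation by ~2 %, swamping the integrator
  error the oracle is meant to measure.

The `study_nights` preset composes these ingredients into a deterministic
(seed-free, bitwise reproducible) three-night atmosphere over Texas
(25–33.5° N, 104–94° W, hourly, 7 height levels): night 1 a southerly jet
(peak 18 m/s at 600 m) east of a shear line at 102° W with weak westerlies
west of it; night 2 weak, variable-direction flow; night 3 a stronger jet
(peak 22 m/s).  Temperature is a dry-ish lapse (20 °C − 6 K/km·z), always
above the 10 °C flight threshold, and precipitation is zero — matching the
report that no flights were weather-terminated during the studied nights.
`study_nights_coarse` renders the same formulas at ~1° / 3-hourly
resolution to emulate a reanalysis-grade wind archive, providing the third
scheme (coarse-wind passive) of the three-way comparison.

### What the synthetic atmosphere does and does not show

The preset reproduces the *structure* that matters to the method — jets,
shear, night gating, inter-night contrast — but none of the mesoscale
detail (fronts, terrain, boundary-layer evolution) of real model output.
Passing tests therefore demonstrate that the integrator, behavior model,
metrics and statistics are correct and internally consistent, and that the
qualitative behavioral signatures (rightward drift ≈ 9–10° in steady wind,
~180 km extra distance per full 12-h night, behavioral paths closer to the
observed trap line) emerge as expected.  Absolute SDP/PtoP values and
p-values computed on the preset characterize the synthetic atmosphere
only; they are not estimates of the values obtainable with historical
reanalysis winds.

## Problem sizes

The shipped configuration is the full published design: 5 sources × 3
nights × 5 heights = 75 trajectories per scheme (225 across the three
schemes), 12-h flights at `dt = 60 s`, evaluated against the 14-record
trap table.  The whole pipeline runs in seconds; the test suite's heaviest
check (re-running both fine-field ensembles at `dt = 30 s` for the
convergence bound) completes in under a minute.

## Known limitations

* Single-night flights only; no multi-night relay, no backward
  trajectories, no stochastic dispersion or turbulence.
* Fixed-altitude advection; vertical wind and layer selection ignored.
* The equirectangular segment projection and the local spherical metric
  drift apart from exact geodesy at distances ≳ several hundred km; both
  are documented and swappable.
* The Wilcoxon exact path enumerates sign assignments only (the classic
  null); heavily tied large samples fall back to the corrected normal
  approximation.
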
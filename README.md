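# mothtraj

Forward-trajectory simulation of windborne insect migration, with the
self-powered flight behavior of nocturnal moths, and the statistical
machinery to score simulated flight paths against pheromone-trap captures
of marked migrants.

## The problem

Noctuid moths such as the corn earworm (*Helicoverpa zea*) migrate at
night several hundred metres above ground, riding southerly low-level jets
(LLJs) that can move them more than 600 km before dawn.  Classic air-parcel
trajectory models treat the insects as inert particles.  Radar studies show
they are not: high-flying moths add an airspeed of roughly 4.5 m/s to the
wind and hold a common orientation offset about 30° to the *right* of the
downwind direction (the crab angle).  `mothtraj` implements both model
classes over gridded wind fields and asks, quantitatively, which one better
explains where marked immigrant moths were actually caught.

## The model

A flight released at position **x₀** at take-off time `t₀` and held at a
fixed altitude `z` (metres AGL) advances by the ground velocity

```
v_ground(x, t) = v_wind(x, z, t)                    (passive)
v_ground(x, t) = v_wind(x, z, t) + a·(sin θ, cos θ) (behavioral)
θ = downwind_bearing(v_wind) + δ
```

with airspeed `a = 4.5 m/s` and crab angle `δ = +30°` by default,
recomputed each step as the wind turns.  Integration is Heun
(predictor–corrector) with `dt = 60 s` on a sphere of radius 6371 km;
waypoints are recorded hourly for up to 12 h.  Flight stops early on domain
exit, air colder than 10 °C, or any precipitation.

Evaluation metrics, per trap that caught pollen-marked males on a morning
(matched to the previous evening's releases):

* **SDP** — shortest distance (km) from the trap to any simulated flight
  polyline (moths can land anywhere en route);
* **PtoP** — distance to the nearest simulated *hourly endpoint*;
* **DAH** — signed drift angle between a test and a reference trajectory's
  net-displacement directions after 4, 8 or 12 h;
* **path length** — summed hourly great-circle chords.

Paired scheme comparisons use a Wilcoxon signed-rank test implemented in
the package: exact null distribution by sign-assignment enumeration for
n ≤ 20 (average ranks under ties), tie- and continuity-corrected normal
approximation beyond.

Since the historical reanalysis/mesoscale wind fields are not shipped, the
package includes deterministic synthetic generators — uniform, shear-line,
Gaussian nocturnal LLJ, rotating-wind (an analytic integrator oracle) — and
a three-night `study_nights` preset emulating the March-1995 synoptic
pattern over Texas.

## Worked example

```python
from datetime import date
import mothtraj as mt

field, _ = mt.load_preset("uniform_test")     # uniform 10 m/s southerly
release, night = (0.0, 0.0), date(2000, 3, 1)
passive = mt.run_trajectory(field, release, night, 600.0,
                            mt.FlightBehavior(), mode="passive")
crab30 = mt.run_trajectory(field, release, night, 600.0,
                           mt.FlightBehavior(), mode="behavioral")
end = (crab30.endpoint.lon, crab30.endpoint.lat)
print(mt.haversine_km(release, end))          # 608.2
print(mt.drift_angle_deg(passive, crab30, 12))  # 9.18
```

608.2 km is the closed-form 12-h displacement of a 10 m/s wind plus a
4.5 m/s airspeed at 30° crab (|ground| = 14.078 m/s × 43 200 s), and the
9.2° drift is atan2(2.25, 13.897) — the behavioral track slides east of the
purely wind-borne one.  Running `python examples/04_trap_evaluation.py`
takes this to the full pipeline and prints, for the synthetic study
atmosphere:

```
SDP: behavioral 13.6 +/- 23.8 km vs passive 20.8 +/- 21.6 km; W = 37, one-sided p = 0.179 (n = 14)
PTOP: behavioral 19.2 +/- 21.7 km vs passive 25.7 +/- 20.7 km; W = 33, one-sided p = 0.121 (n = 14)
```

i.e. the behavioral scheme tracks the trap line more closely on this
synthetic atmosphere, though with n = 14 traps the one-sided test does not
reach the 0.05 level here.

The `examples/` directory holds one short narrative script per capability
(analytic oracles, LLJ generation and termination rules, the 75-trajectory
ensemble, trap evaluation).  A thin CLI mirrors the same steps:
`mothtraj genwind`, `mothtraj run`, `mothtraj eval`, `mothtraj report`.

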
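"""A nocturnal low-level jet field, and the flight termination rules.

The jet profile peaks at a chosen height with a Gaussian falloff and
switches on only during the night window -- the 'conveyor belt' that lets
a moth cover several hundred km in one night.  Cold air (< 10 degC) or any
rain stops a flight immediately; leaving the gridded domain does too.
"""

from datetime import date

import mothtraj as mt
from mothtraj.windfield import Extent

ext = Extent(lon=(-100.0, -94.0), lat=(25.0, 33.0),
             heights=(300.0, 450.0, 600.0, 750.0, 900.0),
             start="1995-03-19T18:00", hours=14.0, n_lon=7, n_lat=9)
jet = mt.make_llj_field(base_speed=6.0, jet_max=20.0, jet_height=600.0,
                        jet_sigma=150.0,
                        night_window=("1995-03-19T19:00", "1995-03-20T07:00"),
                        extent=ext)

for z in (450.0, 600.0, 750.0):
    s = jet.interpolate(-97.0, 26.5, z, "1995-03-19T23:00")
    print(f"jet at {z:5.0f} m AGL, 23:00: v = {s.v:5.2f} m/s (u = {s.u:.1f})")

night = date(1995, 3, 19)
for height in (450.0, 600.0):
    traj = mt.run_trajectory(jet, (-97.0, 25.5), night, height,
                             mt.FlightBehavior(), mode="behavioral")
    end = (traj.endpoint.lon, traj.endpoint.lat)
    km = mt.haversine_km((-97.0, 25.5), end)
    print(f"release {height:.0f} m: {km:6.1f} km in {traj.duration_h:.0f} h "
          f"({traj.termination})")

cold = mt.make_uniform_field(0.0, 10.0, ext, temp=5.0)
stopped = mt.run_trajectory(cold, (-97.0, 26.0), night, 600.0,
                            mt.FlightBehavior(), mode="behavioral")
print(f"in 5 degC air: {stopped.termination} after "
      f"{len(stopped.waypoints) - 1} h (moths do not fly below 10 degC)")
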
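"""Suspended-cell stability: why the membrane constraints matter.

Runs the closed spherical meshwork (702 actin nodes, radius 1.25 um) for
60 s twice — with and without the surface-area constraint and cytoplasmic
volume exclusion — and compares the volume drift. Desk-scale version of
the 360-s experiment.
"""

import memskel as mk

p = mk.Params()
T = 60.0

for label, overrides in (
        ("unconstrained", dict(area_constraint=False, volume_exclusion=False)),
        ("area + volume constraints", dict())):
    sc = mk.make_scenario("SUSPENDED_CELL", p, **overrides)
    state, series, events = mk.simulate(sc, p, T=T, seed=3)
    v0, v1 = series.volume.iloc[0], series.volume.iloc[-1]
    # volume drift over the last 20 s, um^3/s
    tail = series[series.time >= T - 20.0]
    import numpy as np
    drift = np.polyfit(tail.time, tail.volume, 1)[0] / 1e9
    print(f"{label:28s}: V(end)/V(0) = {v1 / v0:.4f}   "
          f"dV/dt(last 20 s) = {drift:+.4f} um^3/s   "
          f"attached = {series.percent_attached.iloc[-1]:.1f} %  "
          f"myosin = {int(series.myosin_count.iloc[-1])}")

print()
print("Myosin contraction alone shrinks the suspended cell steadily; the")
print("global surface-area constraint and the hard cytoplasmic volume floor")
print("(85% of the initial volume) arrest the shrinkage and keep more")
print("spectrin edges attached, stabilising the cell shape.")
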
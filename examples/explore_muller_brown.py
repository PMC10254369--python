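"""Map the Müller–Brown surface's reaction network by artificial-force search.

Starting from the deepest basin, directional forces push the walker over the
barriers; each biased walk is relaxed by locally updated planes and its
endpoints deduplicated into the equilibrium-state catalog.  The printed
barriers can be compared against the literature values of the surface
(saddles at -72.249 and -40.665).
"""

import numpy as np

from forcepath import MullerBrown, surface_point
from forcepath.fixtures import FixtureSpec, make_fixture

fixture = make_fixture(FixtureSpec("muller_brown", rng_seed=0))
net = fixture.network

print(f"equilibrium states found: {net.n_eqs}")
for rec in net.eqs:
    x, y = rec.geometry.coordinates[0, :2]
    print(f"  EQ {rec.eq_id}: ({x:+.3f}, {y:+.3f})  E = {rec.energy:9.3f} kJ/mol")

print("\nlowest refined crossing per basin pair (approximate TS energy):")
best = {}
for p in net.paths:
    if p.flag != "ok" or p.endpoints[0] == p.endpoints[1]:
        continue
    key = tuple(sorted(p.endpoints))
    best[key] = min(best.get(key, np.inf), p.ts_energy)
for (i, j), ts in sorted(best.items()):
    fwd = ts - net.eq(i).energy
    print(f"  EQ {i} <-> EQ {j}:  E_TS = {ts:8.3f} kJ/mol  (barrier from EQ {i}: {fwd:6.2f})")
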
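"""Chemical-space cartography of a search trajectory with GTM.

Fits a generative topographic map on every refined frame of the wall-channel
ground-truth search and prints an ASCII energy landscape plus the
exploration-coverage statistic: how much of the occupied map is populated
only by structures discovered after the first 20% / 50% of the search.
"""

import numpy as np

from forcepath.fixtures import FixtureSpec, make_fixture
from forcepath.gtm import coverage_landscape, fit_gtm, property_landscape

fixture = make_fixture(FixtureSpec("wall_channel", rng_seed=0))
records = sorted(fixture.dataset.records, key=lambda r: r.discovery_index)
X = np.stack([r.geometry.coordinates[0, :2] for r in records])
energies = np.array([r.energy for r in records])

model = fit_gtm(X, K=10, M=5, n_iter=40, rng_seed=0)
print(f"EM iterations: {model.training_meta['iterations']}, "
      f"final objective: {model.loglik_trace[-1]:.1f}")

land = property_landscape(model, X, energies)
grid = land.node_values.reshape(10, 10)
print("\nmean energy per latent node (kJ/mol, '....' = unpopulated):")
for row in grid:
    print(" ".join("...." if np.isnan(v) else f"{v:4.0f}" for v in row))

n = X.shape[0]
for frac in (0.2, 0.5):
    cov = coverage_landscape(model, X[: int(frac * n)], X)
    print(f"\nnodes populated only after the first {int(100*frac)}% of the search: "
          f"{100 * cov.extra['new_only_fraction']:.1f}% of the occupied map")
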
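"""Why a learned potential needs a physics-based safeguard.

Trains two surrogates on the first half of the ground-truth search's paths:
a pure kernel model, and a Δ-composed model (biased-but-robust base plus a
learned correction).  Each then powers its own artificial-force search on the
wall-channel system.  The pure model invents low-energy territory beyond the
repulsive wall it never saw ("leaky holes"); the Δ-composed model inherits
the base's wall and stays honest, reproducing the ground-truth yields.
"""

import json

from forcepath.surrogate import ReplayConfig, replay_experiment

report = replay_experiment(
    ReplayConfig(fractions=(0.5,), temperatures=(300.0,), rng_seed=0)
)

y = report["yields"]
print("yields at 300 K after 1 s (product basin, %):")
for name in ("truth", "base", "pure-50", "delta-50"):
    print(f"  {name:9s} {y[name][300.0]:7.2f}")
print("\nleaky-hole flags (stationary points whose true energy exceeds the")
print("search potential's prediction by >100 kJ/mol):")
print(json.dumps(report["leaky_holes"], indent=2, sort_keys=True))
m = report["metrics"]
print("\nfuture-test energy MAE (kJ/mol) on paths never seen in training:")
for name in ("pure-50", "delta-50"):
    print(f"  {name:9s} {m[name]['mae']:7.3f}  (R² = {m[name]['r2']:.3f}, n = {m[name]['n']})")
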
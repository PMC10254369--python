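# forcepath

Desk-scale toolkit for **artificial-force reaction-path-network exploration**
and for studying when machine-learned surrogate potentials can safely power
such a search.

Automated mechanism discovery builds a *reaction path network*: nodes are
equilibrium states (EQs, local minima of the potential energy surface) and
edges are refined reaction paths with forward/backward barriers. The search
adds an artificial force term to the potential so that crossing a barrier
becomes a downhill walk; relaxing each walk with the locally-updated-planes
(LUP) scheme yields an approximate transition state per path. Because almost
the entire cost of a real search is gradient evaluations at the electronic-
structure level, a fast learned surrogate is attractive — but a surrogate
trained only on the geometries a well-behaved search visits knows nothing
about *broken* geometries, and a strong exploration force will happily drag
the search into regions where the model invents low energy ("leaky holes").
`forcepath` reproduces this entire story on analytic toy potentials where
every quantity has an independent oracle.

What is implemented, per module:

* **potentials** — a uniform `evaluate(geometry) -> (energy, gradient)`
  contract; the Müller–Brown surface; Lennard-Jones / Morse / double-well
  pair clusters; deliberately biased "robust base" potentials (the role a
  fast semiempirical method plays in practice); the Δ-composition
  `E = E_base + E_correction + shift`. Units are kJ/mol and Å throughout.
* **descriptors** — pairwise-sorted interatomic-distance descriptors
  (alignment-free, permutation-invariant) and Boltzmann-weighted group
  descriptors, `X_p = Σ_i w_i X_i^p` with
  `w_i ∝ exp(−E_i / k_B T)`, `T = 300 K` by default.
* **afir** — fragment-pair artificial forces
  `±α·ρ(Q)`, `ρ(Q) = Σ ω_ij r_ij / Σ ω_ij`, `ω_ij = ((R_i+R_j)/r_ij)^p`,
  directional forces for 2-D surfaces, path tracing, LUP refinement,
  EQ identification, and deterministic breadth-wise or kinetically navigated
  network exploration.
* **kinetics** — transition-state-theory rates
  `k = (k_B T/h)·exp(−ΔΔG/RT)` on the refined barriers, the stiff
  master-equation oracle, **rate-constant-matrix contraction** (fast
  bidirectional equilibria are merged into Boltzmann-weighted superstates,
  the small contracted system is propagated exactly), yields, and
  population-based kinetic navigation.
* **surrogate** — kernel-ridge models on the descriptors, *future-oriented*
  path-wise train/validation/test splitting (models are always scored on
  paths discovered later than anything they trained on), energy MAE/RMSE/R²
  metrics, leaky-hole scanning, and the end-to-end replay experiment
  (truth vs biased base vs pure vs Δ-composed surrogates).
* **gtm** — generative topographic mapping (EM-trained 2-D manifold) with
  energy, class, and exploration-coverage landscapes.
* **fixtures** — the deterministic toy-system catalog (Müller–Brown, a
  two-isomer Morse-type trimer, the LJ₇ cluster, and the two-basin
  `wall_channel` surface whose removable outer wall is the robustness
  harness), plus random detailed-balance rate networks.

## Worked example

`examples/delta_learning_replay.py` trains a pure kernel model and a
Δ-composed model on the first half of the ground-truth search's paths, lets
each power its own search on the wall-channel system, and compares kinetics:

```
yields at 300 K after 1 s (product basin, %):
  truth       99.19
  base         3.66
  pure-50     98.88
  delta-50    99.19

leaky-hole flags (stationary points whose true energy exceeds the
search potential's prediction by >100 kJ/mol):
{
  "base": 0,
  "delta-50": 0,
  "pure-50": 10
}

future-test energy MAE (kJ/mol) on paths never seen in training:
  pure-50    85.213  (R² = -45.561, n = 105)
  delta-50    1.231  (R² = 0.993, n = 105)
```

Reading: the biased base alone gets the thermodynamics wrong (3.7% yield vs
99.2% truth), and the pure surrogate — although its yield happens to land
close — walks into 10 leaky holes beyond the wall it never sampled, which is
why its future-test error explodes (negative R² means worse than predicting
the mean). The Δ-composed model keeps the base's repulsive wall as a
safeguard, flags nothing, and reproduces the truth yields to 0.01 points.

Other examples: `explore_muller_brown.py` (network recovery: 3 EQs, barriers
within 0.25% of the saddle catalog), `kinetics_yields.py` (contraction vs
stiff ODE), `descriptor_basics.py`, `gtm_landscape.py` (energy landscape and
exploration coverage of a search trajectory).

There is also a thin CLI over the same library calls:

```bash
forcepath fixture --system wall_channel --seed 0 --out fx/
forcepath kinetics fx/network --T 300 --t 1.0 --method rcmc
forcepath train --data fx/dataset.xyz --split 0.5 --mode delta --system wall_channel --out model.json
forcepath replay --system wall_channel --seed 0 --out report/
forcepath map --data descriptors.csv --property energies.csv -K 15 --seed 3 --out map/
```

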
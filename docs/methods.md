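# Methods

This note records the models, algorithms, numerical choices, and the scope
of the synthetic systems, in the package's own terms.

## Potentials and units

All energies are kJ/mol, all lengths Å, rates 1/s, temperatures K. Every
potential — analytic ground truths, artificial-force bias terms, and trained
surrogates — implements one contract: `evaluate(geometry)` returns the
energy and the analytic Cartesian gradient. This contract is also the
adapter seam for a real electronic-structure or semiempirical backend: any
object with the same method can power the search unchanged.

Shipped ground truths:

* **Müller–Brown**: the standard four-Gaussian parameterization, loaded from
  a versioned constants file (`data/muller_brown.json`) so oracle-derived
  stationary points are bit-reproducible. Note that the fourth term's
  quadratic form is positive definite: the surface *rises* far from the
  wells, so it is globally confining (its exponent is capped at 500 to keep
  far-field probes finite). Minima at (−0.558, 1.442), (0.623, 0.028),
  (−0.050, 0.467); saddles at −72.249 and −40.665 kJ/mol, recovered here by
  a dense-grid + Newton oracle.
* **Pair clusters**: sums of Lennard-Jones, Morse, or Morse+outer-Gaussian
  ("double-well") pair terms keyed by unordered element pairs. Translation,
  rotation, and identical-atom permutation invariance hold by construction;
  every pair kind diverges (LJ) or rises to a very large finite wall (Morse,
  `D·e^{2ar₀}`) at short range.
* **Surface wells**: Gaussian basins on a 2-D plane plus an optional radial
  outer wall `H·max(0, ρ−R)⁴` (C³-smooth hinge). Surface systems are
  represented as single-pseudo-atom geometries; the z coordinate is inert.

**Biased base potentials** model a fast-but-inaccurate method: well depths
scaled and equilibrium distances shifted per pair (clusters) or per well
(surfaces), with scales required positive so repulsive walls survive. On the
trimer fixture's 563-geometry audit set the default bias (depth ×0.85,
r₀ +0.03 Å) produces a mean absolute deviation of ≈29 kJ/mol from the truth
— the size of error for which a learned correction is worthwhile but the
base's asymptotic physics still matters. The wall-channel base instead
under-binds the product well (×0.72), inverting the reaction thermodynamics
while keeping barriers crossable: its equilibrium yield is small and rises
with temperature.

**Δ-composition**: `E_total = E_base + E_correction + shift`, gradients
additive, exactly. Constant alignment shifts between potentials are fitted
by least squares on a reference geometry set (the mean energy difference).

## Descriptors

A structure's descriptor is all N(N−1)/2 interatomic distances, bucketed by
the unordered element pair of their endpoints, sorted ascending within each
bucket, and concatenated with buckets in lexicographic (Z_small, Z_large)
order. Invariance to rigid motions and identical-atom permutation is exact;
no alignment is ever needed. Descriptors compare only across identical
stoichiometry — a mismatch raises instead of padding.

Conformer groups are summarized by the Boltzmann-weighted sum of member
descriptors with `w_i ∝ exp(−E_i/k_B T)` (energies relative to the group
minimum; default T = 300 K). The lowest-energy member always carries the
largest weight, so group projections land next to their most stable
conformer on any map.

For gradients through the descriptor the sorting permutation is frozen at
the evaluation point; this is valid almost everywhere, with kinks only where
two same-label distances tie. 2-D surface systems use the raw (x, y)
coordinates as their feature vector, since a single-point system has no
interatomic distances.

## Artificial-force search

For atomic clusters the bias between fragments A and B is `±α·ρ(Q)` with

    ρ(Q) = Σ_{i∈A,j∈B} ω_ij r_ij / Σ ω_ij,   ω_ij = ((R_i+R_j)/r_ij)^p,

covalent-radius weights, `p = 6`, and `α = γ / r̄₀` where γ is the model
collision energy and r̄₀ the mean covalent contact distance of the fragment
pair. `pull` adds +α·ρ (minimization draws the fragments together), `push`
adds −α·ρ. For 2-D surfaces the analogue is a constant in-plane force of
magnitude γ per unit length along each of `n_directions` compass directions.

**Tracing** minimizes potential + bias from an EQ with a normalized
steepest-descent walk (step 0.02 Å, per-step backtracking) so the recorded
frames form a continuous path; a collapsed line search means the walk sits
at a biased minimum and a quasi-Newton polish finishes it. Walks that do not
converge within 4000 steps are runaway (dissociation or model-collapse
channels): they are kept, flagged `incomplete`, and excluded from kinetics.
The raw walk is truncated at its first arrival in the endpoint's basin —
biased walks may overshoot through the product into outer walls, and those
excursions are not part of the reaction path.

**LUP refinement**: frames are resampled to equal arc length (default 31,
21 for the smaller surface fixtures); each sweep displaces every interior
frame downhill within the hyperplane orthogonal to the central-difference
tangent, with per-frame backtracking so the descent stage never raises a
frame, then redistributes to equal arc length; sweeps stop when the largest
displacement falls below 1e−4 Å (cap 80–100 sweeps depending on fixture).
Endpoints are re-minimized unconstrained. The approximate-TS energy is
parabolic-interpolated through the three frames around the discrete maximum:
the discrete maximum alone undershoots the continuous crossing energy by
O(Δs²), which matters for small barriers. On the Müller–Brown system the
refined barriers agree with the independent saddle catalog to better than
0.25% in both directions.

**EQ identity**: a minimized candidate (gradient max-norm ≤ 1e−4) matches an
existing EQ iff its descriptor-space Euclidean distance is < 0.1 Å *and*
its energy differs by < 1 kJ/mol; otherwise it is registered with the next
discovery index. An optional per-schedule energy ceiling discards endpoints
relaxing above it — the dissociated/plateau channels a practical search
prunes (−20 kJ/mol for Müller–Brown whose plateau sits near 0; −150 for the
trimer whose single-H dissociation sits near −90; none for the wall system,
whose spurious-plateau endpoints are precisely what the robustness harness
must register).

**Exploration** expands one EQ at a time — FIFO by discovery order, or, with
kinetic navigation, the unexpanded EQ carrying the largest population in a
contracted kinetic simulation started from the seed. All scheduled forces
are applied per expansion; refined paths are deduplicated only when their
energy profiles are identical to 1e−9. Everything is deterministic given the
exploration seed; identical runs serialize to byte-identical network JSON.

## Kinetics

Rates are transition-state theory with transmission coefficient 1 on
electronic-energy barriers: `k = (k_B T/h)·exp(−ΔΔG/RT)`, with
`ΔΔG_fwd = E(TS) − E(from)` clamped to at least the endpoint energy gap.
The `ddG` argument is itself the hook for free-energy corrections. Parallel
paths add their rates; self-loops and flagged paths are excluded.

The master equation `dp/dt = Kᵀp` is solved two ways:

* **Stiff ODE oracle**: Radau with rtol 1e−6 / atol 1e−9 (tighter absolute
  tolerances push the error control onto sub-1e−10 population components of
  a system whose eigenvalues span ~12 decades and can stall the stepper;
  the defaults resolve populations to ~1e−6 against a matrix-exponential
  reference). Conservation is enforced by projection; a raw drift above
  1e−5 raises.
* **Rate-constant-matrix contraction**: the fastest eligible process is
  merged into a superstate whose members carry internal Boltzmann weights,
  with outgoing rates combined by those weights. A process is eligible only
  if *both* directional effective rates exceed `contract_factor`/t (default
  25 — residual non-equilibration e^−25) *and* it is ≥ 20× faster than any
  competing escape from the states being merged. One-way drains and flows
  mediated by slow uphill links are deliberately left uncontracted: merging
  them assigns Boltzmann weight that the true dynamics cannot deliver within
  the window. The contracted (possibly still stiff) master equation is then
  propagated exactly by a matrix exponential and superstates expanded back.
  Across 200 random 15-state detailed-balance networks (barriers 5–80
  kJ/mol) the worst population deviation from the ODE route is ≤ 8e−4.

Kinetic navigation scores unexpanded EQs by contracted-simulation population
(flux-based scores would be an alternative; population is the simpler,
documented choice).

## Surrogates

The learned term is kernel ridge regression with an RBF kernel on the
descriptors — deterministic, exactly differentiable, and small enough that
every study here runs in seconds; the fit/predict contract is architecture-
agnostic, so a neural model can stand behind the same interface. Pure mode
regresses total energies; delta mode regresses residuals over the biased
base and predicts base + correction. Targets are centered; training is
energy-only by default (gradient errors are reported but not trained on).
Hyperparameters (length scale as multiples {0.25, 0.5, 1, 2} of the median
pairwise descriptor distance; ridge strengths {1e−7, 1e−6, 1e−5}) are
selected on the validation MAE. The ridge floor matters beyond accuracy:
near-singular interpolants carry ±1e5-scale cancelling coefficients whose
huge high-order derivatives make even the *finite-difference check* of the
(correct) analytic gradient unstable at narrow steps.

**Future-oriented splitting**: paths sorted by discovery index; the earliest
`fraction` of paths form train∪validation, split path-wise (no path's frames
ever straddle the two; when the early set has ≥2 paths at positive
`val_ratio`, at least one is held out so model selection always runs); all
later paths are the test set. Metrics are MAE, RMSE, and R² (which may be
negative — a model extrapolating into invented territory is worse than
predicting the mean, and the replay reproduces exactly that signature).

**Leaky-hole scan**: every EQ and approximate TS of a surrogate-powered
network is re-evaluated with the truth; points where
`E_truth − E_predicted > 100 kJ/mol` are flagged, sorted by discrepancy.

**Replay experiment** (`wall_channel`, seeds fixed): ground-truth search →
future splits at fractions {0.2, 0.5, 0.8} → pure and Δ-composed fits →
surrogate-powered searches → contraction kinetics at {250, 300, 350} K for
1 s. The reproduced pattern: the pure model always leaks beyond the wall it
never sampled (at 20% training its yields collapse to 0%); every Δ-composed
model flags nothing and matches the truth yields to hundredths of a point
at fractions ≥ 0.2 on this small system; the biased base alone yields a few
percent, rising with temperature, exactly the signature of an equilibrium
with inverted thermodynamics.

## GTM

Standard EM-trained generative topographic mapping: a K×K latent grid in
[−1,1]² (default K=15) mapped through an M×M grid of RBFs (default M=8,
common width 1.0 × center spacing) with a Gaussian weight prior
(reg = 1e−3). Columns are standardized internally (constant columns
dropped); initialization is deterministic PCA (sign-fixed eigenvectors), so
`n_iter=0` is a reproducible reference state. The recorded objective is the
*penalized* log-likelihood — the quantity MAP-EM actually ascends — and is
asserted non-decreasing on every fit. β is initialized from the larger of
the third data eigenvalue and the half inter-node distance squared.

`reconstruction_rms` measures the orthogonal reconstruction error: nearest
point on the continuous manifold (fine latent grid + damped Gauss–Newton),
residual projected off the local tangent plane — the PCA-style notion of
reconstruction. For noise-free data on a 2-D affine plane in 20-D the
manifold lies exactly in the plane and the error is ~1e−7. In-plane coverage
of the data hull is a density property and deliberately not part of this
metric.

Landscapes color latent nodes by responsibility-weighted property means
(energy), class fractions, or old/new occupancy; a node is "populated" above
a cumulated responsibility of 1e−3. The coverage summary is the fraction of
populated nodes holding only new structures; on the wall-channel search the
first 50% of discovered frames leaves strictly less new-only territory than
the first 20%, the expected saturation of chemical-space coverage.

## The synthetic systems, and what passing tests do and do not show

The fixtures emulate the *mechanistic* situation of a real search — basins,
barriers, discovery order, training bias away from broken geometries, a
repulsive wall the data never crosses — not chemistry. Problem sizes (2-D
surfaces, 3–7 atoms, tens of paths, ≤15-state rate networks, ≤800 training
points) are chosen so each experiment has an exact or near-exact oracle and
the whole study reruns in minutes. The trimer's "two isomers" require a
double-well pair term: with single-well pair potentials a linear triatomic
is a saddle, not a minimum. Passing the replay shows that the Δ-safeguard
logic, the splitting discipline, and the kinetics pipeline behave as
designed under these conditions; it says nothing about the accuracy of any
particular learned architecture on real electronic-structure data, about
dipoles or charges (stored dipoles in external records are read and
ignored), or about periodic systems.

## Known limitations

* The sorted-distance descriptor's gradient has kinks at distance ties;
  the kernel model inherits them.
* Contraction leaves one-way drains to the exact coarse propagator; on
  networks dominated by irreversible cascades it therefore contracts little
  (correctness is preserved; only the speed advantage shrinks).
* The wall-channel yield matcher labels EQs by proximity to the reference
  basins; surrogate searches that relocate a basin by more than the basin
  radius would need a descriptor-based matcher.
* Single-model variance/uncertainty hooks are not implemented; the
  robustness safeguard is the base potential, not an uncertainty estimate.
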
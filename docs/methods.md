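# Methods

## The two-state model

All thermodynamics derive from the Becktel–Schellman stability curve in
the folding→unfolding direction, with ΔH_m and ΔC_p constant in
temperature:

    ΔG_u(T) = ΔH_m (1 − T/T_m) + ΔC_p [(T − T_m) − T ln(T/T_m)]

so ΔG_u(T_m) = 0, ΔG_u > 0 below the midpoint, and ΔS_m = ΔH_m/T_m.  The
folded fraction is f(T) = 1/(1 + K_u) with K_u = exp(−ΔG_u/RT).  The gas
constant is fixed package-wide at R = 1.9872×10⁻³ kcal/mol/K; the
internal unit system is Å / kcal/mol / ns / K (folding times in µs).

The model is strictly two-state: no intermediate populations, no sloped
native/denatured baselines.  Multi-state fits are out of scope.

## Synthetic data generator

The generator (`foldtherm.synth`) produces data whose statistics match
what the analysis stages expect from real replica-exchange and
constant-temperature simulations of a small two-state folder, with the
truth known exactly.  Defaults are the conditions of the FSD-1 study
system: CD-derived thermodynamics T_m = 315 K, ΔH_m = 10.4 kcal/mol,
ΔC_p = 120.7 cal/mol/K, and simulation-derived kinetics ΔG* = 0.9
kcal/mol with a length-scaled prefactor A = 0.56 µs.

* **Energies** are two-component Gaussian mixtures: state drawn
  Bernoulli(f(T)), energy N(μ_state, σ_state).  The native mean is held
  constant (μ_N = −100 kcal/mol, an arbitrary offset that cancels in all
  fluctuation quantities) and the whole temperature dependence of the
  inter-state gap is placed in the denatured state,
  μ_D − μ_N = ΔH_m + ΔC_p (T − T_m) — the minimal choice that makes the
  fluctuation heat capacity peak at the transition.  Intra-state widths
  default to σ_N = σ_D = 3 kcal/mol, giving a native-baseline C_p of
  ≈ 45 cal/mol/K, small against the transition peak.
* **Order parameters** emit N(2.0, 0.5) Å in the native state and
  N(7.0, 1.5) Å in the unfolded state — the two basins of the folding
  free-energy surface of a 28-residue protein along whole-chain Cα-RMSD.
  Overlapping emissions are permitted but flagged in series metadata.
* **Kinetics** are a two-state Markov chain with k_f = e^(−ΔG*/RT)/A and
  k_u = k_f·K_u(T).  Detailed balance ties the rates to the
  thermodynamics, so the stationary native occupancy equals f(T) and the
  Kramers time 1/k_f and the trajectory-count estimator agree by
  construction.  Dwell times are geometric with per-step switching
  probability 1 − e^(−k·dt), generated run-by-run (exact for the
  discrete chain, cost proportional to the number of transitions).
* **Replica-exchange-style datasets** draw the state i.i.d. per sample
  rather than running the chain: exchange decorrelates equilibrium
  sampling, and at a 2 ps save interval the chain's µs-scale dwells
  would leave each temperature stuck in one state, which is not what
  demultiplexed REMD data look like.  Constant-temperature trajectories
  use the full chain.
* **Seed policy**: one master seed; each series derives its generator
  from a fixed hash of (seed, temperature, series kind), so any series
  regenerates byte-identically in isolation.

What the generator does *not* emulate: atomistic energetics, correlated
multi-dimensional order parameters, non-exponential dwell distributions,
intermediates, or exchange-induced autocorrelation.  Tests passing on
synthetic data therefore validate the estimators and their
book-keeping, not force-field realism.

## Estimators and numerical choices

* **Melting curves**: folded fraction = mean of the 0/1 indicator per
  temperature; classification is strict (`value < cutoff` is folded;
  a value exactly at the cutoff is unfolded).  Errors come from block
  averaging: contiguous equal blocks (remainder truncated), error =
  sd(block means)/√n_blocks; 2 blocks for errors, 5 for convergence
  checks.
* **Van't Hoff fit**: weighted nonlinear least squares of f(T).  Initial
  values: T_m from the interpolated 0.5-crossing, ΔH_m from the midpoint
  slope via df/dT|Tm = −ΔH_m/(4RT_m²), ΔC_p = 0.  Block errors act as
  weights with a floor of 0.01 on fraction errors so noiseless points do
  not get infinite weight.  Standard errors come from the fit
  covariance.  A curve with no 0.5-crossing is still fit but flagged
  `extrapolated_tm`.
* **Heat capacity**: unbiased (n−1) variance over RT²; excess profile
  subtracts the absolute value at the lowest sampled temperature (the
  native-state baseline is hard to resolve when the profile still slopes
  at the cold end, so the coldest point defines it); denaturation
  enthalpy by the trapezoidal rule over a user window, default windows
  being the flanking local minima of a 5-point-smoothed excess profile.
* **Cutoff derivation**: two-component Gaussian mixture by EM (50
  restarts, fixed seed); the cutoff is the equal-posterior point between
  the component means.  Degenerate fits error out as "unimodal": a
  component weight below 0.02, means closer than a quarter of the pooled
  sd, or — the binding check in practice — no density valley between the
  components (on unimodal data EM splits the mode in two and the
  posterior crossing lands near the peak, not in a gap).
* **Superposition**: optimal least-squares rigid-body fit
  (proper rotation only) via `scipy`'s `align_vectors`.  Segment RMSDs
  superpose on the same selection they evaluate; superposing globally
  and evaluating locally is available as an option.
* **Clustering**: greedy neighbor-count clustering on the pairwise RMSD
  matrix.  A distance exactly at the cutoff counts as a neighbor; a
  structure is not its own neighbor; ties in neighbor count resolve to
  the lowest index.  Cluster sizes are non-increasing by construction.
* **Free-energy profiles**: F = −RT ln(bin fraction), min-shifted to 0;
  empty bins are NaN, never zero.  The barrier is the maximum between
  the two basin minima, measured from the folded-basin minimum; it must
  exceed both minima (a monotone stretch between the basins is an
  error), and a plateau resolves to its first bin.
* **Folding events**: earliest t₀ with every sample of
  [t₀, t₀ + 30 ns] strictly below 3.0 Å (both defaults configurable).
* **Count estimator**: τ = M·t/m with uncertainty τ/√m from Poisson
  counting (this simple propagation also reproduces the conventional
  ±7 µs quoted for 2 events in 20 µs of sampling); m = 0 yields a
  censored lower bound M·t, and the flag survives friction rescaling.
  A maximum-likelihood exponential fit with censoring was considered
  and rejected as the default: with single-digit event counts it adds
  model assumptions without reducing the dominant √m noise.
* **Kramers errors**: first-order propagation δτ = τ·δΔG*/(RT).
* **P_fold**: Wilson 95% interval (better coverage than Wald at n = 40);
  transition-state membership = interval contains 0.5, a sharper rule
  than "about half folded".

## Toy replica-exchange engine

One-dimensional overdamped Langevin dynamics (Euler–Maruyama,
x ← x − V′(x)dt/γ + √(2RT dt/γ)·ξ) on the double well
V(x) = h(x² − 1)², with Metropolis swaps of neighboring ladder
temperatures every `exchange_interval` steps on an alternating even/odd
pair schedule, and replica↔temperature records that form a bijection at
every sample.  The 3N-dimensional dynamics of a real protein is out of
scope; one dimension suffices to exercise ladder design, exchange
bookkeeping, demultiplexing and barrier recovery.  One consequence: with
a single degree of freedom the energy distributions of neighboring
temperatures overlap strongly, so exchange acceptance stays high
(≈ 95% on the default ladder) — the ~20% acceptance typical of all-atom
REMD is a property of high-dimensional energetics and cannot be
reproduced by spacing or time-step choices here.  The engine reports
per-pair acceptance so ladder experiments remain auditable.

Integration diverging beyond |x| > 10³ raises an error naming the time
step.  Default dt = 0.01 keeps the Euler scheme stable for h = 2
(stability bound dt < 2γ/max V″ ≈ 0.125) with discretization bias on
the recovered barrier of order 0.05–0.1 kcal/mol, inside the 0.2
kcal/mol validation band.

## Problem sizes

Chosen so the statistical error of each estimator sits comfortably
inside its validation band: 5×10⁴ samples per temperature for
melting-curve round trips (binomial error ≈ 0.002), 10⁵ draws for
moment checks of the energy mixture, 3×10⁵ engine steps (8 replicas,
sampled every 10) for barrier recovery, 40 chains of 1 µs for the
count-vs-Kramers consistency loop, and 500 binomial replicates for
Wilson-interval coverage.

## Known limitations

* The helix-component cutoff (3.7 Å) is taken as a configuration default;
  unlike the other components it is not reproduced by the bimodal rule
  on this package's synthetic data, and helix melting fits near the hot
  end of the ladder extrapolate more than they interpolate.
* The excess-Cp peak of the synthetic model does not sit exactly at T_m:
  the inter-state gap grows with T and the 1/T² factor skews the peak a
  few kelvin upward.  The tests therefore validate the peak against a
  dense scan of the closed-form mixture heat capacity, not against T_m.
* Free-energy barriers from histograms carry binning bias of order
  RT·(bin width · curvature); the default 0.1-unit bins keep it below
  0.05 kcal/mol on the toy well.
* The trajectory-count estimator is biased upward when the run length is
  not short relative to the folding time (events censored at the window
  end); the consistency test only asserts agreement with Kramers within
  a factor of two for this reason.
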
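# Methods

## Model

The process is continuous-time SIS on a simple undirected graph with
adjacency matrix A. Node i, while infected, recovers at Poisson rate δᵢ
and transmits along each incident edge (i, j) at Poisson rate λᵢⱼ. Two
spreading schemes are supported:

- **uniform**: λᵢⱼ = λ on every edge (standard SIS with heterogeneous
  recovery);
- **contact process**: λᵢⱼ = λ/kᵢ, so each infected node spends a total
  transmission effort λ regardless of its degree.

All rates are in inverse time units; time is measured in units of the
mean infectious period when δ has unit mean. Multiplying every rate
(δ and λ) by a constant only rescales time, which the test suite checks
bit-exactly.

## Recovery-rate scenarios

- `homogeneous_rates(n, delta)` — the standard SIS baseline.
- `inverse_gamma_rates(n, alpha, seed)` — empirical infectious periods
  are well described by gamma distributions, so the corresponding *rates*
  are inverse-gamma. The scale is tied to the shape as β = α − 1, making
  the mean exactly 1 analytically (no per-sample rescaling, which would
  distort the shape). Variance is 1/(α − 2) for α > 2 and infinite for
  α ≤ 2; the heavy-tail regime is allowed but logged. α ≤ 1 (undefined
  mean) is rejected.
- `degree_correlated_rates(net)` — δᵢ = kᵢ exactly. Then Q = Δ⁻¹A is the
  random-walk transition matrix, Λ_max = 1, and the threshold is pinned
  at 1 on any connected structure: structural heterogeneity is cancelled
  by the dynamics.
- `powerlaw_shuffled_rates(...)` — the inverse scenario: rates drawn from
  a discrete power law P(k) ∝ k^(−γ) (or a supplied degree sequence)
  assigned to the nodes of a homogeneous network by seeded random
  permutation. The assignment is deliberately uncorrelated with the
  substrate degrees; coupling them is a different experiment.

## Spectral theory

`build_Q` assembles Q = Δ⁻¹(A∘W) at unit λ (λ enters only as a global
scale for both schemes, so thresholds are reported in λ units). For both
schemes Q = S⁻¹A with sᵢ = δᵢ/wᵢ a positive diagonal, hence Q is similar
to the symmetric matrix S^(−1/2) A S^(−1/2). The eigensolver works on
that symmetric form (Lanczos via ARPACK, tol 1e-10; dense `eigh` below
64 nodes where ARPACK is unreliable) and back-transforms the Perron
eigenvector, which is normalized to unit 2-norm with nonnegative entries.
A residual check ‖Qv − Λv‖ guards the similarity assumption.

`critical_point` reports λ_c = 1/Λ_max(Q) together with:

- the norm sandwich min(sᵢ)·τ_std ≤ λ_c ≤ max(sᵢ)·τ_std, where
  τ_std = 1/Λ_max(A) is the homogeneous prediction;
- the Gershgorin infinity-norm bound Λ_max(Q) ≤ max_i kᵢ/sᵢ, i.e.
  λ_c ≥ 1/‖Q‖_∞ — the bound that stays finite when δᵢ ∝ kᵢ;
- the inverse participation ratio IPR = Σᵢ vᵢ⁴ of the unit-norm leading
  eigenvector (≈ 1/N when delocalized, O(1) when localized on hubs).
  This is the standard localization convention.

The mean-field ODE is integrated with LSODA (rtol 1e-8); the steady-state
helper iterates 50-time-unit chunks until ‖dy/dt‖_∞ < 1e-10. [0, 1]^N is
invariant under the exact dynamics; solver overshoot is clipped.

## Stochastic simulation

The Gillespie kernel (numba-compiled) keeps, for each infected node, the
constant weight wᵢ = δᵢ + λkᵢ (uniform) or δᵢ + λ (contact process) in a
Fenwick tree. Each event: draw Exp(total weight) for the time increment,
select a node proportionally to its weight in O(log N), then recover with
probability δᵢ/wᵢ or attempt transmission to a uniformly random neighbor.
Attempts toward already-infected neighbors are *phantom events* — the
time advance is kept and nothing changes. This rejection construction
simulates the exact process law (the accepted transmission rate toward
susceptible neighbors is exactly λ per active edge) without maintaining
per-node susceptible-neighbor counts, whose O(k) updates dominate on
heavy-tailed graphs. Near the threshold, where most neighbors are
susceptible, the rejection overhead is small.

### Quasistationary method

The all-susceptible state is absorbing, so steady-state statistics at
finite N use QS conditioning: a store of `n_store` active configurations
is refreshed with the current configuration at rate `p_store_update` per
unit simulated time (replacing a uniformly chosen slot); on absorption
the state is replaced by a uniformly drawn stored configuration. n_I is
sampled on a fixed time grid (default 1 time unit) after `relax_time`,
over `avg_time`; the histogram yields ρ and χ. Defaults follow common
practice: n_store = 100, p_store_update = 0.01, relax = avg = 1e5 time
units, all-infected start. All parameters are recorded in the output
metadata.

Two finite-run biases of the store method surfaced during validation
against the exact oracle and matter when windows are short:

1. **staleness** — if the store does not turn over several times during
   relaxation, restarts over-sample the initial configuration (upward
   bias when starting fully infected);
2. **feedback** — if the update rate is large, restarts correlate with
   the very recent trajectory and the stationary law acquires an upward
   bias (measured ≈ +0.5% in ρ on a dyad at p = 1, ≈ +1.6% at p = 5,
   < +0.05% at p = 0.2).

Short-window runs in the tests therefore use a small store (10–50 slots),
p = 0.2, and a small initial seed fraction (2%), which the dyad/ring
oracle comparisons show to be unbiased within Monte Carlo error. The
production defaults (long windows, slow store) are standard and unaffected.

### Exact oracle

For N ≤ 12 the full 2^N-state generator is assembled; the QS distribution
is the left eigenvector, for the dominant eigenvalue, of the generator
restricted to the 2^N − 1 active states (dense eig up to 1024 states,
ARPACK above). The simulator is required to reproduce its ρ and χ within
3 Monte Carlo standard errors on heterogeneous instances of both schemes.

## Experiment protocols

- **Sweep**: one QS run per point of a strictly increasing λ grid
  (default: geometric, 25 points, spanning a factor 4 around the spectral
  prediction). The threshold proxy is the χ-maximizing λ refined by a
  quadratic fit in log λ through the maximum and its two neighbors; a
  peak on the grid boundary is flagged and left unrefined. The quadratic
  refinement is an estimator choice; its error is second order in the
  grid spacing.
- **Alpha scan**: per shape α, fresh unit-mean inverse-gamma rates (one
  common seed across α for paired comparisons), sweep + spectral report.
  The prediction column is nondecreasing in α and approaches the
  homogeneous value, per the sandwich bounds.
- **Finite-size analysis**: λ_peak(N) over ≥ 3 sizes with replicate
  seeds; the log-log slope of the median peak vs N (least squares, with
  standard error) classifies the threshold as finite (slope ≈ 0) or
  vanishing (clearly negative).

## Problem sizes used in the checked runs

Spectral quantities run at publication scale (ER N = 1e5; power-law
N = 1e4), taking seconds. Simulation-based checks run at desk scale,
chosen so the full suite completes in minutes on one CPU: sweeps on
N = 1e4 graphs with relax 300–400 / avg 800–1200 time units and 9–15
grid points; finite-size runs at N ∈ {1e3, 3e3, 1e4} with 2 replicate
seeds. At these scales the threshold-shift direction (heterogeneous
recovery lowers both prediction and simulated peak), the δᵢ = kᵢ slope
(|slope| ≈ 0.01) and the standard-SIS slope (≈ −0.34) are
well-resolved. Publication-quality curves (χ resolved deep into the
subcritical region at N = 1e5) need the production QS windows (1e5 time
units); the same functions accept those parameters unchanged.

## Synthetic substrates, and what passing does not show

Erdős–Rényi graphs are G(N, p) with p = ⟨k⟩/(N − 1). Power-law graphs
are uncorrelated configuration models: degrees drawn from P(k) ∝ k^(−γ)
on [k_min, ⌊√N⌋] (structural cutoff suppresses degree correlations for
γ < 3; k_min defaults to 3, keeping the giant component near-spanning),
parity fixed by resampling the last entry, stubs matched uniformly,
self-loops/multi-edges erased (logged; a vanishing fraction at the sizes
used). Experiments run on the giant component.

These substrates have no clustering, no assortativity and no community
structure, and the rate vectors are i.i.d. (or exactly degree-tied);
passing tests therefore demonstrates the theory on idealized topologies,
not on real contact networks — real-network runs are supported through
the edge-list reader but no dataset ships with the package. Directed,
weighted and temporal graphs are out of scope.

## Known limitations

- The QS store method's finite-run biases (above) mean short windows
  need care; the package does not auto-tune windows.
- `exact_qs_oracle` is limited to N ≤ 12 by the 2^N state space.
- The peak refinement assumes a locally quadratic χ(log λ); extremely
  coarse grids or very flat peaks (heavy-tailed rates at small α) reduce
  the precision of λ_peak.
- For γ close to 2 the configuration model at moderate N carries visible
  finite-size corrections to P(k); exponent recovery is validated by MLE
  on the sampled sequence rather than a raw log-log fit.
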
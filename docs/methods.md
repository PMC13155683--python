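# Methods

## Model

The core object is a community of N replicator species. Species *i* is
described by three mass-action rate constants: association `a_i`
(concentration⁻¹ time⁻¹), dissociation `b_i` (time⁻¹), replication `c_i`
(concentration⁻¹ time⁻¹). All concentrations and times are in arbitrary
consistent units. The state holds single-strand concentrations `x_i` and
duplex concentrations `y_i`; duplexes are replication-inert. Complement
strands are not tracked (template and copy are assumed identical), there is
no cross-species hybridization, a single resource pool serves all species,
and the dynamics are deterministic ODEs — no demographic noise.

**Mass-regulated variant (the main model).** Resource concentration `r` is
held constant and an outflow at per-capita rate φ acts on every strand
equally. φ is tied to the current total production through a target
concentration `m`: φ = (r/m) Σ_j c_j x_j. Summing the per-species balance
dμ_i/dt = r c_i x_i − φ μ_i over species gives dμ/dt = φ(m − μ): the total
strand concentration μ follows a logistic law with carrying capacity `m`,
so μ̂ = m at equilibrium. This identity holds at every point of every
trajectory up to round-off and is used as an integrator sanity check.

**Growth rates.** Once a species' single/double-strand ratio has relaxed
(the internal stage structure equilibrates quickly relative to community
turnover), its population grows at

    Lambda_i(x_i) = [ −S_i + sqrt(S_i² + 4 b_i c_i r) ] / 2,
    S_i = 2 a_i x_i + b_i + c_i r,

strictly decreasing in `x_i` when `a_i > 0`. Its value at zero
concentration, λ_i, is the intrinsic growth rate: independent of `a_i`,
increasing in `b_i`, `c_i` and `r`, and zero without resource. A species
with `a_i = 0` (an E-species) grows at λ_i at any concentration —
exponential growth; `a_i > 0` defines the sub-exponential S-species.

**Equilibrium theory.** Every surviving species must grow exactly at the
common outflow: Λ_i(x̂_i) = φ̂. For an S-species this inverts in closed form,

    x̂_i = (λ_i − φ̂)(φ̂ − λ_i⁻) / (2 a_i φ̂),

where λ_i and λ_i⁻ are the two roots of φ² + (b_i + c_i r) φ − b_i c_i r = 0
(the factored form avoids the catastrophic cancellation of the raw
numerator b c r − (b + c r)φ − φ² as φ̂ → λ_i). The species' total then is
μ̂_i = r c_i x̂_i / φ̂, a continuous, strictly decreasing function of φ on
(0, λ_i) that vanishes for φ ≥ λ_i. Summed over S-species it diverges as
φ → 0 and hits zero at max λ_i, so the mass balance Σ μ̂_i(φ) = m has
exactly one root for every m > 0 — found by bracketed Brent iteration on
[1e-12·λ_max, λ_max(1 − 1e-12)] at 1e-13 relative tolerance. Closed-form
expressions for φ̂ itself are deliberately not used; the numerical root is
the contract, and ODE integration serves as the independent oracle. An
E-species can only be stationary at φ̂ = λ₀, so a persisting E-species pins
the production there and absorbs the residual mass m − Σ_S μ̂_i(λ₀); if the
residual is non-positive (absolute tolerance 1e-12) the E-species is
excluded and the pure-S branch applies. At most one E-species can persist;
two E-species tied at the maximal λ₀ are rejected as degenerate input since
the theory provides no tie-breaking rule.

Survivor classification uses strict λ_i > φ̂; species with |λ_i − φ̂| within
1e-9 relative are additionally reported as `marginal`, because on that
boundary both the classification and the ODE comparison are below numerical
resolution. The critical target concentration of the first extinction is
m* = Σ_{i ≠ argmin λ} μ̂_i(λ_min): below it, the smallest-λ species is out.

**Invasion and assembly.** A rare invader grows at λ′, so invasion succeeds
iff λ′ > φ̂_res — independent of the invader's association rate. Invasions
are resolved adiabatically (equilibrium to equilibrium); a trajectory-based
variant (`invade_by_trajectory`, introduction at x = 1e-5) exists purely as
a cross-check, because the analytic route is the theory being implemented.
A successful invasion weakly raises φ̂, and residents with λ in the zone of
exclusion (φ̂_res, φ̂_new] — plus a displaced resident E-species, whose λ sits
exactly at φ̂_res — are lost; `invade` verifies this characterization against
the zero-mass outcome of the new equilibrium on every call. Since φ̂ only
rises, sequential assembly from a pool terminates in the φ̂-maximizing
community regardless of introduction order, identical to solving the whole
pool at once; `assemble` offers both routes.

**Chemostat variant.** Constant dilution φ, explicit resource dynamics
dr/dt = −r Σ c_i x_i + (ρ − r)φ with inflow concentration ρ. At equilibrium
ρ − r̂ = μ̂, and increasing ρ (decreasing φ) scales diversity the way
increasing m (decreasing r) does in the mass-regulated model. Chemostat
equilibria are obtained by integration only; no separate analytic solver is
provided.

**Phenomenological variant.** dz_i/dt = k_i z_i^{p_i} − φ z_i with
φ = (Σ k_j z_j^{p_j})/m, p_i ∈ (0,1) for S-species and p_i = 1 for
E-species. Its per-capita growth k z^{p−1} diverges as z → 0, so every
sub-exponential species invades every community — the "survival of
everybody" artifact the mechanistic model corrects. It is included exactly
to make that contrast testable.

## Numerical choices

* Integrator: SciPy `solve_ivp` with the BDF method (the kinetics are stiff:
  association is the fastest step, a x² ≈ 50–100 per unit concentration²,
  against outflow rates of order 1). Default tolerances rtol = 1e-10,
  atol = 1e-12 — species routinely persist at concentrations of 1e-5 and
  extinction calls depend on small values.
* Steady-state stop: the run ends early when
  max_i |dμ_i/dt| / max(μ, 1e-12) < 1e-12, checked on a log-spaced grid of
  ~200 checkpoints up to the default horizon t_end = 1e6 time units. The
  tolerance is set so that even species holding ~1e-3 of the total mass are
  relaxed to better than 1e-6 relative when the run stops.
* Negative concentrations: entries in (−1e-9, 0) are round-off and are
  clipped to zero at checkpoint boundaries; anything more negative aborts
  with a diagnostic, since it signals a misconfigured solver rather than
  admissible noise. Solver failure always raises; partial output is never
  returned silently.
* Default initial condition (used when a config gives none): x_i = 1e-3,
  y_i = 0 for every species. Equilibria reached from multiple random starts
  coincide in all test runs, consistent with a unique interior equilibrium;
  uniqueness is verified empirically, not proven.
* Extinction bookkeeping on trajectories: μ_i < 1e-7 counts as extinct. The
  fluctuating-environment protocol instead uses its own establishment
  threshold of 3e-5, which is part of that protocol's definition.
* CSV output carries 12 significant digits; JSON numbers are unrounded.
  Species order everywhere is input order. All randomness flows through one
  seeded NumPy generator; the seed is recorded in every CSV header.

## Synthetic inputs and what the tests show

The bundled ten-species table (association 72.5–100, dissociation 5–10,
replication 1.6–5; species 3 optionally exponential) and the discrete rate
grids a ∈ {50, 52.5, …, 100}, b ∈ {5, 5.25, …, 10}, c ∈ {1, 1.2, …, 5}
(21³ = 9261 combinations; 21² = 441 b–c pairs at a common association rate)
define the study conditions. They target the regime where association
dominates and replication is the slowest elementary step at order-one
concentrations. Random communities in the tests are drawn from these grids
with m ∈ [0.1, 10] and r ∈ [0.25, 4], log-uniformly.

These are idealized kinetic parameter sets, not measurements: real
replicator pools have continuous, correlated rate constants,
cross-hybridization, multiple resources, and demographic noise. Passing
tests therefore demonstrate the internal consistency of the theory
(closed forms vs. brute-force integration, invasion algebra vs. dynamics),
not quantitative agreement with any laboratory system.

## Fluctuating-environment protocol

Every 100 time units a species with (b, c) drawn uniformly from the 441-pair
grid enters at x = 1e-5, y = 0; at each introduction, all species below the
establishment threshold 3e-5 are removed. The removal rule is deliberately
applied to *all* below-threshold species, not only the newest — residents
driven under the threshold are treated as stochastically extinct; a
`removal_mode="newest"` switch provides the stricter reading. The common
association rate follows a sinusoid on [50, 100] with period 10,000 time
units; the resource follows a log-sinusoid on [0.25, 4] with period 1,000
(ten times faster); m = 2 throughout; default duration 30,000 time units
(three slow periods). The waveform bounds match the rate-grid and
environment ranges used elsewhere; their amplitudes and periods are
declared defaults of this package, configurable in `FluctuationConfig`.
Segments between introductions are integrated with BDF at rtol = 1e-8,
atol = 1e-10 — transient dynamics with a 3e-5 decision threshold do not
need the equilibrium-grade tolerances.

Diversity in this protocol is introduction-limited (the community stays well
below the equilibrium richness of the full grid pool), so it tracks the
association waveform only weakly and with a lag: the phase contrast between
a(t)-maxima and minima is positive under the default seed but is small and
sensitive to the analysis window, and can invert for individual seeds. The
scarcity effect — counts higher at r(t) minima than maxima within each fast
cycle, tested as a paired per-cycle difference so the slow waveform cancels
— is the more robust signature. Both analyses ship as
`association_phase_contrast` and `resource_phase_contrast`.

## Known limitations

* No complement-strand bookkeeping, cross-hybridization, ligation-based
  (two-resource) replication, or stochastic simulation; perturbation theory
  beyond m* is out of scope.
* The interior equilibrium's uniqueness and global stability are assumed on
  empirical grounds (all integrations from admissible starts converge to
  the analytic fixed point); no Lyapunov argument is implemented.
* `critical_target_concentration` and the extinction-order results apply to
  pure-S communities with distinct intrinsic growth rates; ties are rejected
  rather than broken arbitrarily.
* The chemostat variant has no analytic equilibrium solver; conclusions
  about it rest on integrated steady states.
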
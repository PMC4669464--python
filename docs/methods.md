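# Methods

## The model

### Rate laws under concentration fluctuations

The normalised Michaelis–Menten rate v₀(ρ) = ρ/(ρ+K_M) is concave, so for a
fluctuating substrate concentration the population-averaged rate obeys
⟨v₀(ρ)⟩ ≤ v₀(⟨ρ⟩) (Jensen).  Writing v₀ around the mean m = ⟨ρ⟩ with the
integral-remainder form of Taylor's theorem gives the *exact* identity

    v₀(ρ) = v₀(m) + v₀'(m)(ρ−m) − K_M (ρ−m)² / [(K_M+m)² (K_M+ρ)],

and since ρ ≥ 0 implies K_M+ρ ≥ K_M, averaging yields the optimal
mean/variance lower bound v₀(m) − Var ρ/(m+K_M)².  No sharper bound exists
that uses only the first two moments, because the remainder bound is tight
in the limit of mass accumulating at ρ = 0.  The VCMME,
v₀(m) − K_M·Var ρ/(m+K_M)³, is the second-order Taylor truncation; algebra
shows it always lies inside the bounds (the gaps are Var·m/(m+K_M)³ and
K_M·Var/(m+K_M)³) and coincides with their midpoint exactly at m = K_M.
The general truncation at central-moment order n adds
(−1)^(n+1) K_M μ_n/(m+K_M)^(n+1); for right-skewed cellular concentration
distributions the series alternates, which is why the order-3/4 truncations
can do *worse* than the VCMME.  The VCMME is deliberately **not clamped** at
zero for extreme variance: the optimal bounds, not a clamp, delimit its
validity, and a silently clamped value would hide that the expansion has
left its regime.

All rate-law computations use the normalised rate; `v_max` only scales the
result at the presentation layer.  Central moments are caller-supplied (from
simulation or from the analytics below) — the rate-law layer is pure.

### Stochastic simulators

Both simulators are **direct-method Gillespie** (exact; no tau-leaping): the
target systems have at most tens of reaction channels and small counts, so
exactness is cheap.  Per-run seeds are derived from the base seed with
numpy's `SeedSequence` spawning (counter-based, order-independent); each run
is bit-reproducible from its own seed.  When total propensity vanishes the
simulation idles to the horizon (absorbing state) rather than erroring.

*Enzyme system.*  Substrate enters in batches of size B at Poisson rate r;
binding S+E→SE at k_on·S·E/V, unbinding at k_off, catalysis at k_cat.
Catalysis is the only substrate sink.  The stationary normalised rate is
pinned by flux balance at r·B/(k_cat·n_E); what fluctuations change is the
*mean concentration required to sustain it* — which is exactly what the
MME-at-the-mean mis-predicts and the VCMME restores.  In the batch-size
sweep the input flux r·B is held fixed, so all batch sizes share the same
stationary rate while the variance grows roughly linearly with B.

*Gene regulation.*  Transcription at a_TF from t = 0 (empty initial state:
the cell responds to switching the regulator gene on), per-mRNA decay γ_m,
per-mRNA translation v_TF, κ sequential maturation steps δ₁…δ_κ, dilution
γ_P of mature TF, and TF–DNA binding near one operator: nonspecific
association (rate ns_on·ρ) and dissociation (ns_off), and
specific↔nonspecific interconversion (sp_on, sp_off).  In the *sequential*
model the operator is reached only through the nonspecific state (sliding
search); in the *independent* variant the TF additionally binds the operator
directly from solution with rates chosen to preserve the combined
equilibrium constant K = (ns_on/ns_off)·(sp_on/sp_off), so binding
equilibrates much faster.  Modelling conventions, chosen once and used
consistently: bound TF is sequestered from the free pool and not diluted;
immature protein is not diluted (the kernel ϕ acts from the moment a TF
*matures*); dilution is a first-order death process (no explicit division
events — partitioning noise largely averages out at the ensemble level).

### Exact TF analytics

A mature TF that appeared at time 0 contributes ϕ(t) to the concentration at
the operator at time t; the homogeneous (well-mixed) kernel is
ϕ(t) = e^(−γ_P t)/V_Cell for t ≥ 0 and 0 before (causality).  Synthesis
events form a Poisson process whose intensity v_TF·N_mRNA(s) rides on the
mRNA immigration–death process (birth a_TF, death γ_m per molecule), and
each event is independently delayed by the maturation time Δ with
hypoexponential density f_Δ.  Because an immigration–death process is an
M/M/∞ queue — a Poisson random measure of (birth time, exponential
lifetime) points — the exponential functional factorises over molecules:

    ⟨e^(−λρ(t))⟩ = exp( −a_TF ∫₀ᵗ (1 − g(u)) du ),

where g(u) is the expected deficit contributed by one mRNA born at u,
solving the backward equation g'(u) = (v_TF·F(λ, t−u) + γ_m)·g(u) − γ_m with
g(t) = 1, and F(λ, w) = ⟨1 − e^(−λϕ(w−Δ))⟩_Δ is the delay-smeared
single-event deficit.  Differentiating at λ → 0 gives

    ⟨ρ(t)⟩  = a_TF·b · [(1 − e^(−γ_m s)) ∗ f_Δ ∗ ϕ](t),
    Var ρ(t) = a_TF·b · [(1 − e^(−γ_m s)) ∗ f_Δ ∗ ϕ²](t)
             + 2 a_TF b² γ_m ∫₀ᵗ dx ψ(x) ∫ₓᵗ dy ψ(y) (e^(−γ_m(y−x)) − e^(−γ_m(t−x))),

with b = v_TF/γ_m and ψ = f_Δ ∗ ϕ.  The mean is a convolution of one factor
per cascade stage, so its small-time growth is t^(κ+2) — each stochastic
intermediate step raises the exponent by one — and its stationary value is
a_TF·b/(γ_P·V).  The variance is *not* a single convolution: its second term
is the covariance of proteins sharing one mRNA (translational bursting) and
dominates for b ≫ 1, scaling as b² at fixed transcription rate.  In the
limit γ_m, v_TF → ∞ at fixed b with no delay it collapses to the concave
shot-noise form a·b(2b+1)∫ϕ².  Both formulas are cross-checked in the tests
against finite differences of the Laplace functional and against SSA
ensembles.

Operator occupancy follows the Michaelis–Menten-type law
p₀(ρ) = Kρ/(1+Kρ) obtained from equilibrium of the two binding steps when
specific binding is strong (K_SP ≫ 1); the un-approximated two-state law
p₀ = Kρ/(1 + K(1+1/K_SP)ρ) is available behind `strong_binding=False`.  The
population-averaged occupancy uses the integral identity

    ⟨Kρ/(1+Kρ)⟩ = 1 − ∫₀¹ ⟨exp(K·ln(z)·ρ(t))⟩ dz,

i.e. the semi-infinite exponential integral mapped to the unit interval.
The combined constant K is kept an independent input (its decomposition into
K_NS·K_SP and volume factors is a convention of the binding model); the
simulation fixtures choose ns/sp rates consistent with it.

The Poissonian benchmark replaces the true TF statistics by a Poisson copy
number with the same mean and averages p₀ over it — it captures shot noise
but misses translational bursting, which is why the VCMME (which inherits
the full variance) beats it throughout the transient.

## Fixtures: what the generators emulate

The named fixtures define the study conditions of the shipped experiments.
They are documented, biologically plausible parameter sets; quantities that
depend on the exact values (stationary substrate count, peak occupancy
error) are regime-level characteristics of these fixtures, not universal
constants.

* `fig1a_like` — single enzyme, K_M = 100 copies/volume (k_on = 0.02 /s per
  unit concentration, k_off = k_cat = 1 /s), substrate in batches of 40.
  The input rate (0.0123479 batches/s) was calibrated *a priori* with the
  package's own variance-corrected flux balance — linear-noise stationary
  variance Var ≈ x(B+1)/(2v₀'(S̄)) solved self-consistently with the VCMME —
  so that the stationary substrate count is 117.6 molecules, placing the
  substrate pool just above K_M where the rate law is most sensitive.  The
  linear-noise calibration is itself a few-percent approximation at B = 40,
  which sets the accuracy with which the simulated mean reproduces 117.6.
* `fig1b_like` — an E. coli lac-like TF cascade: one mRNA per 300 s, 120 s
  mRNA lifetime, burst size b = 6, two 50 s maturation steps, 30 min
  dilution time, V = 1 µm³ (stationary level 36 copies), K = 1/3 µm³ with
  K_SP = 100 (strong specific binding), nonspecific search rate 0.1 µm³/s.
  All values are within the literature-plausible range for a lowly expressed
  bacterial repressor; with them the peak error of the MME occupancy is
  ≈ 0.21, reached at ≈ 480 s, and the transient correction persists for
  roughly half an hour.
* `deterministic_limit` — 20 enzymes, K_M = 1000, single-molecule input at
  flux 10 /s: relative fluctuations are tiny and every estimator collapses
  onto the MME within ~5·10⁻⁴ (large-copy control).

What passing tests on these fixtures does **not** show: agreement with any
particular experimental dataset; behaviour under spatial heterogeneity
(nucleoid exclusion, anomalous diffusion), explicit cell-division
partitioning, multimerisation/Hill cooperativity, or multiple interacting
genes — all outside the model class implemented here.

## Numerics

* Closed-form rate-law identities are exact to 1e-12 and tested at that
  tolerance; no quadrature is involved in the rate-law layer.
* The delay density uses the partial-fraction hypoexponential form for
  pairwise-distinct rates, the Erlang closed form for equal rates, and an
  exact phase-type matrix exponential for mixed near-equal rates
  (relative gap < 1e-6), which is stable in the confluent limit.
* The Laplace functional builds F(λ, ·) on a dense grid (panelled
  Gauss–Legendre in the delay variable; grid sized to the fastest rate,
  800–6000 points), interpolates it with a cubic spline and integrates the
  backward ODE with DOP853 at rtol 1e-10/atol 1e-13 (a failed solve raises,
  reporting the solver message).  Many λ values share one vectorised solve.
* The occupancy integral uses panelled Gauss–Legendre on the unit interval
  with the substitution z = y⁴, which removes the algebraic z^(Kρ) endpoint
  behaviour; on point-mass surrogates the rule is exact to machine
  precision (tested at 1e-8).
* Mean/variance convolutions use adaptive quadrature (inner absolute
  tolerance ~1e-11, relative 1e-10) over spline-tabulated ψ = f_Δ∗ϕ;
  integration ranges are truncated where the integrand mass is below
  ~1e-14 (delay cutoff mean + 35/δ_min; kernel cutoff 40/γ_P), which is
  what makes the t → ∞ stationary limits accurate to better than 1e-6.
* λ-derivatives of the functional (cross-checks only; the primary mean and
  variance formulas are analytic) use one-sided second-order stencils on the
  cumulant functional −log⟨e^(−λρ)⟩ with one Richardson step and step scale
  0.025/⟨ρ⟩: truncation ~1e-5 relative, still far above the ODE/quadrature
  noise floor.
* Monte-Carlo comparisons use 3 standard errors.  Where a *prediction* is
  built from empirical moments (VCMME at simulated mean/variance), the
  moment uncertainty is propagated through the first derivatives of the
  VCMME and combined with the rate-estimate SE — otherwise the comparison
  would be biased toward failure at small batch sizes where the rate SE is
  tiny but the moment noise is not.
* Stationary statistics are estimated by time-and-ensemble averaging over
  the second half of each run; per-run time averages are independent
  replicates, so across-run SEs remain valid despite within-run
  autocorrelation.

## Design choices and limitations

* The "reaction volume around the operator" is identified with the cell
  volume (well-mixed assumption), matching the homogeneous kernel; the
  nonspecific on-rate is a lumped effective search rate.  Spatially
  inhomogeneous kernels can be plugged in through `DiffusionKernel` but are
  not provided.
* The analytic occupancy assumes binding equilibrium and does not feed back
  on the TF pool; the simulator sequesters one TF while bound.  At ~36
  stationary copies this causes a ≲0.01 occupancy offset, visible only as a
  slight systematic in high-statistics comparisons; at early times (few
  copies) the sequential-search model genuinely departs from equilibrium —
  the independent-binding variant exists precisely to isolate that effect.
* The growth-exponent fit uses t ∈ [0.25, 1] s, where the next-order
  corrections (~rate·t) bias the log-log slope by well under the 0.05
  assertion band.
* Problem sizes in the shipped studies (500 runs per batch size, 10⁴-run
  Laplace oracle, 17-point occupancy grids) were chosen so the whole
  acceptance computation completes in well under a minute while keeping
  Monte-Carlo error far below the effect sizes being measured.
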
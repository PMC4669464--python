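# vcmm — variance-corrected Michaelis–Menten kinetics

Reaction rates in living cells are routinely estimated by plugging a *mean*
substrate concentration into the Michaelis–Menten equation (MME),

    v = v_max · ρ / (ρ + K_M),        v₀ = v / v_max,

but at the low copy numbers typical of bacterial gene regulation the
concentration ρ(t) fluctuates strongly — substrate arrives in bursts,
transcription factors (TFs) are made in translational bursts of many copies
per mRNA.  Because v₀ is concave, Jensen's inequality makes the naive
estimate v₀(⟨ρ⟩) an *upper bound* on the true population-averaged rate
⟨v₀(ρ)⟩, and the gap can be large.  This package implements the theory that
quantifies and corrects that gap, for computational biologists and
biophysicists modelling enzymatic reactions and transcriptional regulation:

* **Optimal bounds.**  For any nonnegative concentration distribution with
  mean m and variance Var ρ,

      m/(m+K_M) − Var ρ/(m+K_M)²  ≤  ⟨v₀(ρ)⟩  ≤  m/(m+K_M),

  the sharpest bounds expressible through mean and variance alone.

* **VCMME.**  The variance-corrected Michaelis–Menten equation

      v₀ = m/(m+K_M) − K_M · Var ρ/(m+K_M)³

  lies between the bounds (their exact midpoint at m = K_M), needs only the
  first two moments, and tracks exact stochastic simulations remarkably well.
  Higher-order Taylor truncations in central moments are also provided.

* **Exact stochastic simulators** (direct-method Gillespie): a single- or
  multi-enzyme reaction with substrate arriving in Poisson-timed batches, and
  a full TF expression cascade — transcription, mRNA decay, translation,
  κ-step protein maturation, dilution, and TF–DNA binding (sequential
  nonspecific→specific search, or an independent-binding variant).

* **Exact TF analytics.**  For a TF expressed from t = 0 with translational
  bursts (mean size b = v_TF/γ_m), hypoexponential maturation delay f_Δ and
  dilution kernel ϕ(t) = e^(−γ_P t)/V, the Laplace functional
  ⟨e^(−λρ(t))⟩ is computed exactly (the mRNA count is an immigration–death
  process; each molecule's contribution is averaged by a backward ODE).  From
  it: the mean ⟨ρ(t)⟩ = a_TF·b·[(1−e^(−γ_m s)) ∗ f_Δ ∗ ϕ](t), the variance
  time course, and the operator occupancy ⟨Kρ/(1+Kρ)⟩ by integral of the
  functional — alongside MME, VCMME and Poissonian occupancy estimates.

## Worked example

```python
import vcmm as V

# ---- rate laws: bounds and correction at given moments -------------------
rp  = V.RateParameters(michaelis_constant=100.0)
mom = V.ConcentrationMoments(mean=117.6, variance=4964.0)
V.jensen_upper_bound(mom, rp)   # 0.5404  (plain MME at the mean)
V.vcmme(mom, rp)                # 0.4923  (variance-corrected)
V.optimal_lower_bound(mom, rp)  # 0.4356

# ---- bursty-substrate enzyme: simulation vs predictions ------------------
df = V.enzyme_batch_sweep(V.fixture("fig1a_like"), (1, 40), 200, 6000.0, 1)
#  batch_size  mean_concentration  v0_sim  v0_mme  v0_vcmme
#           1             98.4213  0.4937  0.4960    0.4939
#          40            116.4349  0.4903  0.5380    0.4867

# ---- gene regulation: occupancy of the operator over time ----------------
params = V.TFModelParams.from_sim_spec(V.fixture("fig1b_like"))
for t in (300.0, 600.0, 1800.0):
    print(t, V.occupancy_exact(t, params), V.occupancy_mme(t, params),
          V.occupancy_vcmme(t, params))
# t=   300s  <rho>=  2.06  exact=0.240  MME=0.407  VCMME=0.156
# t=   600s  <rho>=  6.81  exact=0.499  MME=0.694  VCMME=0.519
# t=  1800s  <rho>= 20.99  exact=0.819  MME=0.875  VCMME=0.837
```

Reading the output: with batches of 40 substrate molecules the plain MME
overestimates the stationary single-enzyme rate by ~0.05 (a 10% relative
error), while the VCMME at the *same* empirical moments lands on the
simulated value within Monte-Carlo error.  In the gene-regulation transient
the deterministic occupancy estimate is off by up to ~0.2 around t ≈ 400–500 s;
the exact averaged occupancy and the VCMME agree closely once a handful of
TF copies are present.

## Command line

```bash
vcmm fixtures list
vcmm analytics --fixture fig1b_like --grid 0 3600 61 --out occupancy.tsv
vcmm simulate  --fixture fig1a_like --runs 500 --horizon 6000 --seed 1 --out sweep.tsv
vcmm compare   --fixture fig1b_like --runs 500 --grid 0 3600 31 --seed 1 --out cmp.tsv
```

Every table is written with full float precision together with a
`*.meta.yaml` sidecar (parameters, seeds) that reproduces it exactly.

## Layout

* `src/vcmm/core.py` — the whole implementation, sectioned in the order the
  method runs: rate laws → stochastic simulation → TF analytics → workbench.
* `src/vcmm/__main__.py` — the CLI.
* `docs/methods.md` — model assumptions, parameter choices, numerics.
* `tests/` — unit, property and acceptance tests.
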
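# Methods

## Model

A droplet holds a finite amount S₀ of a single growth-limiting resource
and an inoculum of N₀ cells partitioned over metabolic phenotypes. Type i
divides at rate λᵢ per cell per unit time while resource remains, and each
division consumes cᵢ = 1/yᵢ resource units (yᵢ is the yield: divisions
supported per unit resource). Division rates have a step-function
dependence on the substrate: constant while resource is positive, zero
after exhaustion — no Monod-type saturation. Phenotype switching is
assumed slow relative to the growth period and is not simulated; the event
loop is structured so switching events could be added, but none are
implemented. There is no death, no lag phase, and division waiting times
are exponential.

Because only the *order* of divisions determines the endpoint, the
continuous-time process and its embedded jump chain (next division of
type i with probability λᵢnᵢ/Σλⱼnⱼ) induce the same law on the division
lattice; both simulators are provided and tested for agreement.

**Stopping rule (overshoot convention).** A division may begin whenever
remaining resource is strictly positive; it executes in full and may drive
the remainder negative, after which growth stops. The alternative rule —
a division must be fully payable — is available via `overshoot=False` for
sensitivity checks but is not the default and not used in any reported
number. The overshoot rule makes the absorbed set exactly "first lattice
point on or past the stopping line", with no type-dependent affordability
bias. Floating-point slack: "positive remaining resource" means
`remaining > budget * 1e-12`, used identically by simulators and exact
solvers so their stopping sets coincide.

## Parameter conventions

| Parameter | Meaning | Default / convention |
|---|---|---|
| λ₁ | reference division rate | 1 (jump-chain laws depend only on ratios) |
| y₁ | reference yield | 1 (budget measured in type-1 divisions) |
| ratio_rates = λ₂/λ₁ | rate ratio | ≥ 1; type 2 is the faster grower (types relabelled to enforce) |
| r = y₂/y₁ | yield ratio | r < 1 ⇔ metabolic tradeoff (faster grower wastes more resource) |
| ε = N₀/(2 y₂ S₀) | inoculum scale over budget-supported divisions | small parameter of the deterministic expansion |

## Exact solvers

`enumerate_paths` walks every division sequence depth-first, multiplying
step probabilities (guard: ≤ 20 divisions). `forward_dp` propagates mass
over anti-diagonals d₁+d₂ = s of the lattice, so each state's two
predecessors are finalized before its mass is split; absorbed states
retain their mass (guard: ≤ 5·10³ divisions, configurable). Probabilities
stay in linear space: step probabilities are well-conditioned ratios and
the DP sums rather than multiplies along paths, so underflow affects only
sub-10⁻³⁰⁰ tail cells. Normalization is checked to 1e-12 in tests.

## Urn analytics

For equal rates and yields the jump chain *is* Polya's urn; the type-1
division count out of D is Beta-Binomial(D; a₁, a₂), implemented directly
through `gammaln`/`betaln` (scipy's `betabinom` serves only as an
independent cross-check in tests). Closed-form moments give

    CV(D)² = a₂(a₁+a₂+D) / (D a₁ (a₁+a₂+1))  →  a₂/(a₁(a₁+a₂+1)),

so the relative width never vanishes with D and, for symmetric inocula
a₁ = a₂ = N₀/2, equals (N₀+1)^(−1/2) exactly: the inverse-square-root
inoculum law is asymptotic — a log–log fit over N₀ = 2⁶..2¹³ gives slope
−0.499, while over N₀ = 2..32 the exact slope is only ≈ −0.43. Tests and
the acceptance script fit in the large-inoculum regime.

For unequal rates the rate ratio is approximated by coprime integers
(smallest denominator meeting a relative tolerance, default 1e-6, found by
scanning denominators — equivalent to continued-fraction convergents and
semiconvergents) and each cell is represented by kᵢ balls reinforced by
kᵢ, which preserves the rate-weighted odds exactly; the urn simulation is
the jump chain with integer rates.

**Limit scaling variable.** Writing the pure-birth (Yule) limits
nᵢ(t)e^(−λᵢt) → Wᵢ ~ Gamma(aᵢ, 1), both n₁ and n₂^ρ (ρ = λ₁/λ₂) grow like
e^(λ₁t), giving the candidate limit law

    z = W₁ / (W₁ + W₂^ρ),

exactly Beta(a₁, a₂) at ρ = 1. Because this form was derived here rather
than transcribed, it is treated as falsifiable: a two-sample KS test at
level 0.01 against the scaled composition n₁/(n₁+n₂^ρ) of jump-chain
simulation must pass before the sampler is trusted. The simulation side
uses D = 2¹⁴ divisions: at ρ = 0.5 the slow type holds only ~√D cells, and
at D = 2¹² the finite-D bias is comparable to the KS sensitivity at 10⁴
samples. Moments of the no-closed-form law are taken from the sampler
directly (Monte Carlo), cross-checked against exact lattice moments on
small instances.

## Variable yields and the final-size law

With c₁ ≠ c₂ the stopping line is tilted and each endpoint carries its own
final size N_f = N₀ + d₁ + d₂. A monotone trajectory absorbed at type-1
count ≤ d₁ on the tilted line must first cross the unit-cost line through
(d₁, d₂*), d₂* = (S₀ − c₁d₁)/c₂, which a lattice walk does when its total
division count reaches **⌈d₁ + d₂*⌉** — so the variable-yield CDF equals
the uniform-yield CDF at that effective division number. The ceiling (not
floor) reading reproduces the exact enumerated CDF at every support point
of the worked toy instance; when the *more expensive* type divides last a
single endpoint d₁ can correspond to two lattice d₂ values, so the map is
guaranteed only to one division of discretization (documented tolerance;
exact whenever c₁ ≤ c₂). Exact final-size laws marginalize the lattice DP;
the large-budget route samples (W₁, W₂), solves
Σᵢ cᵢ(Wᵢe^(λᵢT) − aᵢ) = S₀ per sample by vectorized bisection (100
iterations), and takes moments of N_f = ΣᵢWᵢe^(λᵢT).

A consequence of the Gamma-pair representation worth stating: with rate
ratio k = λ₂/λ₁, the final-size fluctuation is controlled by W₁W₂^(−1/k),
so std(N_f) ∝ N₀^(1/2−1/k)·√S₀ asymptotically. The inverse-square-root
decrease of final-size variability with inoculum therefore holds for
*equal* rates (measured ensemble slope ≈ −0.45 over N₀ = 2..128), while at
k = 2 the exponent tends to zero and the measured slope over the same
range is ≈ −0.24, a small-inoculum transient. Both slopes are computed by
the acceptance script.

## Deterministic theory

Mean-field growth is nᵢ(t) = nᵢ(0)e^(λᵢt) with stopping condition
Σᵢcᵢ(nᵢ(T)−nᵢ(0)) = S₀, solved by bracketed Brent root finding (relative
tolerance 1e-13; bracket doubled from T = 1/λ_max). The two-type solver
takes an explicit real-valued initial split, defaulting to the spec's
counts; symmetric sweeps use half/half even for odd N₀ (continuum
approximation). For λ_fast/λ_slow = 2 exactly (checked to 1e-12), with
x = e^(λ_slow T) and per-type inocula a_s, a_f:

    c_f a_f x² + c_s a_s x − (c_s a_s + c_f a_f + S₀) = 0,
    N_f = (c_s a_s + c_f a_f + S₀)/c_f + (1 − c_s/c_f) a_s x,

taking the positive root (> 1 whenever S₀ > 0). Expanding the root for
small ε gives

    N_f ≈ S₀/c_f + a_f + a_s c_s/c_f
          + (1 − c_s/c_f) a_s [√(S₀/(c_f a_f)) (1 + (c_s a_s + c_f a_f)/(2S₀))
                               − c_s a_s/(2 c_f a_f)],

whose correction term vanishes identically at uniform yield (recovering
N_f = N₀ + yS₀) and scales as √N₀ for symmetric inocula, with the sign of
c_f − c_s: increasing in N₀ under tradeoff, decreasing under positive
rate–yield correlation. The expansion's error relative to the closed form
vanishes as ε → 0 (tested), so the coefficients — re-derived here — are
validated against the numeric solver rather than asserted.

## Random numbers and reproducibility

Ensembles spawn one child stream per droplet from a master
`SeedSequence(seed)` (PCG64). The vectorized stepping core pre-draws each
replicate's uniforms in blocks and consumes them in exactly the order the
scalar simulators would, so `run_ensemble` is bit-identical to running the
scalar simulator on each child stream (tested for both modes). Gillespie
draws per step are (waiting-time uniform, type uniform) in that order.
Statistical tests are derandomised with fixed seeds chosen up front;
binomial checks use 3-standard-error bounds per outcome, and
many-bin uniformity uses a simultaneous (Šidák-adjusted) bound plus a
chi-square aggregate, which is the calibrated equivalent.

## Ensemble conditions used in tests and the acceptance script

Small exact instances use the worked toy (counts (1,1), costs (1,2),
budget 3) and a six-instance panel spanning unequal rates/costs within the
12-division enumeration range. Stochastic checks use 10⁵ replicates for
binomial/TV comparisons and 10⁴ replicates for inoculum sweeps at
S₀ = 1000 with rate ratio 2 and yield ratios {0.5, 2} — budgets large
enough that mean shifts (≈ 15–170 cells across N₀ = 2..128) exceed
Monte-Carlo noise by an order of magnitude, while a full sweep stays in
the tens of seconds. Limit-shape comparisons use 10⁴ samples at
D ∈ {2¹⁰, 2¹², 2¹⁴} divisions.

## What the generator does and does not emulate

All inputs are synthetic by construction (the model *is* the study
object): droplet ensembles are exchangeable, perfectly mixed, and share
exact initial conditions. Real droplet experiments add inoculum-size
variation between droplets (Poisson loading), resource-volume variation,
phenotype switching during growth, non-exponential division intervals and
measurement noise — none of which are modelled, so passing tests validate
the mathematics of this model class, not agreement with any particular
experimental dataset.

## Known limitations

* Analytic modules (urn, deterministic closed form, yield map) are
  two-type; simulators accept any number of types.
* The exact DP is two-type and bounded by its division guard; beyond it,
  use Monte Carlo or the limit sampler.
* The closed form requires a rate ratio of exactly 2; other ratios go
  through the numeric solver.
* The yield map carries a ≤ 1-division discretization tolerance when the
  costlier type can divide last (c₁ > c₂).
* The unequal-rate scaling variable is a derived candidate validated by
  simulation; an equivalent monotone reparameterization cannot be excluded.
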
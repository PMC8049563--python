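# Methods

## Model and assumptions

The package models two populations that diverged from a panmictic
ancestral population, sampled through two chromosomes per population
(one diploid individual each, or pooled low-coverage genomes). Sites are
assumed independent (composite likelihood), bi-allelic, polarized by a
known ancestral allele, and evolving under infinite sites with a
per-site per-generation mutation rate μ. Under these assumptions the
probability that a site shows configuration *(i, j)* is μ times the
expected total length of genealogy branches subtending *i* population-1
and *j* population-2 leaves — every probability is linear in μ, and no
Poisson correction is applied (mutation probabilities per branch are far
below 1 at realistic μ).

Within the daughter branches nothing is assumed about population-size
history: each branch is summarized by its drift α (probability the pair
does not coalesce before the split) and ν (expected coalescence time
given coalescence happened). Two model tiers differ in the ancestral
population:

- **Constant-ancestor (TT):** ancestral size constant at N_A
  chromosomes, so E[T4_k] = 2N_A/(k(k−1)) and (τ₂, τ₃, τ₄) =
  (θ, θ/3, θ/6) with θ = μN_A. Note that τ₄ = θ/6 is forced by
  E[T4₄] = 2N_A/12; a θ = τ₄/6 reading is dimensionally inconsistent
  with the stage expectations and is not used.
- **General ancestor (TTo):** the ancestral population enters only
  through τ_i = μE[T4_i], the mutation-scaled expected stage durations
  of a 4-lineage coalescent started at the split. Split times appear
  only inside B_k = μt_k + τ₄.

No gene flow after the split is assumed by both estimators; the
simulator deliberately violates this (and the constant-ancestor
assumption) to quantify the resulting biases.

## Estimators and numerical choices

**TT.** Equating observed frequencies to model probabilities gives
closed-form estimators for α₁, α₂, θ, T₁, T₂, V₁, V₂; these are also the
MLEs of the multinomial sampling model, so no optimizer exists anywhere
in the package. The V estimators are defined by the exact algebraic
inverse of the forward model, V̂₁ = p̂₁₀/2 + (p̂₁₂ − 2α̂₁p̂₂₀)/(2(1−α̂₁))
(index-swapped for V̂₂); the package's round-trip property test
(estimate ∘ forward = identity on expected counts, to 1e-8 relative
across a random parameter sweep) pins all seven formulas.

Degenerate inputs are handled as structured outcomes, never silent NaNs:
m₁,₁ = 0 raises an "insufficient shared polymorphism" error (α̂ and θ̂ are
undefined without shared variants); a nonpositive V denominator
(2m₂,₁ ≤ m₁,₁, equivalently α̂₁ ≥ 1) yields V̂ = NaN with a warning and a
flag while all other estimates are returned. Negative time estimates are
*reported and flagged, not clamped* — they are diagnostic of model
violations (e.g. strong ancestral bottlenecks), and clamping would hide
exactly the signal a user needs. α̂ > 1 under sampling noise is likewise
flagged, not truncated.

**TTo.** Given externally obtained drift values (ascertained estimates
or known truth), τ̂₂* and τ̂₃* each have two one-sided forms (via m₂,₁ or
m₁,₂); the package reports their mean and retains both variants — their
divergence is a useful asymmetry diagnostic. τ̂₄* = (3/2)(τ̂₃*)²/τ̂₂*
exploits the stage-duration ratios of a constant coalescent
(E[T4₃]/E[T4₂] = 1/3, E[T4₄]/E[T4₃] = 1/2) as a *ratio approximation*:
exact when the ancestral size is constant, and empirically much less
bottleneck-sensitive than assuming τ₄ = θ/6 outright. When τ̂₂* ≤ 0 the
τ₄ step and the time estimates are undefined (NaN + flag); when α = 1,
V̂* is undefined (division by 1 − α). The V̂* forms are exactly μν only
under a constant ancestral size; otherwise they carry a residual
proportional to (τ₂ − 3τ₃), which is documented rather than corrected.

**Ascertained drift.** The α̂* estimator is the exact symbolic solution
of the no-new-mutation configuration equations,
α̂₁* = 2(m₁,₀*+m₁,₂*+m₁,₁*) / (2(m₁,₀*+2m₂,₀*+m₂,₁*)+m₁,₁*), verified
two ways: symbolically (substituting the ascertained probabilities
expressed in α₁, α₂ and an arbitrary ascertained ancestral spectrum
reduces it to α₁ identically) and by simulation recovery with a genuine
outgroup. The ascertainment rule is "at least one derived copy in the
outgroup sample" by default (configurable to "both copies"); one copy
suffices to certify the variant predates the split, and the looser rule
keeps more sites.

**Tree-ness.** Y₁ compares singleton-sharing ratios across the two
branches; Y₂ sums the signed asymmetries (m₁,₀*−m₀,₁*) + 2(m₂,₀*−m₀,₂*) +
(m₂,₁*−m₁,₂*), scaled by m_tot*. Both are identically zero in
expectation under a true outgroup — including with arbitrarily
asymmetric daughter drift — so a deviation indicates gene flow involving
the outgroup lineage, with the sign of Y₂ tracking which daughter is
involved. The package reports jackknife Z-scores as the primitive; the
conventional |Z| > 3 red flag (mirroring D-statistic practice) is a
reading guide, not a hard-coded verdict.

## The simulator

`simulate_counts` generates data by Monte-Carlo averaging of per-genealogy
configuration probabilities: it simulates R labeled genealogies of the
2+2 sample (plus two outgroup chromosomes when configured), accumulates
branch lengths by the leaf subset each branch subtends, converts the
mean lengths to configuration probabilities (× μ), and forms either
expected counts (m_tot × p̄, real-valued) or one multinomial draw of
m_tot sites. Under the independent-sites assumption this is
distributionally equivalent to simulating one genealogy per site, at a
tiny fraction of the cost for genome-scale m_tot — it is what makes
billion-site experiments desk-cheap.

The demography is a two-population split with constant daughters, a
piecewise-constant ancestral size (one altered epoch: N_A for φ
generations after the split looking backwards, then λN_A for τ_b
generations, then N_A), and an optional single admixture pulse (each
lineage in the recipient jumps to the donor with probability γ at time
δ; donor defaults to the other daughter, and may be the outgroup
lineage). Sizes are configured in diploids; the pairwise coalescence
rate in a population of N diploids is 1/(2N) per generation.

Two implementations coexist and are cross-checked against each other in
the test suite:

- a generic event-driven per-genealogy simulation (any configuration);
- a vectorized path for the no-admixture, no-outgroup case that
  enumerates the small state space of alive-lineage configurations in
  the ancestral phase and inverts piecewise-exponential cumulative
  hazards for stage durations.

Ground truth accompanies every simulated data set: closed-form α
(exp(−t/2N) for constant daughters, extended analytically through a
pulse), Monte-Carlo α from the realized genealogies (the two agree
within MC error — a standing test), Monte-Carlo τ₂/τ₃/τ₄ from a
dedicated ancestral-phase simulation, and the nominal θ, T, V. The
ancestral-phase stage durations are additionally validated against a
dense-grid numeric integration of the two-epoch piecewise-exponential
process, and against the Kingman ratios (1 : 1/3 : 1/6) in the constant
case.

**What the generator does and does not emulate.** Its default study
conditions are those of the package's simulation study: sizes of
17,000 diploids (in line with African ancestral effective-size
estimates), a deeper split of 10,000 generations (300,000 years at
G = 30) and a shallower one of 1,500 generations (45,000 years),
μ = 1.25 × 10⁻⁸, bottlenecks to 1,500 diploids of duration
100–1,000 generations, and pulse admixture over γ ∈ [0, 1]. It does
*not* emulate linkage/recombination (sites are exchangeable, so
jackknife blocks on simulated data test the machinery, not LD
robustness), sequencing or polarization error, ancestral-state
misidentification, or ancient-DNA damage. Passing recovery tests here
therefore demonstrates correctness of the estimators under the model's
own assumptions plus the tested demographic violations — not robustness
to data-quality artifacts.

One scenario deserves a note: with γ = 1, δ = 0 and *all sizes equal*,
the full-replacement pulse makes the realized process exactly a
single constant-size panmictic population, so the correct TT estimate is
t̂ ≈ 0 (the package recovers this); an upward-biased t̂ in that scenario
arises only when the daughter the lineages traverse differs in size from
the ancestral population, which the simulator reproduces when configured
with unequal sizes.

## Uncertainty

The weighted delete-one block jackknife recomputes any statistic on the
total counts minus one block at a time, with block weights equal to
block site counts (Busing-style unequal-group weighting, as used for
D-statistics): with n = Σm_j and h_j = n/m_j,

```
θ_J  = gθ̂ − Σ_j (1 − m_j/n) θ̂₍₋j₎
var  = (1/g) Σ_j (h_j θ̂ − (h_j−1) θ̂₍₋j₎ − θ_J)² / (h_j − 1)
```

which reduces to the classical delete-one jackknife for equal blocks
(checked against a hand-computed 3-block oracle) and is calibrated
against the empirical spread over independent multinomial replicates.
Blocks default to 5 Mb of physical span from the site tally (block size
is a free choice; 5 Mb comfortably exceeds typical human LD scale), or
equal-count blocks for simulated data. Leave-one-out replicates on which
a statistic is undefined are excluded with a warning and the remaining
blocks reweighted; fewer than two usable replicates is an error. SDs
attach to all TT and TTo quantities and to Y₁/Y₂ (whose Z-scores drive
the outgroup verdict).

## Parameters that matter

| parameter | default | units | why |
|---|---|---|---|
| μ | 1.25 × 10⁻⁸ | per site per generation | current human consensus rate; overridable everywhere |
| G | 30 | years | standard human generation time for year conversions |
| block size | 5 Mb | bp | jackknife blocks; beyond typical LD range |
| ascertainment | d_out ≥ 1 | copies | one outgroup copy certifies the variant predates the split |
| R | 2 × 10⁵ | genealogies | default MC size; SE of each p̂ ≲ 1% (warned otherwise) |
| m_tot | 10⁹ | sites | genome-scale default for simulations |
| mode | expected | — | real-valued expected counts; `multinomial` for sampled integers |

## Problem sizes in the reproduction script

`scripts/acceptance.py` uses R = 2 × 10⁶ genealogies for the vectorized
scenarios (bottlenecks and the constant control, MC error on t̂ well
under 1%), three independent replicates for the constant-scenario mean,
and R = 4 × 10⁵ for the admixture scenario on the event-driven path —
about half a minute in total on one core. These sizes are the package's
choice of comfortable MC head-room for the stated tolerances.

## Known limitations

- Sites are treated as independent; on real genomes the multinomial
  variance is optimistic and only the block jackknife gives honest
  errors.
- The 2+2 spectrum cannot separate p₀,₀ from p₂,₂ without an outgroup;
  the lump only enters through m_tot.
- ν̂ (within-branch coalescence time) is poorly determined when drift is
  weak — its influence on the probabilities vanishes as α → 1 — and is
  undefined at α̂ = 1.
- TTo's τ₄ ratio approximation is exact only for a constant ancestral
  size; under strong non-constancy it reduces, but does not eliminate,
  split-time bias.
- Recombination, multi-allelic sites, selection and polarization error
  are out of scope; inputs are assumed pre-filtered and pre-polarized.
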
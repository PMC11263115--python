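# Methods

## Model

`selfid` simulates a hermaphroditic diploid population of constant size *N*
with non-overlapping generations, in which the individual selfing rate and
genome-wide deleterious mutations evolve jointly to a
selection–mutation–drift balance.

**Genome.** Each individual carries one chromosome pair of map length
scaled to 1. The selfing-related trait *z* is controlled by `n_z` additive
loci at positions `0, 1/n_z, …, (n_z−1)/n_z`, each with two alleles of
effect ±`1/n_z` (so the genetic variance does not depend on `n_z` and *z*
is confined to [−2, 2]). Deleterious mutations follow the infinite-sites
model: each occurs at a unique real position in (0, 1) (trait-locus
positions are excluded), and all share the same selection coefficient *s*
and dominance *h*.

**Selfing rate and fitness.** The selfing rate is the logistic map
`α(z) = 1/(1 + e^{−k(z−z_c)})`; `z_c` sets the phenotype at which α = 0.5
and thereby the mean selfing rate. Fitness is
`w = w1·w2` with stabilizing viability selection `w1(z) = e^{−λz²}` (λ
chosen large enough that the phenotypic distribution stays roughly constant
across comparisons of *s* and *h*) and multiplicative deleterious effects
`w2 = (1−hs)^{n_het} (1−s)^{n_hom}`.

**Life cycle.** Each generation: (i) reproduction — for each of *N*
juveniles a mother *i* is drawn uniformly; with probability `α_i` the
juvenile is selfed (two independent meioses of *i*), otherwise a father
*j ≠ i* is drawn uniformly; (ii) meiosis — crossover count ~ Poisson(L)
with breakpoints ~ U(0,1), the starting haplotype chosen with probability
½, then Poisson(U/2) new deleterious positions ~ U(0,1) and Poisson(U_z/2)
trait allele flips per gamete; (iii) viability selection — *N* adults are
resampled from the juveniles with replacement, probability ∝ *w*. If every
juvenile has *w* = 0 the run signals extinction with its generation index.

**Measurements.** Family-level inbreeding depression is assayed by giving
every adult one selfed and one outcrossed offspring (generated by the
production meiosis path, never added to the population) and recording only
the deleterious component `w2`: `family ID = 1 − w_self/w_out`. The
population-level baseline is the ratio of means,
`δ0 = 1 − E[w_self]/E[w_out]`. Association statistics between maternal α
and mutation-copy count, `w_out`, `w_self` and family ID are reported both
as Pearson correlations and as OLS regression slopes.

## Analytic layer

For a rare modifier allele that changes its carrier's selfing rate by
`f(α)` in background α (no pollen discounting), the invasion condition is
`δ_f = 1 − E[w_self f]/E[w_out f] < ½` whenever `E[w_out f] > 0`; the
package computes the resident/modifier mean fitnesses and the advantage
`E[w_self f] − ½E[w_out f]` exactly from any per-family table.

Two measurable approximations assume offspring fitness is linear in the
mother's α:

* modifier form:
  `δ ≈ 1 − (E[w_self] + ρ_self V_α g)/(E[w_out] + ρ_out V_α g)` with
  `g = f′(ᾱ)/f(ᾱ)`; constant `f` reduces it to δ0;
* quantitative-trait form: the selection gradient on the mean selfing rate
  is `w_out(ᾱ)(½ − δ)` with
  `δ = 1 − (w_self(ᾱ) + ᾱρ_self + ½(1−ᾱ)ρ_out)/w_out(ᾱ)`.

**ρ as slope.** The ρ terms are implemented as OLS regression slopes of
offspring fitness on maternal α (Pearson r available via
`use_pearson=True`). The slope reading is the one under which the modifier
form is *algebraically exact* when `w_self(α)`, `w_out(α)` and `f(α)` are
all linear in α (verified in the test suite by comparing against the exact
`δ_f` on synthetic linear families); with Pearson r the identity fails
dimensionally. `w_self(ᾱ)`/`w_out(ᾱ)` are linear-fit values at ᾱ, which
for OLS equal the sample means.

**Thresholds.** `invasion_threshold` bisects (scipy, tolerance 1e-6) the
sign of the modifier advantage over association-free scenario families, or
of the selection gradient with ρ = 0; both recover the classical ½.

## Numerical choices

* Positions are double-precision reals; identity by descent preserves bit
  equality, so homozygosity is exact set intersection of sorted arrays.
  New-mutation draws that would collide with an existing or trait-locus
  position (probability-zero ties) are redrawn.
* Crossover segments are half-open `[prev, b)`; a position equal to a
  breakpoint belongs to the following segment.
* The per-gamete and per-generation inner loops are numba-compiled kernels
  over flat arrays (positions + offsets); the same compiled meiosis
  primitive backs both the per-individual Python API (`make_gamete`,
  `make_offspring`, …) and the batched generation step, so there is a
  single implementation of the genetic mechanics.
* Reproducibility: one PCG64 stream per run (seeded from `SimParams.seed`)
  supplies Python-level draws and per-kernel child seeds; identical seed
  and parameters reproduce every output bit. Replicate *r* of a batch uses
  `seed + r`.
* Correlations/slopes are NaN (written as `NA`) when Var(α) = 0 or, for
  family ID, when fewer than 3 families have `w_out > 0`; excluded-family
  counts are reported. Trailing-window summaries skip NaNs and report the
  number skipped.
* Homozygosity of an individual is `n_hom/(n_hom + n_het)` with 0/0 → 0 — a
  load-scale-free reading of "individual homozygosity"; the raw counts are
  also exposed, and the binned profile uses equal-width α bins with
  half-open edges.

## Default parameters and problem sizes

Defaults (`SimParams()`): N = 1000, U = 0.5, s = 0.2, h = 0.1, L = 10,
n_z = 10, U_z = 0.2, k = 3, z_c = 0, λ = 0.5, 1500 generations with the
trailing 500 averaged. These are a scaled-down version of the full-scale
study conditions (N = 20000, 5000 generations, trailing 2000), which are
available as the `full` preset; the scaled-down sizes give equilibrium
times well past the load relaxation scale ~1/(hs) while keeping a run in
tens of seconds. The initial population is mutation-free with each trait
allele drawn ±1 with probability ½; equilibrium quantities are read only
from the trailing window. Family assays can be restricted to the trailing
window (`assay_start`) since only those generations enter the equilibrium
averages.

## What the simulations do and do not show

The generator *is* the model: it emulates a single linkage group,
equal-effect trait loci, a single (s, h) class of deleterious mutations,
and soft viability selection with a juvenile cohort equal to N. Passing
tests therefore validate the mechanics and the analytic layer under these
idealizations — not real data features such as variable selection-effect
distributions, epistasis, overdominance, pollen discounting, fecundity
selection, or multiple chromosomes, all of which are out of scope.
Association magnitudes at the desk-scale N are close to, but not identical
with, their large-N values; qualitative sign structure (load association
negative; family-ID association flipping from positive to negative as *s*
grows) is robust across the tested range.

## Known limitations

* The juvenile cohort equals N before resampling, which roughly halves the
  effective population size relative to an infinite-gamete-pool scheme; at
  the tested sizes this did not measurably change the association
  statistics (checked at N = 8000).
* With saturating logistic arguments (|k(z−z_c)| ≳ 37) α evaluates to
  exactly 0 or 1 in floating point; this is exploited in tests (forced
  selfing/outcrossing) and harmless in normal parameter ranges.
* Family-ID statistics drop families with `w_out = 0` rather than assign
  ±∞; with lethal mutations and small assays this can bias the family-ID
  correlation toward the surviving families.
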
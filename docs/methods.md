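# Methods

## Model

Handedness is modeled as a threshold-free penetrance system. At a single
autosomal locus with alleles D (dextral) and C (chance), genotypes DD, DC
and CC are left-handed with probabilities l₀ = 0, l₁ = 1/4, l₂ = 1/2. The
key assumption is *deep chance*: conditional on genotype, phenotypic
outcomes are independent Bernoulli draws. This applies across individuals
(co-twins, sibs, parents) and across traits within an individual
(handedness and language dominance are pleiotropic but conditionally
independent). All predictions follow from exact enumeration under:

- random mating, Hardy–Weinberg proportions (1−c)², 2c(1−c), c²;
- autosomal inheritance, no sex effect, no assortative mating;
- parental phenotypes conditioned jointly but independent given genotypes;
- "R×L" unordered (no maternal/paternal distinction).

The multilocus variant has n unlinked loci, each D_i/C_i with frequency
c_i, and the damage-precedence rule: any C_iC_i locus ⇒ l₂; else any
D_iC_i ⇒ l₁; else l₀. The precedence is total and explicit — a CC locus
anywhere dominates regardless of other loci — which is the reading that
reproduces all stated phenotype consequences of the rule. Loci segregate
independently (free recombination); linkage is out of scope.

## Exact computations

Single-locus quantities (`dcmodel.core`) enumerate the 3×3 parental
genotype pairs, Mendelian segregation tables, and 2×2 phenotype outcomes
directly in floating point; no simulation, no approximation beyond float64.
DZ twins are modeled as full siblings (two independent Mendelian draws from
the same mating).

Multilocus family and twin predictions (`dcmodel.multilocus`) avoid the 3ⁿ
genotype space entirely. Phenotype depends on the genotype vector only
through the damage class, and the class-defining events are "no locus CC"
and "all loci DD" — monotone events in the per-locus genotype code. For a
set of k relatives the per-locus joint genotype distribution (e.g. the
27-cell parent–parent–offspring trio) is prefix-summed along each
individual's genotype axis, raised to the n-th power (multiplied across
loci when frequencies are unequal), and finite-differenced, yielding the
exact 3ᵏ joint damage-class distribution for any n at O(3ᵏ) cost. At n = 1
this reduces to the single-locus algebra (asserted in tests); for n ≤ 4 it
matches an exhaustive 3ⁿ×3ⁿ×3ⁿ enumeration oracle to 1e-12.

Population prevalence uses the closed form
p(L) = l₂[1−Π(1−c_i²)] + l₁[Π(1−c_i²)−Π(1−c_i)²] + l₀Π(1−c_i)². The
equal-c frequency for a target prevalence is found with Brent's method on
c ∈ [0, 1] (prevalence is monotone in c for ordered penetrance levels),
xtol 1e-12, reported to 5 decimals in display output. Unattainable targets
raise `NoSolutionError`; conditioning on an impossible phenotype class
raises `DegenerateConditionError` rather than returning NaN.

A note on the published frequency column this package reproduces: solving
the prevalence equation precisely yields values that differ from a handful
of the published 5-decimal entries by up to 2×10⁻⁴ (e.g. 0.11104 vs
0.11110 at n = 2); plugging the published entries back into the equation
gives prevalences between 9.97% and 10.14%. The package keeps the exact
roots — the equation, not the printed digits, is the model.

## Monte Carlo simulator

`dcmodel.simulate` draws nuclear families (two parents + one offspring),
MZ pairs (one shared genotype, two phenotype draws) and DZ pairs (two
offspring of the same parents). Families are simulated unconditionally and
stratified by the realized parental phenotype pair — per-stratum counts
therefore vary (≈81%/18%/1% of families at 10% prevalence), and each
stratum's approximate 95% CI, 1.96·√(p(1−p)/m), uses its own size m. Empty
strata are reported as undefined estimates with count 0, never as 0%.

For equal frequencies the engine exploits the damage-class sufficiency
argument again: per family it draws the multinomial counts of the 27
(parent1, parent2, offspring) per-locus trio cell types (81 cells for DZ
quads) and reads each individual's class off the counts. This is an exact
distributional reformulation — loci are iid and only "any CC / any het"
per individual matters — and makes cost independent of n, so the full
12-row table at 10⁶ replicates per row runs in seconds. Unequal-frequency
models use an explicit per-locus path over `sample_genotype`/`meiosis`;
tests verify both paths against the exact predictions. One
`numpy.random.Generator` per run, seeded from the config, gives
bit-identical estimates for a fixed seed; batches of 200,000 families bound
memory.

The default configuration is 10⁶ replicates at 10% target prevalence,
matching the published table's scale. Note that a per-stratum CI at that
scale is ±0.05% only for the large R×R stratum; the L×L stratum holds only
~10⁴ families, so its honest CI is ±0.9%. Comparisons against published
simulated values therefore combine the quoted CI with this run's own
per-stratum Monte Carlo error.

## GWAS power and sample sizes

`dcmodel.power` inverts the model to phenotype-conditional allele
frequencies: conditioning on the focal locus's genotype, the other loci
aggregate into their "any CC"/"any het" probabilities, giving a closed-form
locus marginal that is exact for every n (checked against 3ⁿ enumeration).
At n = 1, cases carry the C allele at frequency 0.60 vs 0.156 in controls.

Power is estimated by Monte Carlo: allele counts for cases and controls are
drawn as binomials (alleles treated as 2N independent draws; genotype-level
cohort sampling is available separately via `simulate_cohort`), tested with
the 1-df Pearson allelic chi-square without continuity correction — the
standard GWAS allelic test; the model names none — at α = 5×10⁻⁸
(0.05 Bonferroni-corrected for 10⁶ tests). Per-locus power and any-locus
power (≥1 significant locus) are both reported, since "power to detect a
k-locus model" is ambiguous between them. Perfect tagging (r² = 1) is the
default and upper-bounds any real chip; r² < 1 deflates the case–control
frequency difference by √r², pivoting at the sample-size-weighted pooled
frequency. A closed-form normal-approximation power formula
(`analytic_power`) serves as an independent cross-check; its own error is
a few 10⁻³ in extreme-power/deep-tail regimes, so the agreement test runs
in a moderate-power design (≈0.6 power, thousands of alleles) where the
approximation is within Monte Carlo noise. The worked single-locus design
(375 cases / 3,375 controls) assumes 10% left-handers among ~3,750
individuals, consistent with the model's prevalence.

Sample sizes for distinguishing two proportions use the pooled-variance
two-sided normal approximation without continuity correction,
N = (z_{α/2}√(2p̄q̄) + z_β√(p₁q₁+p₂q₂))² / (p₁−p₂)², rounded to the nearest
integer — the convention that reproduces both published values (24,034
parent–offspring pairs for 7.82% vs 8.52%; 18,359 MZ pairs for 14% vs
15.03%) exactly.

## What the generator does and does not emulate

The simulator generates data from the model itself: Hardy–Weinberg parents,
Mendelian segregation, penetrance-Bernoulli phenotypes. It emulates the
study conditions behind the published family/twin table (10⁶ replicates,
10% prevalence, equal frequencies) and nothing more. It does not model
chorionicity or mirror-imaging in twins, maternal or sex effects,
assortative mating, linkage, imprinting, or measurement error in handedness
classification. Passing tests therefore show internal consistency of the
model and fidelity of its published predictions — not that the model is
true of real populations; the `compare-observed` table makes the
model-vs-data gaps visible (observed MZ discordance 19.3% vs predicted
14%, for instance).

## Numerical choices and limitations

- Distributions validate to within 1e-12 of summing to 1 at construction.
- Exact quantities are float64 enumerations; agreement tolerances in tests
  are 1e-12 absolute.
- Monte-Carlo-vs-exact assertions use 5 standard errors (false-alarm
  probability < 1e-5 per cell); oracle-vs-approximation power checks use 3
  Monte Carlo standard errors.
- Test problem sizes: 2×10⁵ replicates for simulator unit checks, 10⁶ for
  the full table reproduction, 10⁵ for power runs — chosen so statistical
  tolerances are tight while the whole suite stays fast on one CPU.
- `solve_equal_c` assumes penetrance levels ordered l₀ ≤ l₁ ≤ l₂ for
  monotonicity; unordered levels may admit multiple roots and are not
  supported by the solver (the closed form itself is general).
- Unequal-frequency models with very large n use the per-locus simulation
  path, whose cost grows linearly in n.
- The package does not implement continuous liability-shift models of
  handedness (a different parameterization), sex-linked inheritance, or
  selection dynamics; these are outside its scope.
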
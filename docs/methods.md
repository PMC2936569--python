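# Methods

`tablup` implements genomic prediction of breeding values with a
trait-specific marker-derived relationship matrix (TABLUP), alongside
the three reference methods it is meant to be compared with — ridge
regression BLUP (RRBLUP), BayesB and GBLUP — and the forward-in-time
simulator that defines the validation design. This note records the
models, the parameter choices and the numerical decisions, in that
order.

## The marker model and the two estimators

All marker-effect estimation happens in a training population where
every individual is genotyped and phenotyped, under the linear model

    y = Xb + Σ_i Z_i g_i + e,   e ~ N(0, I σ_e²),  g_i ~ N(0, σ_gi²)

with the overall mean as the only fixed effect and genotypes coded
−1/0/1 for the 11, 12 and 22 genotypes. The two estimators differ only
in their prior for the per-marker effect variance σ_gi²:

* **RRBLUP** — every marker shares σ_gi² = σ_a²/N, with σ_a² the true
  (simulated) total additive variance and N the marker count. The
  ridge system is solved in the individual dimension
  (V = ZZ'σ_g² + Iσ_e², an n×n system) because N ≫ n; equivalence with
  the marker-dimension mixed-model equations is a tested property.
  The factorisation is cached (`RidgeSolver`) so several phenotype
  vectors on one panel are cheap.
* **BayesB** — σ_gi² is 0 with probability π and scaled inverse-χ²
  (df = 1) with probability 1 − π, where 1 − π is set to the true
  ratio of QTL to markers. The sampler is the classical mixture of
  Gibbs and Metropolis–Hastings: each Gibbs cycle visits every marker,
  runs 100 MH proposals for the (indicator, variance) pair — proposing
  from the prior and accepting on the marginal likelihood ratio with
  the marker effect integrated out, which makes one proposal O(1)
  given the precomputed residual projection — then draws in-model
  effects from their full conditionals. Defaults: 10,000 cycles,
  2,000 burn-in. Post burn-in means give the effect estimates and the
  posterior per-marker variances.

Two BayesB details are not fully determined by the published
description and were fixed as follows:

* **Prior scale.** The scaled inverse-χ² with df = 1 has no finite
  mean, so the scale cannot be set by matching a prior mean. We set it
  so the prior *mode* of an in-model variance equals
  σ_a² / ((1−π) Σ_k 2p_k(1−p_k)), the value that reproduces the total
  additive variance in expectation. The scale is configurable.
* **Residual variance.** Held fixed at its simulated true value, in
  line with providing true variance components to every method, rather
  than being sampled.

## The relationship matrices

For a pair of individuals, the per-locus similarity score averages the
four cross-individual allele identity comparisons (so scores lie in
{0, ¼, ½, ¾, 1} and no phasing is needed). For biallelic loci coded
as allele counts x ∈ {0,1,2} this has the closed form
S = (1 + c_i c_j)/2 with c = x − 1, which reduces the whole matrix to
one rank-N product; the literal four-comparison definition is kept as
an independent implementation and cross-checked exhaustively.

A weighting scheme turns similarity into a trait-specific matrix:

| scheme | weights w_k | mean-IBS correction | diagonal |
|---|---|---|---|
| G (GBLUP) | uniform | yes | self-similarity |
| TAP | 2p_k(1−p_k)ĝ_k² from RRBLUP | yes | self-similarity |
| TAB | posterior variance from BayesB | yes | self-similarity |
| TAB\*/TAP\* (ad hoc) | \|ĝ_k\| | no | fixed at 1 |

The weighted average S_ij = Σ w_k S_ijk / Σ w_k is corrected with the
population mean IBS, f_ij = (S_ij − S̄)/(1 − S̄), and doubled, since
relatedness is twice the kinship. Conventions the source description
leaves open, fixed here: S̄ averages off-diagonal pairs only (so
self-similarity does not deflate the baseline), and the diagonal runs
through the same correction (2f_ii), which keeps individual
homozygosity excess visible. The ad-hoc variants return the raw
weighted IBS with a unit diagonal.

**Indefiniteness is structural, not numerical.** The corrected matrix
is an affine map of a PSD similarity matrix minus the rank-one
baseline S̄·11', so it carries at most one negative eigenvalue; at
realistic scale that eigenvalue is large (≈ −12 for 2,000 individuals
on 5,000 markers) and its eigenvector is ~80 % aligned with the
all-ones vector. An indefinite matrix cannot serve as a covariance,
and Gauss–Seidel diverges on the resulting system. The solver
therefore clamps eigenvalues below 1e-4 of the largest to that floor
whenever a Cholesky factorisation fails. This is equivalent to
shrinking the breeding-value component along the offending
intercept-like direction to zero — a direction the fixed mean absorbs.
On full-scale data the clamped Gauss–Seidel solution matches the
inverse-free BLUP form u = G_cw (G_ww + λI)⁻¹ (y − μ̂) to three
decimals in accuracy; the agreement is also a tested property.

A related size constraint: the weighted-IBS matrix has rank at most
N + 1, so a matrix over more individuals than markers is singular.
Predictions are therefore computed per candidate generation (training
+ that generation), which is exact — BLUP predictions are invariant to
dropping unphenotyped individuals (Schur-complement identity of the
inverse) — and keeps every system comfortably full-rank. An optional
`jitter` ridge exists for deliberately tiny panels.

## Breeding-value prediction

GBLUP/TABLUP solve Henderson's mixed model equations with
λ = σ_e²/σ_a² and the numerically inverted relationship matrix, by
Gauss–Seidel iteration (tolerance 1e-8 on the largest absolute update,
at most 10,000 sweeps; non-convergence is reported, never silently
accepted). Candidates enter with zero records and are driven purely by
the inverse-relationship block. RRBLUP and BayesB predictions are the
direct sums Z ĝ. True variance components are supplied throughout;
variance-component estimation (REML) is out of scope.

## The simulator

The simulator defines the study conditions and is first-class, tested
code:

* **Genome** — 5 chromosomes × 1 Morgan, 1,000 markers per chromosome
  placed uniformly at random, one potential QTL slot at the midpoint
  of every inter-marker segment (5,000 markers, 4,995 slots).
  Midpoints are a choice; the source only places one slot per segment.
* **Recombination** — Haldane map function, no interference,
  per-interval Bernoulli source switching; chromosomes segregate
  independently (switch probability ½ at each chromosome start).
* **History** — 1,000 non-overlapping generations of 50 monogamous
  pairs, two offspring (one of each sex) per pair; infinite-alleles
  mutation in every historical generation at a per-copy, per-locus
  rate of 1.25e-3.
* **Effective size and heterozygosity.** Because every pair leaves
  exactly two offspring, the variance of family size is zero and the
  effective size of the census-100 population is Ne = (4N−2)/2 = 199.
  With u = 1.25e-3 this gives θ = 4Ne·u ≈ 1.0 and equilibrium
  heterozygosity θ/(1+θ) ≈ 0.5 — the stated design value. Reading the
  design as Ne = 100 would wrongly suggest the rate and the
  equilibrium are inconsistent; they are not.
* **Recoding** — in generation 0 every locus collapses to a SNP: the
  allele with frequency closest to 0.5 becomes allele 1 (ties toward
  the smaller label), all others become allele 2. Monomorphic loci
  stay in the panel as constant columns; they receive zero TAP weight
  automatically.
* **Validation structure** — generation 1: 50×50 monogamous pairs,
  20 progeny per dam (the 1,000 phenotyped training individuals);
  generations 2–6: 50 sires drawn from the 500 males of the previous
  generation × 10 dams each × 2 progeny. No mutation after the
  historical phase.
* **Trait** — n_qtl slots drawn among slots polymorphic in
  generation 1 (drawing directly from the polymorphic set is
  distributionally identical to rejection-resampling); |a_i| ~
  Gamma(0.4, 1.66) with random sign; effects rescaled so
  Σ 2p_i(1−p_i)a_i² = σ_A² = 1 exactly at generation-1 frequencies,
  ignoring linkage disequilibrium between QTL. Phenotypes exist in
  generation 1 only: P = TBV + N(0, σ_e²) with σ_e² = σ_A²(1−h²)/h².
* **Randomness** — one master seed per replicate, split into
  independent child streams (map, history, breeding, trait,
  phenotypes, MCMC); replicates are spawned children of a scenario
  seed, so every run is bit-reproducible and single replicates can be
  re-run in isolation.

What the generator does *not* emulate: genotyping errors and missing
genotypes, non-additive gene action, selection other than the random
sire sampling, overlapping generations, sex chromosomes, and real
linkage-disequilibrium structure beyond what mutation–drift at
Ne ≈ 200 produces. Passing tests therefore demonstrate correctness of
the methods under this idealised architecture, not performance on real
livestock data.

## Evaluation

Accuracy is the Pearson correlation between predicted and true
breeding values among individuals without records, reported per
generation; Spearman rank correlation and the slope of TBV regressed
on GEBV (1 = unbiased) complete the picture. Persistency is the mean
one-generation accuracy decline from generation 2 to 6, computed as
(acc₂ − acc₆)/4 — for a monotone sequence identical to the mean of
successive differences, and robust when the sequence is not monotone.
Replicate aggregation reports mean ± SE (sd/√n; undefined for a single
replicate).

## Problem sizes in the test suite and the replication script

The replication script (`scripts/acceptance.py`) runs the full design:
5,000 markers, 1,000 historical generations, 10 replicates, for the
methods whose estimation step is direct (RRBLUP, GBLUP, TAP) — about
ten minutes on one core. The test suite splits its budget: the same
full-scale ten-replicate run backs the accuracy-band checks for those
three methods, while BayesB and the TAB matrix — hours of MCMC at the
published chain length — run at desk scale (2,500 markers, 400
historical generations, 2,000-cycle chains, candidate generations
evaluated on random 400-subsets) for the ordering, persistency and
bias-sign checks, and the heritability/QTL sweeps run on a smaller
panel still (1,500 markers, 250 generations, 800-cycle chains, shared
genomes across levels so only the intended factor varies). The
population design itself (1,000 training individuals, 1,000 candidates
per generation, the Ne ≈ 200 history) is never scaled down, because
prediction accuracy is driven by training size and effective segment
count; equilibrium depth matters too — shortening the history lowers
marker heterozygosity and with it every method's accuracy, which is
why the band checks stay at full scale. Subsampling candidates only
widens the sampling noise of an estimated correlation; shortening the
chain mildly degrades BayesB/TAB, which is why their absolute levels
are checked through orderings and contrasts rather than tight bands at
desk scale.

## Known limitations

* The PSD clamp is a repair, not a derivation; a construction that is
  PSD by design (e.g. VanRaden-type cross-products) would avoid it at
  the cost of departing from the IBS scoring rule implemented here.
* BayesB mixing at df = 1 is heavy-tailed; posterior variance weights
  for markers with weak signal carry occasional large draws. Longer
  chains smooth this; the desk-scale chains in the tests do not fully.
* The Gauss–Seidel solver is dense and single-threaded; systems much
  beyond ~5,000 individuals per generation would want a sparse or
  preconditioned-Krylov treatment that is out of scope here.
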
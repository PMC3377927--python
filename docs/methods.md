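# Methods

## Genetic model

One QTL in a full-sib cross between heterozygous parents P1 (alleles
1/2) and P2 (alleles 3/4) has four offspring genotypes, ordered
canonically 13, 14, 23, 24. Its genotypic value decomposes as
μ_uv = μ + α_u + β_v + γ_uv. The raw allelic effects are not estimable;
the identifiable parameterization sets α = α₁ = −α₂, β = β₃ = −β₄ and
γ = γ₁₃ = −γ₁₄ = −γ₂₃ = γ₂₄, which is exactly a ±1 contrast coding: the
4×4 design matrix has columns 1, A = (1,1,−1,−1), B = (1,−1,1,−1) and
G = A∘B over the canonical order.

For two QTLs the 16 genotypes are ordered with QTL 1 varying slowest
(13/13, 13/14, …, 24/24) and the 16×16 design matrix **D** is built
column-wise from Kronecker products of {1, A, B, G}: main effects pair a
contrast with 1, epistatic effects pair two contrasts (e.g. the
additive×dominance term J_αγ is A⊗G). This construction makes
DᵀD = 16 I, hence u = D a and a = Dᵀu/16 are exact inverses, and the
contrast of each effect (its column of D) has eight +1 and eight −1
entries. The 15 columns were validated against the published constraint
equations of the corresponding null hypotheses; 13 match exactly and two
contain one-genotype transcription errors in print (a genotype appearing
on both sides of the identity), for which the internally consistent
design-matrix columns are used: the dominance-side constraint of the
additive×dominance effect J_βγ (right-hand side) and of the
dominance×additive effect K_γβ (left-hand side, 13/24 in place of
23/24).

Setting the two parental allele systems equal (1≡3, 2≡4) collapses the
decomposition to the classical biallelic additive–dominance–epistasis
model; the package tests this as a heterozygote symmetry (genotypes 14
and 23 receive identical values when the α- and β-type effects agree).

`genetic_variance` is the variance of the 16 genotypic values under
**equal (1/16) genotype frequencies**, which by orthogonality is the sum
of squared non-intercept effects. Equal weights deliberately ignore the
linkage between the two QTLs; this is the convention under which the
benchmark residual variances (1334.25 at h² = 0.1, 222.375 at h² = 0.4)
follow from the benchmark effects, and it defines what "heritability"
means in the simulator. With linked QTLs (40 cM apart, recombination
0.275) the realized genotype frequencies are mildly non-uniform, so the
realized phenotypic heritability in simulated families is slightly below
the nominal value (≈0.36 for nominal 0.4); the simulator tests account
for this.

## Conditional QTL genotype probabilities

Each parental gamete is a Markov chain of grandparental origins (0/1)
along a linkage group; the origin flips between consecutive loci with
probability r = (1 − e^(−2d/100))/2 (Haldane, no interference). The
Haldane choice is what makes the chain Markov, which in turn justifies
conditioning each QTL on its flanking markers only and factorizing the
joint distribution of two QTLs in distinct marker intervals. Markers are
assumed fully informative (cross type 12×34) with known linkage phase,
coded so that the transmitted allele identifies the origin; missing
marker genotypes are rejected rather than marginalized.

The implementation merges QTL positions into the marker chain and, for
each of the 2^k origin configurations of the k QTLs, multiplies the
transition probabilities of the segments adjacent to a QTL locus
(segments between two observed markers are constant across
configurations and cancel in the normalization). This one code path
covers QTLs in the same interval (where the direct q1–q2 segment
appears), distinct intervals, QTLs exactly on markers (zero-length
segments degenerate cleanly to indicators), and, by outer product,
different linkage groups. The 16 genotype weights ω are the product of
the P1-gamete and P2-gamete joint origin probabilities. Correctness is
tested against an exhaustive enumeration oracle over all origin
sequences of the merged chain.

## EM algorithm

At fixed positions the likelihood is a 16-component normal mixture with
known weights ω and unknown class means u and common variance σ². The
E-step computes genotype posteriors (stably, via max-subtraction in log
space); the M-step sets each class mean to its posterior-weighted
average and σ² to the posterior-weighted mean squared residual with the
**1/n divisor** (the ML estimator — its downward bias at small n is
expected and reproduced by the studies). Choices the model statement
leaves open were fixed as follows:

* **Initialization**: ω-weighted class means of y and the total
  phenotypic variance. Deterministic by default (reproducibility);
  `fit(..., n_starts=k)` adds random restarts (class means resampled
  from y) and keeps the best final log-likelihood.
* **Convergence**: absolute log-likelihood increment < 1e−8, cap 2000
  iterations; non-convergence is recorded on the fit, not fatal, and
  scan logs count non-converged fits.
* **Empty classes**: a class with posterior mass < 1e−10 keeps its
  previous mean for that iteration (its update is 0/0).
* **Constrained M-step**: under a single contrast cᵀu = 0 the exact
  Q-function maximizer is the weighted-least-squares Lagrange solution
  u_g = ȳ_g − λ c_g/n_g with λ = (Σ c_g ȳ_g)/(Σ c_g²/n_g); frozen
  classes contribute a constant offset to the constraint. σ² is
  recomputed from the constrained means. The starting point is projected
  onto the constraint plane so every iterate is feasible.
* **σ² floor** of 1e−12 to keep the E-step defined on degenerate
  (noise-free) data.

EM monotonicity is asserted per iteration in the tests. Because EM can
stop in a local maximum, the effect-testing routine exploits model
nesting: if a constrained fit ever outscores the full fit, the full EM
is restarted from the constrained solution before any LR is formed,
keeping every reported LR non-negative.

## Scan, permutations and effect tests

The 2-D scan evaluates all position pairs on a grid (default step 2 cM,
configurable) over one pair of linkage groups. For a group paired with
itself, only pairs with pos1 < pos2 in **distinct marker intervals** are
scanned: with conditioning on flanking markers only, two QTLs inside one
interval are weakly identified. The existence null is the single-normal
(no-QTL) model, so LR = 2(lnL₁ − lnL₀) is scan-wide comparable; ties at
the argmax resolve to the lexicographically smallest pair. LR is
invariant under affine phenotype transforms and offspring reordering
(tested).

Permutation thresholds shuffle phenotypes against fixed genotypes,
rescan fully, and take the ⌈(1−α)·n_perm⌉-th order statistic of the
per-permutation maxima — a group-pair-wide threshold, not genome-wide.
The mixture weights for the grid are computed once and reused across
permutations.

Effect-test thresholds are not tabulated: the helper
`effect_test_threshold` draws parametric-bootstrap datasets from the
constrained (null) MLE — genotype per offspring from its ω row, residual
normal — and refits both models per draw. Under a true null the
effect LR behaves approximately as χ²(1) (tested by simulation).

## Simulator and benchmark design

`simulate_family` draws one P1 and one P2 gamete per offspring along
every group (QTL loci inserted into the chain), records transmitted
alleles at markers, and sets phenotype = true genotypic value + normal
error with σ² = V_g(1−h²)/h². Parental QTL alleles are taken in coupling
phase with the markers (origin 0 ↔ allele 1 resp. 3) — a simulator
convention that does not affect estimation.

The named `benchmark` preset is the reference study design: one 100 cM
group with six equidistant markers (0, 20, …, 100 cM — the only
equidistant reading of "six even-spaced markers"), QTLs at 30 and 70 cM,
and a fixed effect vector (μ = 50, α₁ = 2, β₁ = 3, γ₁ = 4, α₂ = −3,
β₂ = 1, γ₂ = −2.5, I = −2, 2.5, −3, 3.5, J = −4, −4.5, K = −2, 2.5,
L_γγ = −5; V_g = 148.25). Study drivers in `epiqtl.study` replicate
simulate-and-refit cycles with per-replicate seeds spawned from one
master seed.

What the simulator does **not** emulate: genotyping errors, missing or
partially informative markers, selective genotyping, polygenic
background variation, crossover interference, and sex-specific
recombination. Passing tests therefore demonstrate correctness of the
estimator under its own model assumptions, not robustness to these
real-data complications.

## Problem sizes in the shipped studies

The acceptance studies use 200 replicates of the n = 400, h² = 0.4
scan design (full 2 cM grid, 1040 position pairs per replicate) and 100
replicates of the n = 800 fixed-position design; replicate-mean
tolerances are scaled accordingly (3·s.e./√reps against the published
1000-replicate means). The null-calibration property uses a deliberately
small design (three markers, n = 60, 39 permutations, 200 replicate
datasets) where the exchangeability argument makes the nominal size
exact up to binomial noise.

## Known limitations

* Only fully informative 12×34 markers; other segregation types
  (testcrosses, dominant markers) and phase estimation are out of scope.
* Exactly two QTLs per model; no multi-pair search or model selection
  across >2 QTLs, and no FDR control across group pairs.
* No standard errors on effect estimates (LR tests serve inference).
* Same-interval QTL pairs are excluded from scans by design.
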
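# Methods

## Scope and model

`oystergs` evaluates quantitative traits in a closed, two-generation
full-sib breeding population under the additive animal model

    y = Xß + g + e,    g ~ N(0, K σ²ₐ),    e ~ N(0, I σ²ₑ),

with a single genetic random effect and independent residuals. No
dominance, common-environment (full-sib tank) or maternal components are
fitted; in a real full-sib design without environmental replication those
effects would inflate σ²ₐ, which is a limitation of the model class, not of
the implementation.

## Synthetic data generator

The generator emulates the structure of the target breeding program, and
its defaults are the program's published design:

* **Pedigree.** 57 generation-1 full-sib families (one new sire x one new
  dam each, founders unrelated) with 2–8 offspring, then 33 generation-2
  families of 12–15 offspring whose parents are generation-1 individuals
  from different families, each used at most once. This yields roughly
  650–780 phenotyped animals; the real program genotyped 647.
* **Genotypes.** Gene dropping over unlinked biallelic loci: founders are
  drawn from Hardy–Weinberg proportions at frequencies p ~ Uniform(0.05,
  0.5) (the site-frequency spectrum of the real panel is unknown;
  configurable, default chosen to give mostly informative markers), and
  each non-founder receives one allele per parent per locus. The default
  marker count is 13,048 (the post-QC panel size); recovery experiments use
  2,000, which is enough for G to estimate relationships with SE well below
  the family-structure signal.
* **Phenotypes.** Eleven default traits (whole weight, cup/fan ratio, soft
  tissue weight, condition index, shell and mantle L\*/a\*/b\*) with means,
  SDs, per-trait missingness (reproducing the per-trait sample sizes out of
  647) and heritabilities between 0.14 and 0.77 taken from the program's
  summaries. Marker effects are i.i.d. normal per trait — the same
  equal-variance assumption GBLUP makes — and correlated across traits via
  the Cholesky factor of a genetic correlation matrix. Only the
  correlations with whole weight are known (e.g. 0.63 with soft tissue
  weight); the matrix is completed by the single-factor structure
  R_ij = c_i·c_j, which is PSD for any |c| ≤ 1. Residuals are uncorrelated
  across traits by default.
* **Scaling of genetic variance.** Marker-effect variance is set so that,
  *given the realized marker matrix*, the expected sample variance of
  g = Mα equals h²σ²_p. The realized genetic variance therefore fluctuates
  across replicates exactly as the fitted model assumes, which keeps the
  AI-matrix standard errors comparable to the replicate-to-replicate
  scatter of the estimates. (Forcing the realized variance to the target
  exactly would shrink that scatter and make the reported SEs look
  conservative.)
* **Fixed effects.** Generation (+0.3 SD for generation 2 by default), sex
  (Bernoulli(0.5), +0.1 SD for males), their interaction (+0.05 SD), and
  age at harvest ~ Normal(270 d, 15 d) with a per-generation slope —
  harvest age centers around the program's ~9-month grow-out.

What the generator does **not** emulate: linkage and LD between markers,
selection or mortality between generations, genotyping error, common
full-sib environmental effects, and founder population substructure.
Passing recovery tests therefore demonstrates correctness of the
estimators under the stated model, not robustness to those real-data
complications; in particular the simulated F_ST among generation-1
clusters is near zero because founders are exchangeable.

## Quality control

Markers are retained when their call rate is ≥ the threshold (default 0.5,
inclusive — a marker genotyped in exactly half the samples survives).
Missing calls are then replaced by the per-marker mean of observed calls,
which preserves allele frequencies exactly; fractional genotypes are used
as-is in G. No MAF or HWE filter is applied. The optional per-sample
call-rate filter is off by default. VCF export writes hard calls only
(missing as `./.`) on synthetic one-position contigs, since
reduced-representation tags are unplaced.

## Relationship matrices

`grm_vanraden` centers genotypes by 2p̂ⱼ (observed sample frequencies by
default — no base-population frequencies are available in practice) and
scales by Σ2p̂q̂; `grm_gcta` standardizes each marker and averages,
excluding monomorphic markers. Column-centering at sample frequencies
forces Σᵢⱼ G_ij = 0, so G is always singular along the ones vector and its
related-pair entries sit slightly below the pedigree expectations — tests
that compare G classes to A entries center at founder frequencies instead.
`nrm` is the textbook tabular recursion (diagonal 1 + F) after an internal
topological sort; cycles are reported. If the smallest eigenvalue of a
relationship matrix falls below 1e−8, a diagonal ridge of 1e−6 (plus any
deficit) is added before inversion and logged.

## AI-REML

One Newton-type optimizer serves both models. Per iteration: V is built
and Cholesky-factored; the projection matrix P = V⁻¹ − V⁻¹X(X′V⁻¹X)⁻¹X′V⁻¹
is formed once; gradients use tr(P·∂V/∂θ) computed from P blocks by
elementwise products (never forming P·∂V); the AI matrix is
0.5·(∂V·Py)′P(∂V·Py). The first two iterations are EM-REML steps
(θ ← θ + 2θ²·grad/n), which are slow but safe; afterwards AI steps are
halved up to 30 times to stay inside the parameter space, with an EM
fallback. Variances are floored at 1e−6 times the OLS residual variance;
covariances are constrained to |cov| ≤ (1−1e−6)·√(v₁v₂), so a genetic
correlation estimated at the boundary reports as ≈ ±1 with the `boundary`
flag set. Convergence requires |ΔlogL| < 1e−6 (relative parameter change
< 1e−5 also terminates), with a 100-iteration cap; non-convergence returns
the last iterate flagged. If the AI matrix is numerically singular
(condition number > 1e10 — e.g. K = I, where genetic and residual variance
are indistinguishable), updates switch to the pseudo-inverse and the fit
is flagged non-identifiable.

The bivariate model stacks the two traits' records. The genetic covariance
acts through the relationship submatrix between the two sample sets; the
residual covariance applies only where the same animal carries both
records, which is the standard missing-at-random treatment of partially
observed trait pairs. Standard errors come from the inverse AI matrix at
the optimum; h² and r_g use the delta method. Starting values split the
per-trait OLS residual variance in half, with covariances starting at 0.

## GBLUP, ASE and cross-validation

Henderson's MME are solved densely with λ = σ²ₑ/σ²ₐ (n ≈ 650 needs no
sparse machinery). Every animal in K receives a genetic value, so
cross-validation predicts held-out animals simply by masking their
phenotypes while keeping their genotypes in G (`strict_exclusion`
alternatively removes them from K and predicts by the conditional
expectation K_vt K_tt⁻¹ ĝ_t). Variance components are re-estimated inside
every training fold to avoid leakage.

Allele substitution effects are back-solved from ĝ. Because sample-frequency
centering makes G singular along the ones vector, the mean of ĝ cannot be
carried by any marker: α̂ is solved against the pseudo-inverse of G on the
centered ĝ and the mean is returned as an explicit offset to be added to
the fixed part, after which Mα̂ + offset reproduces ĝ to the rank of G.

Predictive ability is reported as the R² of the regression of observed on
predicted phenotypes (equal to the squared Pearson correlation for a
simple regression), pooled per replicate and averaged over the five
replicates; a best-fold summary is also recorded because single best folds
are sometimes quoted in the field. Folds are sample-random; note that with
full-sib structure, random folds leave sibs of every held-out animal in
training, which is the easiest (most optimistic) validation layout.

## Population structure

Pairwise divergence is the allele-sharing distance (mean over markers
non-missing in both individuals of |xᵢ−xⱼ|/2); a raw differing-site count
is available as an option. Nucleotide diversity π is the mean pairwise
divergence per assayed SNP site; dividing by a tag length (e.g. the
sequenced tag size) rescales it to per-base. Neighbor joining follows
Saitou–Nei with deterministic tie-breaking (smallest row/column index) and
negative branch lengths clamped to zero with the deficit moved to the
sister branch, preserving the joined pair's total length; NJ is consistent
on additive matrices, and the tests verify exact recovery. Clusters are
obtained by cutting the (k−1) longest internal branches, and
F_ST = (π_T − π_S)/π_T with π_S the size-weighted mean within-cluster
diversity, clamped to [0, 1]. Note that for an arbitrary (non-genetic)
partition the unclamped value can be negative by sampling noise — the
inequality π_T ≥ π_S holds in expectation and for genuinely differentiated
clusters, which is what the tests exercise. One individual per full-sib
family is selected before tree building (`select_unrelated`) so sibling
clusters do not masquerade as population structure. Whole-weight classes
are left-closed bins I: [30,40) … IV: [60,70), V: ≥ 70 g; animals under
30 g are labeled `unbinned` rather than guessed into class I.

## Problem sizes and numerical choices

Recovery experiments run the default family design (~650+ phenotyped
animals) with 2,000 markers and 10–20 simulation replicates; the balanced
ANOVA cross-check uses 50 families of 10; oracle equivalence checks run at
n ≤ 30 against direct V⁻¹ GLS inversion. These sizes put every Monte Carlo
band (±0.05 on mean h², ±0.10 on mean r_g) at several standard errors of
the mean. All randomness flows from explicit integer seeds through
`numpy.random.default_rng`; a fixed seed reproduces pedigrees, genotypes,
phenotypes and report files byte-for-byte.

## Known limitations

* Univariate and bivariate models only; no >2-trait REML, no Bayesian
  whole-genome regression, no single-step (H-matrix) blending.
* Dense O(n³) algebra throughout — appropriate for n in the hundreds to a
  few thousand, not for national evaluations.
* The AI-based SEs are Wald-type; near parameter boundaries (h² → 0 or
  |r_g| → 1) they are optimistic, as usual for REML.
* The weight-class boundary convention (left-closed) and the per-SNP-site
  π denominator are documented choices; alternatives are exposed as
  options, not defaults.
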
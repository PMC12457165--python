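# Methods

## The model

All breeding-value estimation uses the single-random-effect linear mixed
model

    y = Xβ + u + e,   u ~ N(0, σ²g G),   e ~ N(0, σ²e I)

where G is the additive genomic relationship matrix and X holds the fixed
effects (intercept always; by default birth year as categorical indicators
with the first level dropped, plus the first three genomic principal
components; optionally index scores such as the Behavior Score). Binary and
ordinal responses are fitted on their observed 0/1/k numeric scale — no
threshold-model link — so every trait yields a continuous genomic
prediction that can be thresholded or rank-scored downstream. This mirrors
standard practice in breeding programs, where the linear GBLUP machinery is
applied uniformly and classification is a post-processing step.

**GRM.** Single-ratio ("method 1") construction: per-SNP mean imputation of
missing dosages, centering by twice the sample allele frequency, then
G = MMᵀ / Σⱼ 2pⱼ(1−pⱼ) over polymorphic SNPs. Allele frequencies come from
the analyzed sample itself. A per-SNP-standardized variant is available via
`compute_grm(..., method="standardized")`; the two differ only in how SNPs
are weighted and agree in expectation under the simulator's architecture
(effect variance constant per SNP matches method 1). Principal components
are eigenvectors scaled by the square root of their eigenvalues, with a
deterministic sign convention (largest-magnitude coordinate positive); any
affine rescaling is absorbed by the fixed-effect coefficient.

**REML.** Writing V = σ²(h²G + (1−h²)I), one eigendecomposition of G
rotates the model to independent coordinates; β and σ² profile out in
closed form, leaving a 1-D restricted log-likelihood in h² maximized by a
21-point grid plus bounded Brent refinement (tolerance 1e-8) with the h²=0
and h²=1 boundaries checked explicitly. Boundary solutions are legitimate
and flagged. The reported pseudo-heritability is σ²g/(σ²g+σ²e) = ĥ². If G
has a negative eigenvalue (numerically possible after imputation), a ridge
of 1e-6 × mean diagonal is added.

**BLUP and holdout prediction.** At the estimated components,
β̂ = (XᵀV⁻¹X)⁻¹XᵀV⁻¹y and û = σ²g G V⁻¹(y − Xβ̂), both evaluated in the
eigenbasis where V is diagonal. Held-out individuals are predicted by the
conditional expectation û_test = G_test,train G⁻¹_train,train û_train
(ridge-stabilized at 1e-8 × mean diagonal), with predicted phenotype
X_test β̂ + û_test. For this model the conditional-expectation route is
equivalent to solving one joint mixed-model equation system with missing
responses, and much simpler to validate against a dense-algebra oracle;
that equivalence is why it was chosen. Fixed-effect columns that are
constant within a training fold (e.g. a birth-year level absent from the
fold) are dropped for that fold.

## Quality control

Filters run in the conventional order — variant call rate, sample call
rate, Hardy–Weinberg, MAF — with defaults 0.90 / 0.90 / p < 1e-5 / 0.01.
All thresholds are strict inequalities on the failing side ("less than"
removes). The HWE test is the plain two-sided exact test: enumeration of
all heterozygote counts conditional on the allele counts, summing the
probabilities of configurations no more probable than the observed one
(log-space, stable to n in the thousands); monomorphic sites return p = 1.
A mid-p variant was considered and not used: the plain exact form is the
default in the standard GWAS toolchain this pipeline mirrors. HWE is
computed on all samples, not founders only. The filter order and test form
are configurable at the API level; the defaults are what the QC report
documents.

## Selection indices

Behavior traits arrive as trainer categories and are condensed to ordinal
scores (`standardize_trait`); the shipped map pools adjacent thin
categories so each retained level holds at least ~5% of the reference
colony, and reproduces that colony's published score-level counts exactly
(a test asserts this). Normalization is direction-aware — negative traits
(neck, distraction, rating) use |xₘₐₓ−x|/xₘₐₓ, positive traits (soundness,
trainability) use x/xₘₐₓ, optimum-at-middle traits (pace, pull) use
1−|x−1| — so 1 is always "closer to optimal".

**Weight sign.** The Behavior Score multiplies each normalized value by the
magnitude of the trait's correlation with success. Using the signed
correlation after direction normalization would re-penalize traits that the
normalization already inverted, contradicting the 1-is-optimal semantics;
the signed literal reading remains available via `raw_sign_weights`. The
Health Score keeps signed correlations (all health weights are negative, so
it is ≤ 0 by construction, each diagnosis subtracting its correlation
magnitude). The Total Score weights w_health and w_behavior default to
0.02 and 0.324 — the magnitudes of the two scores' own correlations with
success — and are configurable; no canonical pair is published.

**Open scale choices.** The trainability instrument's raw scale is not
published; it is treated as positive-direction with x_max = 4 on a 5-level
ordinal scale (configurable — users with the real instrument must set
x_max to its observed maximum). Health Score sums exactly the 20
catalogued health conditions. Counts tally diagnosed conditions per
category (dental, ocular, dermal), with the Health Count covering every
group including neurological, musculoskeletal, congenital and infectious
conditions that have no dedicated count.

## Evaluation

Five-fold cross-validation partitions individuals uniformly at random
(seeded, unstratified by default; sizes differ by at most one, every dog is
held out exactly once). Metrics are matched to trait type — MCC + AUROC
(binary), Kendall τ-b + Spearman ρ (ordinal), Pearson R + NMSE
(continuous) — and reported both pooled over the concatenated out-of-fold
predictions and per fold. Conventions:

* MCC returns 0 when any denominator factor is zero — the degenerate case
  where a low-prevalence trait's linear predictor never crosses the class
  threshold, which is the typical outcome for rare binary traits.
* Classification uses the simplest rule consistent with that behavior:
  binary class 1 at prediction ≥ 0.5; ordinal rounding to the nearest
  valid class, clipped. Both are exposed as options, not hard-coded policy.
* AUROC is the rank-based (Mann–Whitney) form with ties credited ½;
  undefined when a class is absent, reported as missing.
* NMSE divides the mean squared error by the population (divide-by-n)
  variance of the observations, so a constant-at-the-mean predictor scores
  exactly 1.

## The synthetic-data generator

The generator emulates the statistical structure the analysis assumes, at
the documented colony scale: 844 dogs (500 founders, 344 offspring of
which 172 form recorded parent trios; the other offspring descend from
unrecorded parents drawn from the founder distribution), 20,000 unlinked
biallelic SNPs with founder frequencies uniform on (0.05, 0.5), genotypes
missing completely at random at 8.6% (matching a 91.4% genotyping rate),
birth years uniform over 26 seasons with an optional additive year effect
(default 0) to exercise the fixed effect, 20 binary health diagnoses at 5%
prevalence (prevalences are not published; "low prevalence, incidental
findings" guided the choice), and 7 behavior traits with the published
category frequencies. Per-trait heritabilities are the published marker
heritabilities (trainability 0.147 from the tabulated value; a conflicting
in-text 0.47 exists and the table was taken as authoritative).

Traits follow a liability-threshold model: ~200 causal SNPs per trait with
Gaussian effects, genetic values standardized to variance exactly h²,
independent N(0, 1−h²) environmental noise (optionally equicorrelated
across traits via `residual_corr`, default 0 — no residual trait
covariances are published), and thresholds at standard-normal quantiles of
the configured prevalence/category frequencies. Loci are unlinked and
there is no recombination map: the analysis uses only relationship, never
linkage, and unlinked loci give the same GRM expectations with far simpler
code. Training success is a weighted sum of trait liabilities plus noise,
dichotomized at a 50% success rate (not published; typical program rates
guided the choice); the latent weights are deflated by the
dichotomization attenuation factor φ(z)/√(q(1−q)) so the realized
point-biserial correlations between the binary outcome and the trait
liabilities approach the published correlation table (trainability ≈ 0.53
dominating). A single integer seed determines every output bit.

**What the generator does not emulate — and what that means for the
numbers.** Real colonies carry deep multi-generation pedigrees, strong
family structure, and linkage disequilibrium between markers and causal
variants. This generator's sample is mostly unrelated founders, so with
tens of thousands of independent markers the expected GBLUP accuracy per
trait is low (r ≈ √(nh²/(nh²+m))): at the full study scale the
cross-validated AUROCs and rank correlations for individual traits sit
near their null values even at the published heritabilities, far below the
moderate-to-high values reported for the real, highly related colony.
Passing tests therefore demonstrate correctness and internal consistency
of the machinery (parameter recovery, heritability-ordered accuracy, index
arithmetic, filter behavior), not the absolute accuracy attainable on real
colony data. The fixed-effect comparisons are an exception — the
behavior-score uplift for predicting success is driven by phenotypic, not
genomic, information and reproduces clearly at simulation scale.

## Problem sizes used in the test suite

Property checks that need replication run at reduced, stated sizes chosen
to make the statistical assertions sharp: REML recovery uses 50 replicates
at n = 1000, m = 10,000 (mean estimate within ±0.05 of h² = 0.5);
accuracy-ordering uses 50 replicates per heritability at n = 800,
m = 2,000; the fixed-effect uplift uses 20 paired replicates at n = 500,
m = 2,000. Metric implementations are verified against brute-force
pair-enumeration and exact-rational oracles on ≥ 1000 random short vectors,
and the Hardy–Weinberg test against full enumeration for all totals ≤ 50.

## Known limitations

* No threshold (probit) model for binary/ordinal traits; heritabilities
  are on the observed scale.
* Single-trait REML only; genetic correlations between traits are neither
  simulated (beyond the success construction) nor estimated.
* Phasing/imputation against an external reference panel is out of scope;
  the simulator produces complete (masked-at-random) genotypes instead.
* Fold assignment is unstratified by default; for very rare binary traits
  a fold can lack cases, in which case fold-level AUROC is reported as
  missing (pooled metrics are unaffected).
* The GCTA-format GRM reader/writer stores float32; round-trips are exact
  to ~1e-7 relative, not bit-exact.
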
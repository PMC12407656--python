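# Methods

This note documents the models implemented in `gnurture`, the choices made
where the design was genuinely open, and what the synthetic-data tests do and
do not establish about real data.

## 1. The estimand

For an offspring outcome Y and combined parental polygenic scores computed on
transmitted (PGS_T) and non-transmitted (PGS_NT) haplotypes, the joint model

Y = β_T·PGS_T + β_NT·PGS_NT + β_s·sex + β_a·age + u_family + ε

identifies genetic nurture as β_NT (the non-transmitted haplotypes can reach
the offspring only through the environment) and direct transmission as
β_DGT = β_T − β_NT (the transmitted score carries both channels; subtracting
β_NT removes the nurture share). β_DGT is always computed from unrounded
fitted values. Parent-of-origin models split the four components
(maternal/paternal x T/NT); mediation models route the nurture path through a
parental phenotype.

## 2. Synthetic family generator (`simfam`)

The generator encodes the causal structure the analysis is meant to recover,
with every latent quantity retained for oracle tests.

* **Genomes.** Markers are evenly spaced on per-chromosome genetic maps
  (default 2 chromosomes x 3,000 markers, 100 cM — chosen for desk-scale
  runtime, not genome fidelity). Founder haplotype alleles are independent
  Bernoulli draws from per-marker frequencies (uniform on [0.05, 0.95] by
  default): no background LD, which the tile matcher must not require.
* **Meiosis.** Haldane model: crossover counts per chromosome are
  Poisson(length/100) with positions uniform on the cM scale and no
  interference — the simplest defensible meiosis model. The per-marker
  transmission source and crossover positions are recorded as ground truth.
* **Mating.** Optional genetic assortment: both parental pools are ranked on
  a noisy key sqrt(ρ)·z(score) + sqrt(1−ρ)·ε and matched by rank, giving a
  realized mate-score correlation ≈ ρ_AM (exact at the extremes: ρ = 0 is
  random pairing, ρ = 1 perfect rank matching). Default ρ_AM = 0.
* **Family structure.** Sibling count uniform on 1–3 (exercises the family
  random effect); a configurable fraction of families (default 0.83,
  matching a pairs-heavy cohort) has one parent's genotyped flag cleared,
  the father with probability 0.7 (fathers are the scarcer genotyped parent
  in such cohorts).
* **Phenotypes.** Parent phenotype P = γ·Z(G) + e with γ = 0.4. Offspring
  latent outcome: δ·Z(G_off) + η_m·Z(P_m) + η_f·Z(P_f) + ν·(Z(G_m)+Z(G_f)) +
  β_sex·sex + β_age·Z(age) + ε, with defaults δ = 0.18, η_m = η_f = 0.12,
  residual nurture ν = 0.03. ν is a nurture path that bypasses the measured
  parental-phenotype mediator, so proportion mediated stays below 100% — as
  observed in real families, where parental phenotype is one channel among
  several. Binary traits threshold the latent liability at the quantile
  matching target prevalence (smoking initiation 0.414, cannabis 0.227);
  quantity traits (cigarettes/day, pack-years) are emitted only for
  initiators; cannabis is measured in a 57% subset (a later assessment
  wave); parental phenotypes are missing at 15% (mothers) / 40% (fathers).
  Sex ~ Bernoulli(0.5); age ~ uniform(18, 67). Continuous outcomes are
  affine transforms of the latent (e.g. cigarettes/day = 10.24 + 6·latent),
  deliberately left unclipped so generative coefficients stay exactly
  recoverable by linear fits; consequently a few simulated quantity values
  can be negative, which the analysis (z-scored outcomes) does not care
  about.
* **Phase-switch errors.** Optionally, at each marker with probability r the
  remaining suffix of an individual's two haplotypes is swapped. Dosages are
  invariant; only phase degrades.
* **Randomness.** One master seed; each stage (frequencies, founders,
  mating, meiosis, phenotypes, weights) draws from a named substream, so a
  fixed seed yields a byte-identical dataset.
* **Score-level shortcut.** `simulate_analysis_table` simulates the four
  score components directly (each haplotype-score half N(0, 1/2)) under the
  same causal structure, skipping genotypes. Repeated-seed calibration
  studies (type-I error, bootstrap coverage, parameter recovery) use it;
  everything it asserts about the analysis stack is also exercised once per
  suite through the full genotype path.

What passing tests on this generator do **not** show: robustness to LD
(tiles here never face correlated markers), to genotyping error (only phase
errors are modeled), to non-normal phenotype distributions, or to
X-chromosome/sex-specific transmission, all of which are out of scope.

## 3. Tile-based transmission inference (`transmission`)

Each chromosome is cut into consecutive tiles of 150 adjacent markers
(CLI-overridable); a trailing remainder shorter than half a tile merges into
the previous tile (avoids noisy short-tile calls). For each offspring
haplotype and candidate parent, per-tile Hamming distances against the
parent's two haplotypes are computed over non-missing markers; the source is
the argmin, with ties resolved toward the previous tile's assignment
(continuity minimizes spurious breakpoints; a first-tile tie defaults to
haplotype 1 and is flagged). Tiles with fewer than 10 informative
(parent-heterozygous, non-missing) markers inherit a neighbour's assignment
and are flagged low-information.

Offspring haplotypes are mapped to parents by genome-wide best-tile mismatch:
trios take the better of the two pairings, pairs assign the better-matching
haplotype to the single genotyped parent; a zero margin falls back to a fixed
rule (haplotype 1 → mother) and is flagged ambiguous.

Where adjacent tiles disagree on the source, a change-point scan over the
union of the two tiles places the breakpoint at the position minimizing total
mismatches (the leftmost minimizer of the zero-cost plateau; the true
crossover is localized up to the surrounding run of parent-homozygous
markers, within ±2 markers when the flanking markers are informative).
Refinement is on by default; off, source changes sit at tile boundaries.

**Output definition.** The transmitted allele at a marker is the allele the
offspring actually carries on the haplotype assigned to that parent — which
equals the source haplotype's allele wherever the source is correctly
resolved. The non-transmitted allele is the parent's genotype complement
(dosage minus transmitted), falling back to the source-complement haplotype
at Mendelian-inconsistent markers (possible only under phase or genotype
errors). This definition makes two identities exact simultaneously, always:
transmitted + non-transmitted = parental genotype, and the combined
transmitted score reconstructs the offspring's own genome score. A
definition that reads the transmitted allele off the parent's source
haplotype instead would break both whenever a double crossover lands inside
one tile. For a non-genotyped parent, its transmitted alleles are the
unassigned offspring haplotype and its non-transmitted alleles are missing.

Concordance against simulator truth compares inferred non-transmitted
alleles with the parental haplotype not recorded as the transmission source;
on clean data it is driven by the haplotype-to-parent assignment and
degrades continuously with the phase-switch-error rate.

## 4. Polygenic scores (`scores`)

Haplotype score = Σ_j w_j x effect-allele indicator, with weights matched by
marker id and aligned to the dataset's allele coding (a weight whose effect
allele is the reference allele contributes w·(1−a)); unmatched markers are
excluded with a logged count; missing alleles contribute the marker's mean
haplotype dosage (standard scoring convention). Scores are computed on raw
allele counts so the conservation identity (parent's T + NT = parent's
diploid score) holds exactly; standardization happens only at the end.

Missing non-transmitted scores (pairs) are imputed with the sample mean of
observed parents' NT scores — role-specific by default (missing fathers get
the observed-father mean), pooled mean as the configurable alternative; the
phrase "average of the observed parents" admits either reading. Imputed rows
are flagged, and the combined PGS_NT is recomputed. Parent-of-origin models
skip imputation entirely and leave the NT score missing for FIML.

Standardization: per genotyping batch, each score column is OLS-residualized
on an intercept plus the first 10 genetic PCs (PCs are an input; the
simulator emits none, reducing to a plain within-batch z-score), then
z-scored with ddof 0. The operation is idempotent to 1e-12 and errors on
degenerate post-residual variance or batches smaller than PCs + 2.

## 5. Association models (`assoc`)

Continuous outcomes: REML linear mixed model with a family random intercept
(statsmodels MixedLM). The outcome is z-scored before fitting — with scores
already standardized, coefficients are standardized betas (the choice of
standardization mechanics is ours). A singular fit (family variance < 1e-8)
degenerates to OLS and is flagged.

Binary outcomes: random-intercept logistic likelihood integrated by 15-node
Gauss-Hermite quadrature, maximized by BFGS on (β, log σ); SEs from the
numerical observed information; effects reported as odds ratios per SD.
A coefficient beyond ±15 log-odds is treated as separation and raised.
This fitter is implemented in-package because the Python stack has no
frequentist random-intercept logistic GLMM.

FDR: Benjamini-Hochberg step-up with an explicit family size m (default 5 —
the five non-transmitted-score tests); the transmitted-score tests get the
same adjustment separately. Quantity outcomes are restricted to initiators
by their generative missingness.

## 6. FIML path models (`pathmodels`)

Recursive linear systems over observed variables under a joint multivariate
normal: exogenous variables get free means and a free full covariance
(which is how potential assortative-mating covariance between parental
scores is absorbed); each equation contributes paths, an intercept, and a
residual variance. The observed-data log-likelihood sums, over rows grouped
by missingness pattern, the normal log-density of each row's observed
subvector under the implied moments (rows with every model variable missing
are dropped and counted).

Estimation: when every equation regresses on all causally prior variables
the model is a reparameterization of the saturated model, and the FIML
optimum is computed exactly — EM on the saturated mean/covariance followed
by moment matching (complete data reduce further to per-equation OLS).
Otherwise L-BFGS maximizes the likelihood directly (relative tolerance
1e-8), initialized from the EM moments; residual variances and the
exogenous covariance are parameterized through logs/Cholesky so the implied
covariance stays positive definite. Both routes agree to optimizer tolerance
and with statsmodels OLS under completeness, which serves as the independent
oracle in tests.

Standardized coefficients rescale by implied SDs (β·σ_x/σ_y); binary
covariates are left on their raw scale in the standardized solution. Wald
equality tests of two standardized coefficients use the delta method over
the numerical observed-information covariance of the parameter vector
(Δχ², df = 1). Mediation models are two-equation parallel designs
(mediator ~ aT·T + aNT·NT + covariates; outcome ~ b·mediator + c'T·T +
c'NT·NT + covariates); indirect = a·b, total = c' + a·b (an identity of the
linear model, exact at machine precision), and proportion mediated =
100·indirect/total, reported only when the two share a sign.

Bootstrap CIs resample family clusters with replacement (respecting sibling
dependence; individual-level resampling by flag), refit, and take percentile
intervals; failed replicates are excluded and counted, erroring beyond 10%.

Fit indices: χ² = 2(loglik_saturated − loglik_model) — the raw likelihood
ratio, n-multiplier convention, no n−1 rescaling — with df the
parameter-count difference; RMSEA = sqrt(max(0, (χ²−df)/(df·n)));
CFI against the independence baseline (all covariances zero, per-variable
normal MLEs). A model with as many parameters as the saturated model (the
default mediation and parent-of-origin specs) reports exact-fit constants.

## 7. Pipeline defaults and problem sizes

The orchestrated run uses tile size 150, 10 PCs, bootstrap B = 1000, FDR
family 5. Tests and the acceptance script run the generator at desk scale
(hundreds of families, 2 chromosomes, 400–3,000 markers per chromosome;
calibration studies use the score-level generator at 200 seeds, bootstrap
coverage at B = 200) — sizes chosen so a full verification pass stays in the
minutes range on one core while keeping every Monte-Carlo check comfortably
powered. Per-stage wall times go to `run_log.json`, kept out of
`report.json` so a fixed seed reproduces the report byte-for-byte.

## 8. Known limitations

* No LD in the simulator means tile-mismatch statistics are optimistic
  relative to real genotype panels; tile size 150 is taken as given, not
  re-derived.
* Mean imputation of missing NT scores shrinks PGS_NT variance and, under
  strong parental effects, attenuates β_NT toward zero relative to a
  FIML treatment; the parent-of-origin models avoid it for exactly that
  reason.
* The Wald test covariance comes from the observed information, not the
  bootstrap; with heavy non-normality the two can disagree.
* The logistic quadrature assumes small family clusters (here ≤ 3
  offspring); very large clusters would need adaptive quadrature.
* Liability thresholds are set from the realized latent distribution, so
  simulated prevalences match targets up to sampling noise only.
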
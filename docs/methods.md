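# Methods

This note documents the models, rules, and numerical choices behind
`pressorgwas`, and what the synthetic-data-driven tests do and do not
establish about real operative records.

## Phenotype definition and episode QC

An anesthesia episode carries infusion segments `(t_start, t_end, rate)`,
SBP readings `(t, value, modality)`, bolus events, and demographics. Times
are minutes from episode start; segments are half-open `[t_start, t_end)`
and non-overlapping.

The quantitative trait is the **average infusion rate**: the
duration-weighted mean of segment rates, `Σ r_k d_k / Σ d_k` (mcg/min).
Duration weighting matches the physically delivered dose rate; the
arithmetic mean of recorded settings is available behind
`compute_features(..., rate_method="arithmetic")` for sensitivity checks.
`mean_sbp` and `sd_sbp` are the mean and *sample* SD (n−1) of the valid
readings within the infusion window `[first segment start, last segment
end]`, both endpoints inclusive.

QC order matters: SBP values outside the open interval (20, 200) mmHg are
removed at the value level first (they are overwhelmingly artifacts —
arterial-line flushes, disconnections), and only then are the
reading-count (≥ 3) and modality-consistency rules evaluated. An episode is
excluded if any rule fails; every failing rule is logged, so the exclusion
log is exhaustive rather than first-match. Episode rules and defaults:

| rule | threshold | reason code |
|---|---|---|
| total infused time | < 10 min | `short_infusion` |
| valid in-window readings | < 3 | `few_sbp` |
| phenylephrine/ephedrine bolus in window | any | `bolus_during_infusion` |
| > 1 modality among valid readings | any | `mixed_modality` |
| segment unit ≠ mcg/min | any | `bad_unit` |
| missing body weight | — | `missing_weight` |
| no infusion segments | — | `no_infusion` |

## Response stratification

Episode features (avg rate, mean SBP, SD SBP) are z-scored with the sample
SD and clustered by k-means (k-means++ initialization, best of `n_init=10`
restarts, `max_iter=300`; scikit-learn's implementation and defaults).
Clustering runs at the episode level; the patient-level concordance rule is
applied afterwards, so a patient whose surgeries land in different clusters
is removed rather than averaged across regimes, and concordant
multi-surgery patients contribute the mean of their features.

Semantics at k = 3 are assigned from the *unstandardized* centroids:
`resistant` = highest rate centroid; among the remaining two, `sensitive` =
higher mean-SBP centroid, `intermediate` = the other. Near-ties in the rate
centroid (within 1e-9) resolve to the lower cluster index and are reported.

The k = 2 vs k = 3 comparison is summarized by `evaluate_k`, which reports
sizes, within-cluster sum of squares, and the fraction assigned to the
high-dose cluster at each k.

## Cohort statistics

Categorical contrasts use the Pearson chi-square without continuity
correction (sample sizes here make Yates irrelevant); continuous contrasts
use classic equal-variance one-way ANOVA, with an algebraically identical
summary-statistics variant for `(n, mean, sd)` inputs. The multiple-testing
threshold is Bonferroni `α/m` (default 0.05/8 = 0.00625 for the eight
clinical features). Pairwise group contrasts are provided as Welch t-tests
— a deliberate package choice; the omnibus tests are the primary analyses.

Comorbidities: ICD-9 codes truncate to the 3-digit class (V/E prefixes
kept), a class is *reportable* for a patient only when coded on ≥ 3
distinct dates, and classes with prevalence ≥ 0.5% in **every** subgroup
enter the prevalence matrix, which is ordered by UPGMA (Euclidean distance,
average linkage, scipy).

## Genotype QC

Dosages live in `[0, 2]` (fractional for imputed genotypes; effect allele =
VCF alt). Filters run in the fixed order info score → variant call rate →
MAF → HWE so per-filter removal counts are disjoint. HWE uses the 1-df
Pearson chi-square against `p², 2pq, q²` on hard calls (thresholds 0.5/1.5)
— adequate at the 10⁻⁷ screen; the exact test would matter only at small
minor-allele counts. Imputed dosages are used as-is in association and
hard-called only for HWE and relatedness.

Relatedness is the method-of-moments IBS→IBD decomposition (the classic
PLINK `--genome` estimator without the finite-sample correction):
`π̂ = P(IBD=1)/2 + P(IBD=2)`. The pruning threshold 0.1875 is the midpoint
between second-degree (0.25) and third-degree (0.125) expectations; the
lower-call-rate member of a flagged pair is removed (tie → later sample
id). The estimator needs a few thousand reasonably independent markers: at
a few hundred LD-correlated variants its sampling noise approaches the
threshold itself and false-positive pruning becomes likely. PCA standardizes
columns by `2p̂` and `sqrt(2p̂(1−p̂))`, mean-imputes missing entries, and
returns orthonormal sample coordinates with non-increasing eigenvalues;
PCs are computed per phase, and no LD pruning is applied by default (a
config hook subsets variants).

## Association and meta-analysis

Covariate screening fits one multivariable OLS of the rate on all
candidates (age, sex, weight, mean SBP, SD SBP, anesthesia type,
comorbidity indicators) and retains those with Wald P < 0.05; categorical
candidates enter as indicator sets retained jointly by an F-test. Because
mean/SD of SBP define the clusters, the GWAS adjusts only for the
demographic covariates (plus six PCs); the BP features are screened and
reported but not carried into the genetic models.

The per-variant linear engine residualizes the phenotype and all
complete-data dosage columns on the covariate design once (QR-based
Frisch–Waugh–Lovell) and computes slope, SE, and a two-sided t-test per
variant — exact OLS at a fraction of the cost; variants with missing
dosages fall back to a per-variant complete-case fit. Monomorphic and
collinear variants are flagged in `status`, never fatal. Logistic subgroup
models (resistant vs sensitive; resistant vs pooled) use statsmodels IRLS
(tol 1e-8, max 50 iterations); unbounded Wald SEs or non-convergence are
reported as `not_converged`. Interaction models contain exactly SNP,
modifier, and SNP×modifier; the interaction coefficient is invariant to
centering the modifier, which the tests verify. Conventions: two-sided
tests throughout, sex coded F = 1/M = 0, complete-case per model.

Meta-analysis is fixed-effect inverse-variance with weights `1/SE²`;
Cochran's Q is computed and reported but never used to filter. CIs use
z = 1.959964. `se_from_ci` recovers SEs from printed CI half-widths, which
lets published phase-level tables serve as direct numeric inputs; printed
values carry ±1-last-digit rounding drift, reflected in the comparison
tolerances. Genomic λ is the median 1-df chi-square over 0.4549364. LD
clumping is greedy: best remaining P below 10⁻⁵ becomes a lead, absorbing
variants within 500 kb with dosage r² ≥ 0.1 (ties broken by position then
id); the parameters are exposed in config.

## Power

For an additive variant with MAF p and per-allele effect β on a trait with
marginal SD σ, the Wald chi-square has noncentrality
`ncp = n·2p(1−p)·β²/σ²_resid` with `σ²_resid = σ² − 2p(1−p)β²`: the printed
trait SD *includes* the variant's own contribution, so the residual form is
the consistent denominator (at the reference design point — n = 1534,
p = 0.017, β = 13, σ = 19.7, α = 10⁻⁴ — it gives 0.808 vs 0.798 for the
naive form, and only the former matches direct simulation). Two
simulation-based companions exist: `power_monte_carlo` pushes simulated
datasets through the same Wald test, and `power_expected_finite` integrates
the conditional power over the realized genotype variance. At rare alleles
(~52 expected carriers here) that integration sits a Jensen gap (~0.015)
below the fixed-ncp value because the power curve is concave in that range;
Monte-Carlo estimates center on the integrated value, not the fixed-ncp
one.

## The synthetic cohort

The generator emulates the structure the analysis must recover, not any
real population:

* **Latent classes** resistant/intermediate/sensitive with probabilities
  (0.13, 0.56, 0.31) and class-conditional Normal features — rate
  76.2±22.4 / 32.1±11.8 / 32.4±12.3 mcg/min, mean SBP 108.0±11.0 /
  105.4±8.7 / 123.9±10.9 mmHg, SD-of-SBP 15.0±6.4 / 10.0±3.7 / 19.9±7.3 —
  whose mixture reproduces a marginal trait of ≈37±20 mcg/min. The class
  draw uses the class SDs as its noise scale; `residual_sd` (default 0)
  adds idiosyncratic noise for flat, class-free simulations, because
  stacking a second ~20-SD term on the class SDs would double-count
  variance.
* **Covariate effects** on the rate: +0.08 per year of age, −4.05 for
  female sex, +0.14 per kg, applied to centered covariates; demographics
  are drawn class-conditionally so sex/age/weight contrasts across
  subgroups are non-null.
* **Genotypes**: per-variant ancestral frequency uniform on the MAF range,
  optionally perturbed per subpopulation on the `sqrt(p(1−p))` scale;
  haplotype alleles from a latent AR(1) Gaussian copula (ρ = 0.8) within
  blocks of 20 variants, independent across blocks — the simplest LD
  structure that exercises clumping. Causal variants are pinned at MAF
  0.017 with β = 13 mcg/min per allele by default; variants can instead act
  on the latent class (log-odds toward resistant) to emulate signals that
  differentiate subgroups rather than shift the rate.
* **Episodes**: 30–180 min, readings every 2–5 min, SBP as AR(1) (φ = 0.5)
  around the patient's class-conditional mean with stationary SD equal to
  the patient's target SBP variability; segment rates jittered but rescaled
  so the duration-weighted mean equals the patient's target. ~4% of
  patients get a second episode whose class re-draws with probability 0.5,
  producing the discordant patients the concordance rule must drop.
* **Planted violations** at configurable rates on disjoint episode sets,
  recorded with the exact reason code QC must emit; genotype-side failures
  (low info, missingness, rare MAF, HWE violations, duplicates) are
  constructed directly in tests.
* **Scale**: defaults are 4000 patients, 40% genotyped, a 5000-variant
  panel split evenly into two phases sharing one panel. Tests and examples
  run at a few hundred to a few thousand patients and 400–10,000 variants —
  sizes chosen so each statistical check retains its designed sensitivity.

What passing tests show: the engines are correct (closed-form and
brute-force oracles), calibrated (type-I error, λ, CI coverage at the
reference design point), and the pipeline recovers planted structure
(classes, covariates, causal variants, violations) deterministically under
a fixed seed. What they do not show: robustness to real-EHR phenomena the
generator does not emulate — titration dynamics within segments, informative
missingness, charting errors beyond the planted vocabulary, imputation-error
structure in dosages, or ancestry admixture beyond discrete subpopulations.

## Known limitations

* The k = 3 class structure is a modeling device; with the reference
  feature distributions the intermediate and sensitive classes overlap so
  strongly in rate that even the Bayes rule on the true densities caps the
  recoverable ARI near 0.64 — cluster labels should be read as graded, not
  categorical.
* The HWE chi-square is anti-conservative at very small minor-allele
  counts; the exact test is the alternative if screening near-monomorphic
  variants matters.
* π̂ estimates below ~1000 effective markers are noisy enough to prune
  unrelated pairs; the pipeline leaves panels that small to the caller's
  judgment (a warning fires under 50 variants).
* Logistic subgroup validation inherits the small-case-count fragility of
  Wald tests; quasi-separation is flagged, not rescued (no Firth
  correction).
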
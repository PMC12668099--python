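# Methods

This note documents the statistical procedures, the synthetic-data
model behind the tests, the numerical choices, and the design
decisions that were genuinely open.

## Association scans

Every EWAS and cis-QTL fit is ordinary least squares with the focal
predictor (CpG beta value or SNP dosage) plus covariates and an
intercept. The implementation residualises both the outcome and all
focal predictors against the shared covariate design (Frisch–Waugh
partialling via a QR factorisation), after which each per-feature fit
reduces to a simple regression whose coefficient, SE and t statistic
equal the full-model OLS solution exactly; unit tests assert equality
with statsmodels to 1e-8. Two-sided p-values come from the t
distribution at the residual degrees of freedom (exact in small
samples, indistinguishable from the normal at cohort sizes). Missing
methylation values trigger listwise deletion per CpG; CpGs whose
residualised predictor is numerically constant are skipped and
logged. Regression is on beta values, not M-values, so the EWAS, the
risk score and the QTL scans share one scale; an M-value analysis can
be run by transforming the matrix before the scan.

cIMT enters as its natural logarithm and must be strictly positive;
non-positive phenotypes are a hard error rather than a silent drop.

Quantile normalisation maps every sample's value distribution onto the
across-sample mean of sorted values, with ties receiving the mean of
the implied values. It is an array-level preprocessing step: the risk
score normalises the full matrix before extracting sentinel CpGs,
because a few-CpG submatrix carries only rank information and
normalising it alone collapses the score onto within-sample orderings.

## Meta-analysis

Stouffer combination uses z_i = sign_i · Φ⁻¹(1 − p_i/2) and
z_meta = Σ √N_i z_i / √(Σ N_i). z is derived from p and direction, not
from β/se, because effect sizes are not comparable across cohorts with
different cIMT acquisition protocols. p-values of zero are clamped at
the smallest positive normal double with a warning. Features present
in a single study pass through unchanged and are flagged.

Heterogeneity (Cochran's Q, I² = max(0, (Q−df)/Q)) is computed on the
per-study z-scores treated as unit-variance effects when only the
Stouffer path exists; because z scales with √N, imbalanced cohorts can
show large I² even under effect homogeneity, so an effect-scale mode
(`het_on="effect"`) is provided and neither convention is asserted as
canonical. IVW pooling follows the textbook fixed-effects formulas and
is property-tested against a generalized-least-squares oracle.

The two-stage screen advances discovery-stage features with
p < stage1_alpha that are measured in every replication dataset,
re-pools all studies by Stouffer, sets the threshold to
bonferroni_base divided by the number advanced, and keeps the lowest-p
passer per chromosome as the sentinel (chromosome-distinct signals are
treated as independent). The discovery stage defaults to Stouffer;
`stage1_method="ivw"` exists because fixed-effects pooling is an
equally defensible discovery-stage choice.

## Causal inference

SMR uses the single-instrument Wald ratio β_SMR = β_out/β_exp with the
delta-method SE written as √(se_out²/β_exp² + β_out²·se_exp²/β_exp⁴),
a form that stays defined when the outcome effect is exactly zero
(then β_SMR = 0, p = 1). The chi-square statistic
T = z_e²z_o²/(z_e²+z_o²) is available via `statistic="tsmr"`; both
agree asymptotically and the SMR z² converges to the outcome z² as the
instrument SE vanishes (asserted numerically). Instruments must pass
p < 1e-5 and F ≥ 10; allele harmonisation flips swapped alleles,
errors on true mismatches, and drops strand-ambiguous palindromic
SNPs.

Colocalisation computes per-SNP Wakefield log-ABFs,
log ABF = ½(log(1−r) + r z²) with r = W/(V+W), V = se², and W the
squared prior effect SD — 0.15·sd(Y) for quantitative traits, 0.2 on
the log-odds scale for case/control, following the method's published
defaults. Hypothesis weights are assembled in log space with
log-sum-exp; the H3 term (two distinct variants) is
exp(S1+S2) − exp(S12) evaluated by signed log-sum-exp, and with a
single shared SNP H3 is −∞. Posteriors are validated against an
exhaustive enumeration oracle on toy panels (≤ 5 SNPs, plain
products over all causal-SNP configurations, agreement to 1e-9) and
sum to 1 within 1e-9 on every input. The decision rule is `shared` if
PP.H4 > 0.5 and PP.H4/PP.H3 ≥ 3 (the ratio on posteriors, not Bayes
factors), `distinct` if PP.H3 > 0.5, `none` if PP.H0 > 0.5, else
`underpowered`. p₁₂ sensitivity re-runs the analysis over a grid in
(0, min(p₁, p₂)) and flags the call robust only if `shared` holds at
every grid point. Summary inputs are (β, se) pairs; MAF+p input is not
implemented.

## Risk score

Elevated cIMT means cIMT ≥ the age-/sex-/ethnicity-specific 75th
percentile (the "at or above" convention); samples older than the
table's range are excluded with a logged count. The normative table is
empirical (type-7 linear interpolation); cells under 30 samples merge
across ethnicity, then sex.

The 70/30 split stratifies on ethnicity × elevated status with
largest-remainder rounding: floors of 0.7·n per stratum, the leftover
going to the largest fractional remainders so the train total equals
round(0.7·N). At N = 1,353 this yields 947/406 (the floor/ceil pair
948/405 is one rounding unit away and within the same convention).

Weights are per-CpG Stouffer-combined z-scores from
ethnicity-stratified regressions of ln(cIMT) on the CpG + age + sex
(`basic`) or the full EWAS covariate set (`comprehensive`); a
pooled-IVW-coefficient mode exists because a coefficient-based weight
is an equally valid reading, and neither is asserted as the original.
Strata under 20 training samples merge into one pooled stratum.

Evaluation fits nested logistic models on the evaluated cohort —
M1 = MRS + age + sex + ethnicity, M2 without the MRS, M3 = M1 +
smoking (chosen so the predictor sets nest monotonically
M2 ⊂ M1 ⊂ M3) — and compares AUCs of the fitted probabilities with
paired DeLong tests. AUC is the Mann–Whitney rank statistic,
cross-checked against trapezoidal ROC integration to 1e-10. Quartile
odds ratios come from a logistic model on score quartiles (cut-points
from the evaluated scores; train-derived cut-points are an option) +
demographics, with Wald CIs; effect modification is a likelihood-ratio
test adding MRS × ethnicity. Perfect separation or non-convergence
falls back to an L2-penalised fit and is flagged (penalised fits
report no Wald CIs).

One calibration subtlety is documented rather than hidden: comparing
nested models that were fit on the evaluation data itself makes the
DeLong test conservative under the null (the fitted coefficient of a
non-informative score inflates both in-sample AUCs), so null p-values
are stochastically larger than uniform. The test suite therefore
asserts the operative property — no anti-conservatism (the fraction of
null p < 0.05 stays within its binomial bound) — not exact uniformity.

## Enrichment

Backgrounds are matched per test CpG: candidates must lie on another
chromosome or > 5,000 bp away, must not themselves be test CpGs, and
must match the test CpG's mean beta within ±m and beta-SD within ±s,
where (m, s) expand over 10 equal linear steps from (0.025, 0.0025) to
(0.25, 0.025); the tightest step with at least n_sets candidates is
used and logged. n_sets candidates are sampled without replacement
(seeded), and background set j takes the j-th draw of every test CpG,
so each of the 200 sets is size-matched. If even the loosest step
falls short, sampling falls back to replacement under a prominent
warning. Empirical p is (#backgrounds ≥ observed)/n_sets with no
pseudo-count, and significance requires a count of exactly zero;
reported gene-set hits additionally require log₂ fold change > 1.
Gene mapping applies the same cis-eQTM p < 0.05 filter to test and
background sets symmetrically. TFBS overlap treats intervals as
0-based half-open and CpG positions as 1-based points.

## Synthetic cohorts

The generator is the test bed, not a model of any real population.
Methylation is simulated on a latent logit scale (per-CpG baseline
logit(U(0.15, 0.85)), stratum shifts of SD 0.1, per-CpG noise SD
uniform in 0.5–1.5 × 0.4) and mapped through the inverse logit, which
keeps beta in (0,1) while making injected effects linear on the latent
scale. CpG→phenotype effects act on ln(cIMT) per SD of realised beta;
SNP→CpG effects act on the latent logit per SD of dosage; expression
effects are linear per SD of source. The truth table records both the
injected per-SD effect and the implied per-unit slope, which is what a
downstream regression estimates. Because the phenotype depends on
dosage only through beta, Wald-ratio mediation recovery is exact in
expectation even though the logit link attenuates the beta-scale meQTL
slope.

ln(cIMT) = log(0.65) + 0.004·(age−55) + 0.03·sex + stratum offsets
(0–0.03) + smoking offsets + injected CpG effects + N(0, noise_sd);
defaults give cIMT ≈ 0.55–0.9 mm, plausible positive values chosen
once — no claim of matching any real cohort's distribution. Age is
uniform on 30–84 (the recruitment range); default strata mirror the
discovery cohort's proportions (Chinese 1063 / Malay 150 / Indian
144). Genotypes use AR(1) latent LD (ρ = 0.8) thresholded into two
haplotypes with MAF ~ U(0.1, 0.5). Colocalisation scenario panels
draw two independent sample sets from one LD structure; H4 shares the
causal SNP, H3 forces the two causal indices ≥ max(10, m/10) apart so
LD leakage does not blur the scenario; the case-control option
thresholds a liability at the target prevalence and summarises by
linear regression on the 0/1 indicator.

What the generator does not emulate — probe cross-reactivity, batch
structure, cell-composition confounding correlated with ethnicity,
realistic genome-wide LD, bimodal CpGs — bounds what passing tests
show: calibration and recovery hold under a clean, correctly-specified
data-generating process, not under real-array artefacts.

## Problem sizes

The test and acceptance experiments use: threshold/attrition checks at
the study's own counts (54,617 / 53,470 features); 1,000 random
5-study panels for the meta-analysis oracles; 200 toy panels for the
colocalisation oracle; 100 seeds × (n = 5,000, 200 SNPs) per
colocalisation scenario; 50 mediation seeds at n = 2,000; 20 permuted
EWAS nulls × 1,000 CpGs at n = 500; 20 enrichment nulls × 100 entries
over a 2,000-CpG universe with 200 background sets; 50 risk-score
seeds at n = 1,400 (plus 50 null seeds); and one 1,353-sample split.
These sizes were chosen so each experiment's Monte-Carlo error is
small relative to the property being asserted while the whole suite
completes in minutes.

## Known limitations

Single-instrument SMR only (no IVW/Egger/median multi-instrument MR,
no HEIDI); colocalisation assumes at most one causal variant per
trait and no LD-aware fine-mapping; no trans-QTL or conditional
secondary signals; no random-effects meta-analysis or genomic
control; the CLI covers the common verbs thinly and the library is
the primary interface.
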
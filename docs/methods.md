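# Methods

`admixscan` implements an admixture-mapping analysis of type 2 diabetes in
African Americans as a reusable, testable pipeline. Real cohort genotype
and phenotype data of this design (ARIC, JHS, MEC) are not publicly
deposited, so the package pairs every analysis stage with a synthetic-data
generator that reproduces the study's genetic and epidemiological
structure. This note records the models, the defaults and why they were
chosen, the numerical decisions, and what the synthetic data can and
cannot establish.

## Generative model (`admixscan.simulate`)

**Marker panel.** `n_markers` ancestry-informative SNPs (default 2,189,
the size of the study panel) are spread nearly evenly over 22 autosomes of
1.5 Morgans each (33 Morgans total, close to the autosomal genetic map),
with sorted uniform positions and a nominal 1 cM/Mb physical coordinate.
Parental allele frequencies `pE` (European) and `pA` (West African) are
drawn so the mean absolute divergence |pE − pA| equals `freq_divergence`
(default 0.5, typical of a purpose-built ancestry-informative panel; the
study does not report its panel's divergence). `freq_divergence = 0`
produces an uninformative panel for degenerate-case testing.

**Ancestry tracts.** Each individual draws a European ancestry proportion
M ~ Beta(a, b). Along each chromosome, each haplotype switches ancestry at
the points of a Poisson process with rate λ per Morgan; at each switch the
new ancestry is European with probability M. This is the standard Markov
approximation to post-admixture recombination; λ plays the role of
generations since admixture and defaults to 6, the conventional depth for
African-American admixture. Consequences used by tests: interior tract
lengths are Exponential(mean 1/λ) and the marginal law of local ancestry
at every locus is Binomial(2, M)/2.

**Ancestry distribution calibration.** The study reports median global
African ancestry 83.7% (IQR 76.2–88.7%). `calibrate_ancestry_beta` fits
Beta shape parameters to those three quantiles by weighted least squares
(median weighted 4×); the result, Beta(12.95, 2.82) on the African
proportion — i.e. Beta(2.8168, 12.9517) on the European side — is frozen
as the config default and reproduces the target median within a fraction
of a percentage point at the cohort size of 7,021.

**Genotypes.** Each allele carries the counted variant with probability
`pE` or `pA` according to its haplotype's local ancestry; the genotype is
the unphased sum. Genotypes go missing independently at `missing_rate`
(default 2%; the study's three partially overlapping genotyping panels —
median 1,243 typed markers per person — are not modelled as such).

**Phenotypes.** A latent socioeconomic (SES) score is Gaussian with
correlation −0.35 to standardized African ancestry (the study reports the
association's direction, not a coefficient); education (4 levels), family
income (4 levels plus an explicit `missing` category, 12% missing) and
occupation (6 census groups) are thresholded from noisy copies of the
latent score. BMI is normal with positive loading on African ancestry and
negative loading on SES. Diabetes follows a logistic model in African
ancestry, BMI, SES, age, sex, and — when a risk locus is configured — a
per-allele log-odds of log(ψ_true) on the European allele count at the
locus. Default coefficients (ancestry 1.6 per unit African proportion,
BMI 0.08 per kg/m², SES −0.30 per SD, age 0.04 per year, male 0.15;
intercept −2.0) give a prevalence near the study's 2,373/7,021 ≈ 34% and
an unadjusted top-vs-bottom tertile odds ratio of the observed order
(~1.5) partly mediated through BMI and SES. Quantitative traits (HbA1c,
fasting glucose, fasting insulin) are additive-normal in the same
covariates with a diabetes offset; 60% of diabetics are flagged as
treated. MEC rows carry no SES indicators or fasting traits, mirroring
the study design. These phenotype coefficients are plausibility choices,
fixed once; no downstream test depends on their exact values, only on
directions and internal consistency.

**Determinism.** All randomness flows from `SimConfig.seed` through four
named `SeedSequence` substreams (panel, ancestry, genotypes, phenotypes);
identical configs give byte-identical outputs.

## Local/global ancestry HMM (`admixscan.hmm`)

The hidden state at a marker is e ∈ {0, 1, 2} European-origin alleles.
The haploid chain keeps its ancestry over d Morgans with probability
exp(−λd) and otherwise redraws it (European with probability M); the
diploid transition matrix is the tensor square of the haploid one
collapsed onto allele counts, assuming independent haplotypes (no
assortative mating). The stationary prior is Binomial(2, M). Emissions
multiply per-allele Bernoulli frequencies; a genotype of e = 1 sums over
which parental chromosome carries the variant; missing genotypes emit 1.

Smoothed posteriors come from scaled forward–backward recursions run per
chromosome; the log-likelihood is the sum of the log scaling factors, and
a backward-recursion implementation of the same quantity is kept as a
numerical cross-check. Posteriors on chromosomes of ≤ 8 markers are
verified against exhaustive enumeration of all 3^L hidden paths.

Global ancestry is the maximum-likelihood (M, λ) over a grid — M from
0.005 to 0.995 in steps of 0.005, λ ∈ {2, 4, 6, 8, 10} — with likelihoods
computed for all individuals and grid points in one vectorised pass. Ties
break toward smaller λ. African ancestry is reported as 1 − M̂; the
genome-averaged posterior mean local ancestry is also exposed, since the
two answer slightly different questions. Frequencies at exactly 0 or 1 are
clamped to [1e-4, 1 − 1e-4] so a single genotyping error cannot zero out
the likelihood. A panel with no marker at |pE − pA| > 0.05 raises an
estimation error (unidentifiable); a flat likelihood (e.g. all genotypes
missing) warns. This fixed-frequency maximum-likelihood HMM is the
identifiable core of the analysis; it does not model uncertainty in the
parental allele frequencies, which the original Bayesian estimator
integrated over.

## Scan statistics (`admixscan.scan`)

**Locus-genome LOD (cases only).** For risk model ψ (multiplicative odds
per European-origin allele) the per-case likelihood ratio reweights the
unmodified posterior by ψ^e and normalises by the same reweighting of the
case's prior Binomial(2, M̂_i); the locus LR is the product over cases,
computed in log space. The posterior is *not* re-decoded per ψ
(score-statistic style); this matches the published statistic's form and
costs one HMM pass. Six pre-specified risk models ψ ∈ {0.7, 0.8, 0.9,
1.1, 1.2, 1.3} (the 0.1-grid from 0.7 to 1.3 excluding the null ψ = 1,
which has LR ≡ 1) are averaged on the LR scale and the LOD is the log10
of that average. The genome-wide score is log10 of the mean per-locus
ψ-averaged LR over all loci. Thresholds: LOD ≥ 5 genome-wide significant,
≥ 4 suggestive; genome-wide score ≥ 2 / ≥ 1. The thresholds are applied
inclusively so a LOD printed as 4.0 classifies as suggestive.

**Case-control Z.** Per individual and locus, the deviation δ = (posterior
mean local European ancestry) − M̂; Z is the Welch-standardised difference
of mean deviations between cases and controls (the variance estimator is
a package choice). Positive Z means cases carry more European ancestry at
the locus. |Z| ≥ 4.06 is genome-wide significant: the two-sided normal
tail there is ≤ 5×10⁻⁵, i.e. 0.05 after a conservative 1,000-hypothesis
correction. Loci where a group has < 2 members return NaN and classify as
`undefined`; degenerate loci with zero variance and zero difference
return Z = 0.

**Power.** `power_simulation` reproduces the semi-analytic, per-locus
power treatment: each replicate draws case ancestry proportions from the
calibrated Beta, samples the true local allele count from the
ψ_true-weighted prior at a fully informative locus (posteriors = truth),
computes the locus LOD over the ψ grid, and declares detection at
LOD > 5. Genome-wide multiplicity enters only through the threshold. With
2,373 cases and ψ_true = 1.8 the expected per-case log10-LR at ψ = 1.3 is
≈ 0.017, so the expected LOD is ≈ 40 and simulated power is essentially
100% — comfortably above the ~80% quoted for this design by power
analyses that also average over partially informative markers, which this
perfect-information design deliberately excludes.

## Epidemiological layer (`admixscan.epi`)

**Classification.** A record is a diabetes case if any of: fasting
glucose ≥ 126 mg/dL, non-fasting glucose ≥ 200 mg/dL, HbA1c ≥ 6.5%,
diabetes medication, or self-report; cases with age at diagnosis < 30 are
excluded (suspected type 1; applied outside MEC, whose case definition is
questionnaire-based). Glucose without a fasting flag is judged against
the conservative 200 mg/dL cut and flagged. HOMA-IR = glucose [mmol/L] ×
insulin [mU/L] / 22.5, with mg/dL inputs divided by 18.0.

**Tertile ladder.** African-ancestry tertiles are cut at the empirical
1/3 and 2/3 quantiles of the analysis sample (ties to the lower tertile;
cuts reported to one decimal percent). Model 1 adjusts for age, sex and
study; models 2–4 add BMI, SES (education, income incl. the missing
category, occupation as unordered dummies with homemaker as reference —
reference levels are package choices), and both. Logistic (diabetes) and
linear (trait) fits use statsmodels GLM/OLS with Wald 95% CIs; the trend
p-value enters the tertile index as a single ordinal term (a continuous-
ancestry trend would be the natural alternative). Suspected separation
(|log OR| > 15) flags the row and reports an unbounded CI. Trait models
exclude treated individuals by default. `variance_explained` reports the
incremental coefficient of determination of a term over the base model.

**Decompositions.** Percent excess odds explained = 100(θ₁ − θ₂)/(θ₁ − 1)
(undefined when θ₁ ≤ 1); percent effect explained = 100(β₁ − β₂)/β₁
(undefined at β₁ = 0). Both are attenuation measures, not counterfactual
mediation. They are computed from unrounded fitted coefficients; a
separate from-printed-values mode (`admixscan.tables`) recomputes every
published decomposition cell from the rounded printed odds ratios and
coefficients, which is what the acceptance checks verify.

**Splines.** Restricted cubic splines use the truncated-power natural
basis (K knots → K − 1 columns including the linear term; linear beyond
the boundary knots), knots at the 5th/35th/65th/95th percentiles, and an
odds-ratio curve referenced to the 5th percentile with delta-method CIs.

## Problem sizes used in the tests

Statistical tests run at sizes chosen to make their tolerances
meaningful at interactive cost: global-ancestry recovery uses 200
individuals × 1,000 markers on 22 chromosomes (mean |M̂ − M| tolerance
0.01 on the cohort mean); tract-length and switch-count checks use ≥
2,000 tracts; permutation calibration uses 2,000 permutations of 400
individuals; the null-genome score check uses 100 replicates of 500 loci
× 200 cases with perfect-information posteriors; power uses 500
replicates of 2,373 cases. Exhaustive-enumeration oracles cap chromosomes
at 7 markers (3⁷ paths).

## What the synthetic data does not establish

The generator draws unlinked founder alleles (no linkage disequilibrium
within ancestral populations), one homogeneous marker panel (no
multi-phase panel overlap), no family structure, no genotyping error
beyond missingness, and phenotype models that are exactly the fitted
model's form. Passing tests therefore demonstrate correctness of the
estimators and statistics under the assumed generative model, and
calibration of their null distributions — not robustness to model
misspecification in real cohorts. The published data-dependent results
(ancestry medians by cohort, the specific LOD/Z peaks at 12p13.31 and
13q14.3, fitted OR magnitudes) depend on the real genotypes and are out
of reach by construction; what is reproduced exactly is everything
computable from printed inputs, plus the analytic threshold identities
and the design's detection power.

## Known limitations

- Global-ancestry grid search is O(individuals × markers × grid); the
  default 199 × 5 grid takes ~30 s for 200 × 1,000 genotypes on one core.
  A coarser `m_grid` is the supported speed knob.
- λ is estimated on a coarse grid {2,...,10} and is only weakly
  identified at realistic marker densities; it is reported but should not
  be over-interpreted.
- The Welch variance for Z and Wald inference for the ladder are
  conventional choices; small-sample refinements are not implemented.
- `classify_diabetes` trusts field semantics (units mg/dL, HbA1c %);
  no unit inference is attempted.
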
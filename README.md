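# admixscan

Admixture mapping of type 2 diabetes in admixed cohorts: cohort
simulation, hidden-Markov-model local-ancestry inference, genome-scan
statistics, and ancestry–risk decomposition models.

## The scientific problem

Type 2 diabetes is roughly twice as common in African Americans as in
European Americans, even after adjusting for known environmental risk
factors. Two questions follow. First, is *genetic ancestry itself*
associated with diabetes risk beyond its association with body mass index
(BMI) and socioeconomic status (SES)? Second, is there any single locus
where excess African (or European) ancestry in diabetic cases points to a
major risk gene? Admixture mapping answers both by exploiting the mosaic
genomes of recently admixed individuals: each African American carries
chromosomal segments of West African and European origin, and a disease
locus reveals itself as a local distortion of ancestry among cases.

Real cohort data of this design (ARIC, JHS, MEC; 7,021 participants,
2,373 with diabetes, 2,189 ancestry-informative markers) are not publicly
deposited, so `admixscan` pairs every analysis stage with a synthetic
cohort generator that reproduces the design's genetic and epidemiological
structure — ~2,189 markers on 22 autosomes, admixture ~6 generations
deep, median global African ancestry 83.7% (IQR 76.2–88.7%),
ancestry-correlated SES and BMI, and an optional locus with a per-allele
risk — making the whole pipeline testable end to end.

## Models and statistics

**Local ancestry HMM.** The hidden state at a marker is e ∈ {0, 1, 2}
European-origin alleles. Each haplotype keeps its ancestry over d Morgans
with probability e^(−λd) and otherwise redraws it (European with
probability M, the individual's genome-wide European proportion); the
diploid transition matrix is the tensor square of the haploid chain, the
stationary prior is Binomial(2, M), and genotypes are emitted from the
parental allele frequencies pE, pA. Exact smoothed posteriors γ_i(e) come
from scaled forward–backward recursions; global ancestry M̂ (African
ancestry = 1 − M̂) and the switch rate λ̂ are maximum likelihood on a
grid.

**Locus-genome statistic (LOD).** In cases only, for risk model ψ (odds
per European-origin allele),

    LR(ψ) = ∏_cases [ Σ_e γ_i(e) ψ^e / Σ_e π_i(e) ψ^e ],   π_i = Binomial(2, M̂_i),

averaged over six pre-specified models ψ ∈ {0.7, 0.8, 0.9, 1.1, 1.2,
1.3}; LOD = log₁₀ of the average. LOD ≥ 5 is genome-wide significant,
≥ 4 suggestive. The genome-wide score — log₁₀ of the mean LR over all
loci — is significant above 2, suggestive above 1.

**Case-control statistic (Z).** With δ_i = (posterior mean local European
ancestry) − M̂_i, Z is the Welch-standardised case-vs-control difference
in mean δ at each locus; |Z| ≥ 4.06 (two-sided normal tail ≤ 5×10⁻⁵,
i.e. 0.05 after a conservative 1,000-hypothesis correction) is
genome-wide significant. Positive Z means cases carry more European
ancestry at the locus.

**Epidemiological layer.** Diabetes classification (fasting glucose
≥ 126 mg/dL, random ≥ 200 mg/dL, HbA1c ≥ 6.5%, medication, self-report;
onset < 30 excluded), HOMA-IR = glucose[mmol/L] × insulin[mU/L] / 22.5,
ancestry tertiles, the nested logistic/linear model ladder (model 1:
age + sex + study; 2: +BMI; 3: +SES; 4: +BMI+SES), restricted-cubic-
spline risk curves, and the attenuation decompositions

    % excess odds explained = 100 (θ₁ − θ₂) / (θ₁ − 1)
    % effect explained      = 100 (β₁ − β₂) / β₁

where θ₁/β₁ come from the base model and θ₂/β₂ from an adjusted model.

See `docs/methods.md` for assumptions, defaults, and numerical choices.

## Worked example

```python
import numpy as np
import admixscan as ax

cfg = ax.SimConfig(n_individuals=2000, n_markers=400, n_chromosomes=10, seed=1)
sim = ax.simulate_cohort(cfg)

est = ax.estimate_global_ancestry(sim.genotypes[:200], sim.panel,
                                  m_grid=np.arange(0.01, 0.99, 0.01))
print("median estimated African ancestry:",
      round(est["african_ancestry"].median(), 3))

df = sim.cohort.copy()
df["african_ancestry"] = df["true_ancestry"]
ladder = ax.fit_logistic_tertiles(df, models=(1, 2))
print(ladder[["model", "tertile", "estimate", "ci_low", "ci_high",
              "percent_explained"]].round(2).to_string(index=False))

power = ax.power_simulation(2373, 1.8, reps=500,
                            beta_a=2.8168, beta_b=12.9517, rng=1)
print(f"power at psi=1.8, 2373 cases: {power.power:.2f} (se {power.se:.3f})")
```

prints

```
median estimated African ancestry: 0.83
model  tertile  estimate  ci_low  ci_high  percent_explained
 base        2      1.32    1.05     1.66                NaN
 base        3      1.67    1.33     2.09                NaN
  BMI        2      1.23    0.98     1.56              27.85
  BMI        3      1.47    1.17     1.86              29.46
power at psi=1.8, 2373 cases: 1.00 (se 0.000)
```

Reading the output: the HMM recovers the cohort's median African ancestry
(the generator is calibrated to 83.7%); individuals in the top ancestry
tertile have 1.67× the odds of diabetes of the bottom tertile after
age/sex/study adjustment, attenuated to 1.47× by BMI adjustment — BMI
"explains" 29% of the excess odds; and a case-only scan of 2,373 cases
detects a 1.8-fold per-allele risk at a fully informative locus
essentially always.

## Command-line pipeline

```sh
admixscan simulate --config cfg.yaml --seed 1 --out sim/
admixscan infer-ancestry --panel sim/panel.tsv --genotypes sim/genotypes.tsv --out anc/
admixscan scan --panel sim/panel.tsv --genotypes sim/genotypes.tsv --cohort sim/cohort.csv --out scan/
admixscan epi  --cohort sim/cohort.csv --ancestry anc/ancestry.tsv --out epi/
admixscan power --n-cases 2373 --psi 1.8 --reps 500 --seed 1 --out pow/
```

Every stage writes a `manifest.json` (config hash, seed, input/output
SHA-256 checksums); identical configs and inputs give identical
checksums.

### File formats

- **marker panel** — TSV: `marker_id, chromosome, genetic_pos` (Morgans,
  sorted within chromosome), `physical_pos` (1-based bp), `pE, pA`.
- **genotypes** — TSV: first column `id`, one column per marker, values
  0/1/2 or `NA`; or a VCF 4.2 subset (biallelic SNPs, GT only, `./.`
  missing, frequencies and Morgan positions in INFO).
- **cohort** — CSV preceded by `#key=value` header lines; columns include
  diabetes status, study, age, sex, BMI, education/income/occupation,
  HbA1c, glucose, insulin, fasting and treatment flags, age at diagnosis.
- **scan output** — TSV per locus (LOD, per-ψ log₁₀ LR, Z, calls) plus a
  0-based half-open BED of suggestive/significant intervals.

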
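"""Synthetic admixed cohorts: marker panels, ancestry tracts, genotypes, phenotypes.

Generative model
----------------
Each individual carries a European ancestry proportion M drawn from a Beta
distribution. Along each chromosome, each of the two haplotypes switches
ancestry at the points of a Poisson process with rate ``lambda_gen`` per
Morgan; at every switch the new ancestry is redrawn European with
probability M (the standard Markov approximation to post-admixture
recombination). Alleles are emitted from the ancestral allele frequency of
the haplotype's local ancestry (pE European, pA African), and genotypes are
unphased allele sums with a uniform missing rate.

Phenotypes follow a logistic diabetes model in African ancestry, BMI,
latent socioeconomic status (SES), age and sex — with an optional
per-allele multiplicative risk at a chosen locus — and additive-normal
quantitative traits (HbA1c, fasting glucose, fasting insulin).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .config import SimConfig
from .errors import AlignmentError, InvalidConfigError

STUDIES = ("ARIC", "JHS", "MEC")
# Cohort composition: ARIC 2,285 / JHS 3,185 / MEC 1,551 participants.
STUDY_PROBS = np.array([2285, 3185, 1551], dtype=float) / 7021.0
STUDY_AGE_RANGE = {"ARIC": (45, 64), "JHS": (35, 84), "MEC": (45, 75)}

EDUCATION_LEVELS = ["less_than_hs", "hs_grad", "some_college", "college_grad"]
INCOME_LEVELS = ["poor", "lower_middle", "upper_middle", "affluent", "missing"]
OCCUPATION_LEVELS = [
    "managerial_professional",
    "sales_technical_admin",
    "service",
    "farming_precision",
    "operators_laborers",
    "homemaker",
]

_EDU_PROBS = [0.40, 0.30, 0.17, 0.13]
_INCOME_PROBS = [0.20, 0.28, 0.30, 0.22]  # before the missing-income carve-out
_INCOME_MISSING_RATE = 0.12
_OCC_PROBS = [0.14, 0.24, 0.22, 0.11, 0.21, 0.08]
_SES_ANCESTRY_RHO = -0.35  # corr(latent SES, standardized African ancestry)


def simulate_marker_panel(config: SimConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Draw an ancestry-informative marker panel.

    Markers are spread (nearly) evenly over ``n_chromosomes`` chromosomes of
    ``chrom_length`` Morgans each, with sorted genetic positions and ancestral
    allele frequencies whose mean absolute divergence |pE - pA| matches
    ``freq_divergence``.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(4)[0])

    n, k = config.n_markers, config.n_chromosomes
    counts = np.full(k, n // k, dtype=int)
    counts[: n % k] += 1

    chroms = np.repeat(np.arange(1, k + 1), counts)
    pos = np.concatenate(
        [np.sort(rng.uniform(0.0, config.chrom_length, c)) for c in counts]
    )
    # 1 cM/Mb convention for the nominal physical coordinate.
    physical = np.rint(pos * 1e8).astype(np.int64) + 1

    if config.freq_divergence == 0.0:
        p_mid = rng.uniform(0.05, 0.95, n)
        p_eur = p_mid.copy()
        p_afr = p_mid.copy()
    else:
        div = np.clip(config.freq_divergence * rng.uniform(0.5, 1.5, n), 0.0, 0.95)
        mid = rng.uniform(div / 2 + 0.02, 1.0 - div / 2 - 0.02)
        sign = rng.choice([-1.0, 1.0], n)
        p_eur = mid + sign * div / 2
        p_afr = mid - sign * div / 2

    return pd.DataFrame(
        {
            "marker_id": [f"rs{c}_{i}" for c, i in zip(chroms, np.arange(n))],
            "chromosome": chroms.astype(int),
            "genetic_pos": pos,
            "physical_pos": physical,
            "pE": p_eur,
            "pA": p_afr,
        }
    )


def _haploid_path(M: float, lambda_gen: float, length: float, rng: np.random.Generator):
    """One haplotype's ancestry path: (switch positions, ancestries per segment).

    Ancestry coding: 1 = European, 0 = African. Segment ``i`` spans
    ``switches[i-1]``..``switches[i]`` (with implicit 0 and ``length`` ends).
    """
    n_switch = rng.poisson(lambda_gen * length)
    switches = np.sort(rng.uniform(0.0, length, n_switch))
    anc = (rng.uniform(size=n_switch + 1) < M).astype(np.int8)
    return switches, anc


def haploid_tract_lengths(
    M: float, lambda_gen: float, length: float, n_paths: int, rng: np.random.Generator
) -> np.ndarray:
    """Inter-switch distances pooled over ``n_paths`` haplotype paths.

    Interior tracts only (both ends censored); under the generative model
    these are Exponential with mean 1/lambda_gen Morgans.
    """
    out = []
    for _ in range(n_paths):
        sw, _anc = _haploid_path(M, lambda_gen, length, rng)
        if len(sw) >= 2:
            out.append(np.diff(sw))
    return np.concatenate(out) if out else np.empty(0)


def simulate_ancestry_tracts(
    M: float, lambda_gen: float, panel: pd.DataFrame, rng: np.random.Generator
) -> np.ndarray:
    """Diploid local-ancestry states (0/1/2 European alleles) at each marker."""
    if not (0.0 <= M <= 1.0):
        raise InvalidConfigError("ancestry proportion M must be in [0, 1]")
    if lambda_gen < 0:
        raise InvalidConfigError("lambda_gen must be >= 0")
    states = np.empty(len(panel), dtype=np.int8)
    for _chrom, idx in panel.groupby("chromosome", sort=True).indices.items():
        pos = panel["genetic_pos"].to_numpy()[idx]
        length = pos[-1] if len(pos) else 0.0
        dose = np.zeros(len(pos), dtype=np.int8)
        for _hap in range(2):
            sw, anc = _haploid_path(M, lambda_gen, length, rng)
            seg = np.searchsorted(sw, pos, side="right")
            dose += anc[seg]
        states[idx] = dose
    return states


def simulate_genotypes(
    states: np.ndarray,
    panel: pd.DataFrame,
    missing_rate: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Unphased genotypes (0/1/2 copies of the panel's counted allele, NaN missing).

    ``states`` may be (n_markers,) for one individual or
    (n_individuals, n_markers); the output has the same shape as float.
    """
    states = np.asarray(states)
    if states.shape[-1] != len(panel):
        raise AlignmentError(
            f"states last dimension {states.shape[-1]} != panel size {len(panel)}"
        )
    p_eur = panel["pE"].to_numpy()
    p_afr = panel["pA"].to_numpy()
    e = states.astype(np.int64)
    g = rng.binomial(e, np.broadcast_to(p_eur, states.shape)) + rng.binomial(
        2 - e, np.broadcast_to(p_afr, states.shape)
    )
    g = g.astype(float)
    if missing_rate > 0:
        g[rng.uniform(size=states.shape) < missing_rate] = np.nan
    return g


def calibrate_ancestry_beta(
    median_african: float = 0.837,
    iqr_african: tuple[float, float] = (0.762, 0.887),
) -> tuple[float, float]:
    """Beta shapes (a, b) for the *European* proportion matching target
    African-ancestry quantiles.

    Fits Beta(aA, bA) on African ancestry to the target median and IQR by
    weighted least squares on the three quantiles (median weighted 4x), then
    returns the mirrored European-side shapes (bA, aA).
    """
    targets = np.array([iqr_african[0], median_african, iqr_african[1]])
    weights = np.array([1.0, 4.0, 1.0])

    def loss(logp):
        a, b = np.exp(logp)
        q = stats.beta.ppf([0.25, 0.5, 0.75], a, b)
        return float(np.sum(weights * (q - targets) ** 2))

    res = optimize.minimize(
        loss, np.log([13.0, 3.0]), method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 2000},
    )
    a_afr, b_afr = np.exp(res.x)
    return float(b_afr), float(a_afr)


def _ordinal_from_latent(
    latent: np.ndarray, probs, levels, rng: np.random.Generator, noise: float = 0.6
) -> np.ndarray:
    """Threshold a noisy copy of a latent score into ordered categories.

    ``probs`` are the marginal category probabilities from lowest latent to
    highest; thresholds are the corresponding standard-normal quantiles.
    """
    z = (latent + noise * rng.standard_normal(len(latent))) / np.sqrt(1 + noise**2)
    cuts = stats.norm.ppf(np.cumsum(probs)[:-1])
    idx = np.searchsorted(cuts, z)
    return np.asarray(levels, dtype=object)[idx]


def simulate_phenotypes(
    african_ancestry: np.ndarray,
    risk_allele_dose: np.ndarray | None,
    config: SimConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Draw the cohort phenotype/covariate table.

    ``risk_allele_dose`` is the per-individual European-origin allele count
    (0/1/2) at the configured risk locus, or None when no locus is set.
    """
    config.validate()
    A = np.asarray(african_ancestry, dtype=float)
    n = len(A)
    eff = config.covariate_effects
    if risk_allele_dose is None and config.risk_locus is not None:
        raise InvalidConfigError("risk_locus is configured but no allele dose was given")

    study = rng.choice(STUDIES, size=n, p=STUDY_PROBS)
    age = np.empty(n)
    for s in STUDIES:
        lo, hi = STUDY_AGE_RANGE[s]
        m = study == s
        age[m] = rng.uniform(lo, hi, m.sum())
    sex = np.where(rng.uniform(size=n) < 0.40, "M", "F")

    zA = (A - A.mean()) / (A.std() + 1e-12)
    rho = _SES_ANCESTRY_RHO
    ses_latent = rho * zA + np.sqrt(1 - rho**2) * rng.standard_normal(n)

    bmi = np.clip(28.0 + 2.5 * (A - A.mean()) - 1.0 * ses_latent + rng.normal(0, 4.5, n), 15, 60)

    education = _ordinal_from_latent(-ses_latent, _EDU_PROBS[::-1], EDUCATION_LEVELS[::-1], rng)
    income = _ordinal_from_latent(ses_latent, _INCOME_PROBS, INCOME_LEVELS[:4], rng)
    income[rng.uniform(size=n) < _INCOME_MISSING_RATE] = "missing"
    occupation = _ordinal_from_latent(ses_latent, _OCC_PROBS, OCCUPATION_LEVELS[::-1], rng)

    logit = (
        eff.intercept
        + eff.ancestry * A
        + eff.bmi * (bmi - 28.0)
        + eff.ses * ses_latent
        + eff.age * (age - 55.0)
        + eff.sex_male * (sex == "M")
    )
    if config.risk_locus is not None:
        logit = logit + np.log(config.risk_locus.psi_true) * np.asarray(risk_allele_dose)
    diabetes = (rng.uniform(size=n) < 1.0 / (1.0 + np.exp(-logit))).astype(int)

    traits = {}
    for name, t in config.trait_effects.items():
        traits[name] = np.maximum(
            t.base
            + t.ancestry * A
            + t.bmi * (bmi - 28.0)
            + t.ses * ses_latent
            + t.diabetes * diabetes
            + rng.normal(0, t.sd, n),
            0.05,
        )

    on_treatment = (diabetes == 1) & (rng.uniform(size=n) < config.treated_fraction)
    fasting = rng.uniform(size=n) < 0.95
    age_at_diagnosis = np.full(n, np.nan)
    dcases = diabetes == 1
    age_at_diagnosis[dcases] = np.maximum(
        20.0, age[dcases] - rng.exponential(6.0, dcases.sum())
    )

    df = pd.DataFrame(
        {
            "id": [f"ind{i:05d}" for i in range(n)],
            "diabetes": diabetes,
            "study": study,
            "age": age,
            "sex": sex,
            "bmi": bmi,
            "education": education,
            "income": income,
            "occupation": occupation,
            "hba1c": traits.get("hba1c"),
            "glucose": traits.get("glucose"),
            "insulin": traits.get("insulin"),
            "fasting": fasting.astype(int),
            "on_treatment": on_treatment.astype(int),
            "age_at_diagnosis": age_at_diagnosis,
            "true_ancestry": A,
        }
    )
    # Mirror the study design: SES indicators and fasting traits were not
    # collected for the MEC controls used here.
    mec = df["study"] == "MEC"
    df.loc[mec, ["education", "income", "occupation"]] = pd.NA
    df.loc[mec, ["hba1c", "glucose", "insulin"]] = np.nan
    return df


@dataclass
class SimulatedCohort:
    """Everything one simulation run produces (truth included)."""

    config: SimConfig
    panel: pd.DataFrame
    european_ancestry: np.ndarray  # per-individual M (truth)
    states: np.ndarray  # (n_individuals, n_markers) true diploid European dose
    genotypes: np.ndarray  # (n_individuals, n_markers), NaN = missing
    cohort: pd.DataFrame


def simulate_cohort(config: SimConfig) -> SimulatedCohort:
    """Run the full generative pipeline under one seed.

    Randomness is split into named substreams (panel, ancestry, genotypes,
    phenotypes) spawned from ``config.seed``, so the whole output is a pure
    function of the config.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed).spawn(4)
    rng_panel, rng_anc, rng_geno, rng_pheno = (np.random.default_rng(s) for s in ss)

    panel = simulate_marker_panel(config, rng_panel)
    M = rng_anc.beta(config.ancestry_beta_a, config.ancestry_beta_b, config.n_individuals)
    states = np.vstack(
        [simulate_ancestry_tracts(m, config.lambda_gen, panel, rng_anc) for m in M]
    )
    genotypes = simulate_genotypes(states, panel, config.missing_rate, rng_geno)

    dose = None
    if config.risk_locus is not None:
        rl = config.risk_locus
        on_chrom = panel.index[panel["chromosome"] == rl.chromosome]
        j = on_chrom[np.argmin(np.abs(panel.loc[on_chrom, "genetic_pos"] - rl.position))]
        dose = states[:, j]
    cohort = simulate_phenotypes(1.0 - M, dose, config, rng_pheno)
    return SimulatedCohort(config, panel, M, states, genotypes, cohort)
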